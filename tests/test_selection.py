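"""Cross-validation, the 1% rule, subset enumeration/search, model comparison."""

import itertools

import numpy as np
import pytest

from phonotaxnet import network as nw
from phonotaxnet.selection import (
    CVResult,
    ModelSpec,
    SearchBudget,
    compare_models,
    cross_validate,
    enumerate_feature_sets,
    search,
    select_n_hidden,
)
from phonotaxnet.song_features import FeatureSet
from phonotaxnet.synthetic_data import (
    BehavioralDataset,
    generate_dataset,
    random_design,
)


def toy_dataset(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return generate_dataset(n, design=random_design(n, rng), rng=rng)


class TestEnumerateFeatureSets:
    def test_counts_match_binomials(self):
        sets = enumerate_feature_sets()
        assert len(sets) == 255
        by_size = {s: sum(1 for fs in sets if len(fs) == s) for s in range(1, 9)}
        assert by_size[1] == 8
        # brute-force oracle
        assert by_size[4] == len(list(itertools.combinations(range(8), 4))) == 70

    def test_deterministic_canonical_order(self):
        a = enumerate_feature_sets()
        b = enumerate_feature_sets()
        assert [fs.names for fs in a] == [fs.names for fs in b]
        sizes = [len(fs) for fs in a]
        assert sizes == sorted(sizes)


class TestSelectNHidden:
    def test_rule_applied_directly(self):
        # i(1) = 100*(1.0-0.5)/1.0 = 50 > 1; i(2) = 100*(0.5-0.498)/1.0 = 0.2 <= 1
        n, capped = select_n_hidden({1: 1.0, 2: 0.5, 3: 0.498})
        assert n == 2 and not capped

    def test_constant_errors_select_one(self):
        n, capped = select_n_hidden({1: 0.3, 2: 0.3, 3: 0.3})
        assert n == 1 and not capped

    def test_steady_improvement_caps_at_n_max(self):
        errors = {n: 1.0 - 0.1 * (n - 1) for n in range(1, 6)}
        with pytest.warns(UserWarning, match="1%"):
            n, capped = select_n_hidden(errors)
        assert n == 5 and capped

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            select_n_hidden({1: 1.0})
        with pytest.raises(ValueError):
            select_n_hidden({1: 0.0, 2: 0.1})
        with pytest.raises(ValueError):
            select_n_hidden({2: 1.0, 3: 0.5})


class TestCrossValidate:
    def test_single_repeat_two_folds(self):
        ds = toy_dataset()
        spec = ModelSpec(FeatureSet(("pulse_period", "chirp_period")), 1)
        cv = cross_validate(spec, ds, k=2, repeats=1,
                            rprop=nw.RPropConfig(cycles=100), rng=0)
        assert cv.n_repeats == 1
        assert cv.mse_val_mean == cv.per_repeat_val_mse[0]

    def test_master_seed_determinism(self):
        ds = toy_dataset()
        spec = ModelSpec(FeatureSet(("pulse_period", "chirp_pause")), 2)
        kwargs = dict(k=3, repeats=2, rprop=nw.RPropConfig(cycles=100))
        a = cross_validate(spec, ds, rng=42, **kwargs)
        b = cross_validate(spec, ds, rng=42, **kwargs)
        assert a.per_repeat_val_mse == b.per_repeat_val_mse
        assert a.per_repeat_train_mse == b.per_repeat_train_mse

    def test_realizable_targets_validate_below_001(self):
        """Noise-free targets from a 1-hidden-unit teacher are recovered in CV."""
        rng = np.random.default_rng(5)
        ds = toy_dataset(60, seed=5)
        fs = FeatureSet(("pulse_period", "chirp_period"))
        teacher = nw.init_network(2, 1, rng)
        X = ds.feature_matrix(fs.names)
        Xn = (X - X.mean(0)) / X.std(0)
        frame = ds.frame.copy()
        frame["mean_score"] = np.clip(nw.forward(teacher, Xn), -1, 1)
        ds2 = BehavioralDataset(frame)
        cv = cross_validate(ModelSpec(fs, 1), ds2, k=5, repeats=2,
                            rprop=nw.RPropConfig(cycles=2000), rng=6)
        assert cv.mse_val_mean < 0.01

    def test_validation_rows_cannot_leak_into_training(self):
        """Perturbing a row changes trained weights only where it is a training row."""
        from phonotaxnet.preprocessing import classify

        ds = toy_dataset(30, seed=7)
        spec = ModelSpec(FeatureSet(("pulse_period", "chirp_pause")), 1)
        kwargs = dict(k=2, repeats=1, rprop=nw.RPropConfig(cycles=150),
                      redraw_folds=False)

        def capture(store):
            def cb(rep, fold, va_idx, params):
                store[(rep, fold)] = (np.array(va_idx), params.flatten())
            return cb

        base: dict = {}
        cross_validate(spec, ds, rng=8, fold_callback=capture(base), **kwargs)
        # perturb one row's score without changing its class (folds stay identical)
        va_row = 0
        frame = ds.frame.copy()
        old = float(frame.loc[va_row, "mean_score"])
        new = next(
            v for v in (old + 0.05, old - 0.05)
            if -1 <= v <= 1 and classify(v) == classify(old)
        )
        frame.loc[va_row, "mean_score"] = new
        pert: dict = {}
        cross_validate(spec, BehavioralDataset(frame), rng=8,
                       fold_callback=capture(pert), **kwargs)

        checked_val = checked_train = False
        for key in base:
            va_idx, w_base = base[key]
            va_idx2, w_pert = pert[key]
            np.testing.assert_array_equal(va_idx, va_idx2)
            if va_row in va_idx:
                # row was validation-only for this fold: weights untouched
                np.testing.assert_array_equal(w_base, w_pert)
                checked_val = True
            else:
                assert not np.array_equal(w_base, w_pert)
                checked_train = True
        assert checked_val and checked_train


class TestSearch:
    @pytest.fixture(scope="class")
    def small_search(self):
        ds = toy_dataset(60, seed=9)
        budget = SearchBudget(repeats=1, cycles=60, k=5, n_max=1)
        return search(ds, budget=budget, rng=10)

    def test_returns_all_255_entries(self, small_search):
        assert len(small_search) == 255

    def test_ranking_is_a_permutation(self, small_search):
        names = sorted(e.spec.feature_set.names for e in small_search)
        expected = sorted(fs.names for fs in enumerate_feature_sets())
        assert names == expected
        assert [e.rank for e in small_search] == list(range(1, 256))

    def test_collinear_subsets_flagged_and_ranked_last(self, small_search):
        failed = [e for e in small_search if e.failed]
        # subsets containing {duration, pause, period} of one scale are singular
        assert len(failed) == 60
        assert all(e.rank > 195 for e in failed)
        for e in small_search:
            triple = {"pulse_duration", "pulse_pause", "pulse_period"}
            if triple <= set(e.spec.feature_set.names):
                assert e.failed


class TestCompareModels:
    @staticmethod
    def exact_ranksum_p(x, y):
        """Two-sided rank-sum p by brute-force enumeration (small n oracle)."""
        both = np.concatenate([x, y])
        ranks = both.argsort().argsort() + 1.0
        observed = ranks[: len(x)].sum()
        n = len(both)
        stats = [
            sum(combo)
            for combo in itertools.combinations(range(1, n + 1), len(x))
        ]
        stats = np.array(stats, dtype=float)
        mean = stats.mean()
        p = np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
        return float(p)

    def test_identical_samples_not_different(self):
        cv = CVResult(tuple(np.linspace(0.1, 0.2, 10)), tuple(np.zeros(10)))
        p, different = compare_models(cv, cv)
        assert p == pytest.approx(1.0)
        assert not different

    def test_separated_samples_highly_significant(self):
        a = CVResult(tuple(np.arange(1.0, 101.0)), tuple(np.zeros(100)))
        b = CVResult(tuple(np.arange(201.0, 301.0)), tuple(np.zeros(100)))
        p, different = compare_models(a, b)
        assert p < 1e-10 and different

    def test_normal_approximation_close_to_exact_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([201.0, 202.0, 203.0, 204.0, 205.0])
        p_exact = self.exact_ranksum_p(x, y)
        p_approx, _ = compare_models(
            CVResult(tuple(x), tuple(np.zeros(5))), CVResult(tuple(y), tuple(np.zeros(5)))
        )
        # fully separated n=5 samples: exact p = 2/252
        assert p_exact == pytest.approx(2 / 252)
        assert p_approx < 0.05
        assert abs(p_approx - p_exact) < 0.01

    def test_null_jitter_rarely_significant(self):
        """Same-mean tiny-jitter samples must almost never flag a difference."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = CVResult(tuple(0.5 + 1e-6 * rng.normal(size=100)), tuple(np.zeros(100)))
            b = CVResult(tuple(0.5 + 1e-6 * rng.normal(size=100)), tuple(np.zeros(100)))
            _, different = compare_models(a, b)
            hits += different
        assert hits <= 1

    def test_too_few_repeats_rejected(self):
        a = CVResult((0.1,), (0.1,))
        with pytest.raises(ValueError):
            compare_models(a, a)
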