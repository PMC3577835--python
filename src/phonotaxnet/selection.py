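"""Model selection: repeated stratified CV, the 1% rule, and subset search.

Every candidate model is a (feature set, hidden-layer size) pair.  Its
quality is the validation MSE of a stratified k-fold cross-validation,
repeated with fresh random weight initializations (and, by default,
freshly drawn folds) and averaged.  The hidden-layer size is chosen by the
1% rule: the smallest n whose successor improves the validation error by no
more than 1% of the single-hidden-unit error.  The exhaustive search runs
this procedure for every one of the 255 non-empty subsets of the eight
temporal features and ranks the selected models; pairs of models are
compared with a two-sided Wilcoxon rank-sum test on their per-repeat
validation errors.

Within each fold the whitening transform is fit on that fold's training
rows only, so validation rows never influence preprocessing or weights.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import network as nw
from .preprocessing import (
    RankDeficientError,
    classify_scores,
    fit_whitening,
    apply_whitening,
    stratified_kfold,
)
from .song_features import FEATURE_NAMES, FeatureSet
from .synthetic_data import BehavioralDataset


@dataclass(frozen=True)
class ModelSpec:
    feature_set: FeatureSet
    n_hidden: int

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")


@dataclass(frozen=True)
class CVResult:
    """Aggregated repeated-CV errors; per-repeat values retained for testing."""

    per_repeat_val_mse: tuple[float, ...]
    per_repeat_train_mse: tuple[float, ...]

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat_val_mse)

    @property
    def mse_val_mean(self) -> float:
        return float(np.mean(self.per_repeat_val_mse))

    @property
    def mse_val_sd(self) -> float:
        return float(np.std(self.per_repeat_val_mse, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def mse_train_mean(self) -> float:
        return float(np.mean(self.per_repeat_train_mse))

    @property
    def mse_train_sd(self) -> float:
        return float(np.std(self.per_repeat_train_mse, ddof=1)) if self.n_repeats > 1 else 0.0


@dataclass
class RankingEntry:
    spec: ModelSpec
    cv: CVResult | None
    rank: int = 0
    failed: bool = False
    error: str | None = None


def cross_validate(
    spec: ModelSpec,
    train: BehavioralDataset,
    k: int = 5,
    repeats: int = 100,
    rprop: nw.RPropConfig | None = None,
    rng: np.random.Generator | int | None = None,
    redraw_folds: bool = True,
    whiten_per_fold: bool = True,
    fold_callback=None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of one model spec.

    Each repeat draws fresh initial weights (and, with ``redraw_folds``,
    fresh fold assignments), fits whitening on the k-1 training folds, trains
    for the full cycle budget, and records fold-averaged train/validation
    MSE.  With ``whiten_per_fold=False`` a single transform fit on the whole
    training set is reused inside every fold (the leakier global variant).
    """
    rprop = rprop or nw.RPropConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X_all = train.feature_matrix(spec.feature_set.names)
    y_all = train.scores
    labels = classify_scores(y_all)
    global_white = None if whiten_per_fold else fit_whitening(X_all)

    folds = stratified_kfold(labels, k, rng)
    val_mses, train_mses = [], []
    for rep in range(repeats):
        if redraw_folds:
            folds = stratified_kfold(labels, k, rng)
        fold_val, fold_train = [], []
        for fold_i, (tr_idx, va_idx) in enumerate(folds):
            X_tr, y_tr = X_all[tr_idx], y_all[tr_idx]
            X_va, y_va = X_all[va_idx], y_all[va_idx]
            white = fit_whitening(X_tr) if whiten_per_fold else global_white
            Z_tr = apply_whitening(white, X_tr)
            Z_va = apply_whitening(white, X_va)
            p0 = nw.init_network(
                len(spec.feature_set), spec.n_hidden, rng, rprop.init_weight_range
            )
            p_fit, report = nw.train_rprop(p0, Z_tr, y_tr, rprop)
            fold_train.append(report.final_train_mse)
            fold_val.append(nw.mse(nw.forward(p_fit, Z_va), y_va))
            if fold_callback is not None:
                fold_callback(rep, fold_i, va_idx, p_fit)
        val_mses.append(float(np.mean(fold_val)))
        train_mses.append(float(np.mean(fold_train)))
    return CVResult(tuple(val_mses), tuple(train_mses))


def select_n_hidden(
    errors_by_n: dict[int, float], relative_to_first: bool = True
) -> tuple[int, bool]:
    """Smallest hidden-layer size beyond which the gain is at most 1%.

    The improvement of step n is ``100 * (E(n) - E(n+1)) / E(1)`` (or
    ``/ E(n)`` with ``relative_to_first=False``); the selected n is the
    smallest with improvement <= 1.  Returns ``(n, capped)`` where ``capped``
    flags that no n qualified and the largest scanned value was returned.
    """
    ns = sorted(errors_by_n)
    if ns != list(range(1, len(ns) + 1)) or len(ns) < 2:
        raise ValueError("need contiguous n = 1..n_max with n_max >= 2")
    if errors_by_n[1] <= 0:
        raise ValueError("E(1) must be positive")
    for n in ns[:-1]:
        denom = errors_by_n[1] if relative_to_first else errors_by_n[n]
        improvement = 100.0 * (errors_by_n[n] - errors_by_n[n + 1]) / denom
        if improvement <= 1.0:
            return n, False
    warnings.warn("no hidden-layer size met the 1% rule; returning the scan maximum")
    return ns[-1], True


def enumerate_feature_sets() -> list[FeatureSet]:
    """All 255 non-empty subsets of the eight features, by size then canonical order."""
    out = []
    for size in range(1, len(FEATURE_NAMES) + 1):
        for combo in itertools.combinations(FEATURE_NAMES, size):
            out.append(FeatureSet(combo))
    return out


@dataclass(frozen=True)
class SearchBudget:
    """Desk-scale knobs for the exhaustive search (full study: 100/10000/10)."""

    repeats: int = 5
    cycles: int = 2_000
    k: int = 5
    n_max: int = 10


def search(
    train: BehavioralDataset,
    budget: SearchBudget | None = None,
    rng: np.random.Generator | int | None = None,
    rprop: nw.RPropConfig | None = None,
) -> list[RankingEntry]:
    """Exhaustive feature-subset search with per-subset hidden-size selection.

    For every feature set, cross-validates n = 1..n_max hidden units, applies
    the 1% rule, and keeps the selected spec's CV result.  Subsets on which
    preprocessing or training fails (e.g. exactly collinear subsets such as
    {duration, pause, period} of one time scale, whose covariance is
    singular) are flagged and ranked last rather than aborting the search.
    Ranking is ascending in validation MSE; ties break toward smaller
    feature sets, then fewer hidden units, then canonical order.
    """
    budget = budget or SearchBudget()
    base = rprop or nw.RPropConfig()
    rprop_run = nw.RPropConfig(
        cycles=budget.cycles,
        eta_plus=base.eta_plus,
        eta_minus=base.eta_minus,
        delta_init=base.delta_init,
        delta_min=base.delta_min,
        delta_max=base.delta_max,
        init_weight_range=base.init_weight_range,
    )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    entries: list[RankingEntry] = []
    for i, fs in enumerate(enumerate_feature_sets()):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        try:
            errors: dict[int, float] = {}
            results: dict[int, CVResult] = {}
            for n in range(1, budget.n_max + 1):
                cv = cross_validate(
                    ModelSpec(fs, n), train, k=budget.k, repeats=budget.repeats,
                    rprop=rprop_run, rng=sub_rng,
                )
                errors[n] = cv.mse_val_mean
                results[n] = cv
            if budget.n_max >= 2:
                n_sel, _ = select_n_hidden(errors)
            else:
                n_sel = 1
            entries.append(RankingEntry(ModelSpec(fs, n_sel), results[n_sel]))
        except (RankDeficientError, nw.TrainingDivergedError, ValueError) as exc:
            entries.append(
                RankingEntry(ModelSpec(fs, 1), None, failed=True, error=str(exc))
            )

    canon = {fs.names: i for i, fs in enumerate(enumerate_feature_sets())}

    def sort_key(e: RankingEntry):
        val = e.cv.mse_val_mean if not e.failed else np.inf
        return (e.failed, val, len(e.spec.feature_set), e.spec.n_hidden, canon[e.spec.feature_set.names])

    entries.sort(key=sort_key)
    for r, e in enumerate(entries, start=1):
        e.rank = r
    return entries


def compare_models(a: CVResult, b: CVResult, alpha: float = 0.01) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum test on per-repeat validation errors.

    Returns ``(p_value, different)`` with ``different`` true iff p < alpha.
    """
    xa = np.asarray(a.per_repeat_val_mse)
    xb = np.asarray(b.per_repeat_val_mse)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 repeats per model")
    stat, p = stats.ranksums(xa, xb)
    return float(p), bool(p < alpha)
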