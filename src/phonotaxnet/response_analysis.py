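"""Ensemble prediction, response fields, time-scale fusion, and calibration.

For predictions on untested song patterns the selected network is retrained
from fresh random weights many times on the full dataset (whitened features)
and the predictions are averaged across repetitions; the across-member
standard deviation quantifies the initialization variability.  Response
fields evaluate the ensemble over a 2-D grid of two song features with the
remaining degrees of freedom fixed, e.g. pulse duration x pulse pause at a
fixed attractive chirp.  A scalar fusion index summarizes whether the
predicted period x period surface behaves like a logical AND (high response
requires attractive structure on both time scales) or OR (either suffices).
Finally, a two-parameter sigmoid mapping the network output onto [-1, 1]
can be fit on training predictions to correct the compressive bias of the
linear output unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit

from . import network as nw
from .preprocessing import WhiteningTransform, apply_whitening, fit_whitening
from .selection import ModelSpec
from .song_features import PatternError, SongPattern, complete_pattern, vectorize_many
from .synthetic_data import BehavioralDataset


@dataclass
class Ensemble:
    """Independently retrained copies of one model spec on one dataset."""

    members: list[nw.NetworkParams]
    whitening: WhiteningTransform
    spec: ModelSpec

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PerformanceReport:
    mse_test: float
    pearson_r: float
    regression_slope: float
    pred_mean: np.ndarray
    pred_sd: np.ndarray


@dataclass(frozen=True)
class ResponseField:
    axis_features: tuple[str, str]
    axis_grids: tuple[np.ndarray, np.ndarray]
    fixed_assignment: dict[str, float]
    mean_scores: np.ndarray  # (len(grid1), len(grid2)); NaN where completion invalid
    sd_scores: np.ndarray

    def argmax_coordinates(self) -> tuple[float, float]:
        """Grid coordinates of the field's maximum mean score."""
        flat = np.where(np.isnan(self.mean_scores), -np.inf, self.mean_scores)
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        return float(self.axis_grids[0][i]), float(self.axis_grids[1][j])


@dataclass(frozen=True)
class FusionRegions:
    """Sub-rectangles of the pulse-period x chirp-period plane (ms)."""

    attractive_pulse: tuple[float, float] = (35.0, 45.0)
    attractive_chirp: tuple[float, float] = (250.0, 500.0)
    # the unattractive strips start beyond the response flanks, where the
    # attractiveness of the detuned scale has genuinely decayed; chirp
    # periods just above 500 ms still yield intermediate responses
    unattractive_pulse_above: float = 60.0
    unattractive_chirp_above: float = 700.0


@dataclass(frozen=True)
class FusionIndex:
    value: float
    r_both: float
    r_pulse_only: float
    r_chirp_only: float
    baseline: float


@dataclass(frozen=True)
class CalibrationParams:
    """Sigmoid g(y) = -1 + 2 / (1 + exp(-slope * (y - midpoint))) onto (-1, 1)."""

    slope: float
    midpoint: float
    identity_fallback: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def build_ensemble(
    ds: BehavioralDataset,
    spec: ModelSpec,
    n_members: int = 100,
    rprop: nw.RPropConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Ensemble:
    """Train ``n_members`` fresh networks on the whitened full dataset.

    The whitening transform is fit once on the dataset (it is deterministic)
    and shared by all members; members differ only in their random initial
    weights.  Diverged members are dropped with a warning; more than 10%
    divergence fails the ensemble.
    """
    rprop = rprop or nw.RPropConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = ds.feature_matrix(spec.feature_set.names)
    y = ds.scores
    white = fit_whitening(X)
    Z = apply_whitening(white, X)
    members, diverged = [], 0
    for _ in range(n_members):
        p0 = nw.init_network(len(spec.feature_set), spec.n_hidden, rng, rprop.init_weight_range)
        try:
            p_fit, _ = nw.train_rprop(p0, Z, y, rprop)
            members.append(p_fit)
        except nw.TrainingDivergedError:
            diverged += 1
    if diverged > 0.1 * n_members:
        raise nw.TrainingDivergedError(
            f"{diverged}/{n_members} ensemble members diverged"
        )
    if diverged:
        warnings.warn(f"dropped {diverged} diverged ensemble member(s)")
    return Ensemble(members, white, spec)


def member_predictions(e: Ensemble, patterns: list[SongPattern]) -> np.ndarray:
    """(n_members, n_patterns) matrix of raw member outputs."""
    X = vectorize_many(patterns, e.spec.feature_set)
    Z = apply_whitening(e.whitening, X)
    return np.array([nw.forward(m, Z) for m in e.members])


def predict(e: Ensemble, patterns: list[SongPattern]) -> tuple[np.ndarray, np.ndarray]:
    """Across-member mean and standard deviation of predictions per pattern."""
    P = member_predictions(e, patterns)
    sd = P.std(axis=0, ddof=1) if P.shape[0] > 1 else np.zeros(P.shape[1])
    return P.mean(axis=0), sd


def evaluate(
    train: BehavioralDataset,
    test: BehavioralDataset,
    spec: ModelSpec,
    n_members: int = 100,
    rprop: nw.RPropConfig | None = None,
    rng: np.random.Generator | int | None = None,
    calibration: CalibrationParams | None = None,
) -> PerformanceReport:
    """Test-set performance of the averaged retrained model.

    Trains an ensemble on the training rows (whitening fit there as well),
    averages its predictions on the held-out rows, and reports test MSE,
    the Pearson correlation with the observed mean scores, and the ordinary
    least-squares slope of observed on predicted.
    """
    ens = build_ensemble(train, spec, n_members=n_members, rprop=rprop, rng=rng)
    pred_mean, pred_sd = predict(ens, test.patterns())
    if calibration is not None:
        pred_mean = apply_calibration(calibration, pred_mean)
    obs = test.scores
    if np.ptp(pred_mean) == 0:
        raise ValueError("constant predictions: correlation undefined")
    slope = float(np.polyfit(pred_mean, obs, 1)[0])
    return PerformanceReport(
        mse_test=nw.mse(pred_mean, obs),
        pearson_r=nw.pearson_r(pred_mean, obs),
        regression_slope=slope,
        pred_mean=pred_mean,
        pred_sd=pred_sd,
    )


def response_field(
    e: Ensemble,
    axis_features: tuple[str, str],
    axis_grids: tuple[np.ndarray, np.ndarray],
    fixed: dict[str, float],
) -> ResponseField:
    """Predicted score surface over a 2-D grid of two song features.

    ``axis_features`` plus ``fixed`` must supply exactly two descriptors per
    time scale so each grid point completes to a unique pattern.  Grid
    points whose completion is invalid (e.g. implied negative pause) are
    excluded and carry NaN.
    """
    f1, f2 = axis_features
    g1 = np.asarray(axis_grids[0], dtype=float)
    g2 = np.asarray(axis_grids[1], dtype=float)
    given_names = {f1, f2, *fixed}
    if len(given_names) != 4:
        raise ValueError("axes plus fixed values must name four distinct descriptors")
    for scale in ("pulse", "chirp"):
        if sum(n.startswith(scale) for n in given_names) != 2:
            raise ValueError(
                f"need exactly two {scale} descriptors among axes and fixed values"
            )

    patterns, where = [], []
    for i, a in enumerate(g1):
        for j, b in enumerate(g2):
            try:
                patterns.append(complete_pattern(**{f1: a, f2: b, **fixed}))
                where.append((i, j))
            except PatternError:
                continue
    mean = np.full((len(g1), len(g2)), np.nan)
    sd = np.full((len(g1), len(g2)), np.nan)
    if patterns:
        m, s = predict(e, patterns)
        for (i, j), mv, sv in zip(where, m, s):
            mean[i, j] = mv
            sd[i, j] = sv
    return ResponseField((f1, f2), (g1, g2), dict(fixed), mean, sd)


def fusion_index_from_surface(
    pulse_periods: np.ndarray,
    chirp_periods: np.ndarray,
    surface: np.ndarray,
    regions: FusionRegions | None = None,
) -> FusionIndex:
    """AND/OR index of a pulse-period x chirp-period score surface.

    value = clip((r_both - max(r_pulse_only, r_chirp_only)) / (r_both - baseline), 0, 1)

    where r_both is the peak response with both time scales attractive,
    r_pulse_only / r_chirp_only the peaks with the other scale detuned, and
    the baseline is the surface minimum.  Near 1 the surface requires both
    scales (AND); near 0 either scale suffices (OR).
    """
    regions = regions or FusionRegions()
    P = np.asarray(pulse_periods, dtype=float)
    C = np.asarray(chirp_periods, dtype=float)
    S = np.asarray(surface, dtype=float)
    if S.shape != (len(P), len(C)):
        raise ValueError("surface shape must be (len(pulse_periods), len(chirp_periods))")
    ap = (P >= regions.attractive_pulse[0]) & (P <= regions.attractive_pulse[1])
    ac = (C >= regions.attractive_chirp[0]) & (C <= regions.attractive_chirp[1])
    up = P > regions.unattractive_pulse_above
    uc = C > regions.unattractive_chirp_above
    for name, mask in (("attractive pulse", ap), ("attractive chirp", ac),
                       ("unattractive pulse", up), ("unattractive chirp", uc)):
        if not mask.any():
            raise ValueError(f"no grid points in the {name} region")
    valid = np.isfinite(S)
    def region_max(rows, cols):
        block = np.where(valid[np.ix_(rows, cols)], S[np.ix_(rows, cols)], -np.inf)
        return float(block.max())
    r_both = region_max(ap, ac)
    r_pulse = region_max(ap, uc)
    r_chirp = region_max(up, ac)
    baseline = float(np.min(np.where(valid, S, np.inf)))
    if r_both <= baseline:
        raise ValueError("degenerate surface: peak response does not exceed baseline")
    raw = (r_both - max(r_pulse, r_chirp)) / (r_both - baseline)
    return FusionIndex(float(np.clip(raw, 0.0, 1.0)), r_both, r_pulse, r_chirp, baseline)


def fusion_index(
    e: Ensemble,
    pulse_periods: np.ndarray | None = None,
    chirp_periods: np.ndarray | None = None,
    regions: FusionRegions | None = None,
) -> FusionIndex:
    """Fusion index of the ensemble's period x period field at duty cycles 0.5."""
    if pulse_periods is None:
        pulse_periods = np.arange(10.0, 80.0 + 1e-9, 2.5)
    if chirp_periods is None:
        chirp_periods = np.arange(50.0, 900.0 + 1e-9, 10.0)
    fld = response_field(
        e,
        ("pulse_period", "chirp_period"),
        (np.asarray(pulse_periods), np.asarray(chirp_periods)),
        {"pulse_duty_cycle": 0.5, "chirp_duty_cycle": 0.5},
    )
    return fusion_index_from_surface(
        fld.axis_grids[0], fld.axis_grids[1], fld.mean_scores, regions
    )


def apply_calibration(c: CalibrationParams, pred: np.ndarray) -> np.ndarray:
    """Elementwise sigmoid mapping raw predictions into (-1, 1)."""
    y = np.asarray(pred, dtype=float)
    return -1.0 + 2.0 * expit(c.slope * (y - c.midpoint))


def _calibration_mse(ab: np.ndarray, pred: np.ndarray, obs: np.ndarray) -> float:
    a, b = ab
    if a <= 0:
        return np.inf
    g = -1.0 + 2.0 * expit(a * (pred - b))
    return float(np.mean((g - obs) ** 2))


def fit_calibration(train_pred: np.ndarray, train_obs: np.ndarray) -> CalibrationParams:
    """Fit the sigmoid's slope and midpoint by training-MSE minimization.

    A coarse grid over slope (log-spaced) and midpoint seeds a Nelder-Mead
    refinement.  If even the best sigmoid is worse than the raw predictions,
    the sigmoid closest to the identity on the prediction range is returned
    instead, flagged via ``identity_fallback`` (and a warning).
    """
    pred = np.asarray(train_pred, dtype=float).reshape(-1)
    obs = np.asarray(train_obs, dtype=float).reshape(-1)
    if len(pred) < 4:
        raise ValueError("need at least 4 points to fit the calibration")
    if np.ptp(pred) == 0:
        raise ValueError("constant predictions: calibration undefined")

    slopes = np.geomspace(0.25, 32.0, 12)
    mids = np.linspace(pred.min(), pred.max(), 13)
    best = min(
        ((a, b) for a in slopes for b in mids),
        key=lambda ab: _calibration_mse(np.array(ab), pred, obs),
    )
    res = optimize.minimize(
        _calibration_mse, x0=np.array(best), args=(pred, obs), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    a, b = res.x
    calibrated = _calibration_mse(res.x, pred, obs)
    uncalibrated = float(np.mean((pred - obs) ** 2))
    if calibrated <= uncalibrated + 1e-9:
        return CalibrationParams(float(a), float(b))
    # identity-approximating fallback: least-squares fit of g to y on the range
    grid = np.linspace(pred.min(), pred.max(), 64)
    res_id = optimize.minimize(
        _calibration_mse, x0=np.array([2.0, 0.0]), args=(grid, grid), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    warnings.warn("sigmoid calibration did not improve the training MSE; "
                  "returning the identity-approximating sigmoid")
    return CalibrationParams(float(res_id.x[0]), float(res_id.x[1]), identity_fallback=True)
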