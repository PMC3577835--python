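"""Class stratification, stratified splitting, and PCA whitening.

The behavioral scores are grouped into three attractiveness classes
(unattractive < 0.2, intermediate in [0.2, 0.6], attractive > 0.6) and every
division of the data — the train/test split and the cross-validation folds —
preserves the class proportions (stratified sampling).  Feature matrices are
whitened before network training: projection onto principal components
removes linear correlations, then each component is scaled to zero mean and
unit variance.  The transform is always fit on training rows only and merely
applied to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

CLASS_LABELS = ("unattractive", "intermediate", "attractive")
UNATTRACTIVE_BELOW = 0.2
ATTRACTIVE_ABOVE = 0.6


class RankDeficientError(ValueError):
    """Feature matrix has (numerically) linearly dependent columns."""

    def __init__(self, message: str, null_directions: np.ndarray):
        super().__init__(message)
        self.null_directions = null_directions


def classify(score: float) -> str:
    """Attractiveness class of a mean phonotactic score.

    Boundary scores 0.2 and 0.6 belong to the (closed) intermediate interval.
    """
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [-1, 1]")
    if score < UNATTRACTIVE_BELOW:
        return "unattractive"
    if score > ATTRACTIVE_ABOVE:
        return "attractive"
    return "intermediate"


def classify_scores(scores: Sequence[float]) -> np.ndarray:
    return np.array([classify(float(s)) for s in scores])


@dataclass(frozen=True)
class SplitAssignment:
    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        both = np.concatenate([tr, te])
        if len(np.unique(both)) != len(both):
            raise ValueError("train/test indices overlap or repeat")


def _largest_remainder_quotas(counts: np.ndarray, n_total: int) -> np.ndarray:
    """Proportional integer allocation with largest-remainder rounding."""
    ideal = counts * n_total / counts.sum()
    quotas = np.floor(ideal).astype(int)
    remainder = ideal - quotas
    short = n_total - quotas.sum()
    # ties broken by class order (deterministic)
    for i in np.argsort(-remainder, kind="stable")[:short]:
        quotas[i] += 1
    return quotas


def stratified_split(labels: Sequence[str], n_test: int, rng: np.random.Generator) -> SplitAssignment:
    """Stratified train/test split over class labels.

    Test quotas per class follow proportional allocation with
    largest-remainder rounding; class members are sampled without
    replacement.  ``labels`` may come from :func:`classify_scores`.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if not 0 <= n_test < n:
        raise ValueError("need 0 <= n_test < dataset size")
    classes, counts = np.unique(labels, return_counts=True)
    quotas = _largest_remainder_quotas(counts, n_test)
    if np.any(quotas > counts):
        bad = classes[quotas > counts]
        raise ValueError(f"class smaller than its test quota: {list(bad)}")
    test_idx = []
    for cls, q in zip(classes, quotas):
        members = np.flatnonzero(labels == cls)
        test_idx.extend(rng.choice(members, size=q, replace=False))
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return SplitAssignment(train_idx, test_idx)


def stratified_kfold(
    labels: Sequence[str], k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k stratified folds as (train_indices, val_indices) pairs.

    Folds partition the data, fold sizes differ by at most one, and per-fold
    class counts stay within one of the proportional ideal.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels):
        raise ValueError("k exceeds number of rows")
    seed = int(rng.integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (np.asarray(tr, dtype=int), np.asarray(va, dtype=int))
        for tr, va in skf.split(np.zeros((len(labels), 1)), labels)
    ]


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map z = linear_map @ (x - center) with identity output covariance."""

    center: np.ndarray       # (d,)
    linear_map: np.ndarray   # (d, d): rows scale principal components

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return apply_whitening(self, X)

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ np.linalg.inv(self.linear_map).T + self.center


def fit_whitening(X: np.ndarray, rank_tol: float = 1e-10) -> WhiteningTransform:
    """Fit a PCA whitening transform on the rows of ``X``.

    Raises
    ------
    RankDeficientError
        If the sample covariance is numerically singular (some feature
        combination is constant), carrying the offending null directions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more rows ({n}) than features ({d})")
    center = X.mean(axis=0)
    cov = np.cov(X - center, rowvar=False, ddof=1).reshape(d, d)
    evals, evecs = np.linalg.eigh(cov)
    scale = max(float(evals.max()), 1e-300)
    bad = evals < rank_tol * scale
    if bad.any():
        raise RankDeficientError(
            f"feature matrix is rank deficient ({int(bad.sum())} null direction(s))",
            null_directions=evecs[:, bad].T,
        )
    linear_map = (evecs / np.sqrt(evals)).T  # rows: scaled principal axes
    return WhiteningTransform(center=center, linear_map=linear_map)


def apply_whitening(t: WhiteningTransform, X: np.ndarray) -> np.ndarray:
    """Apply a fitted whitening transform (no refit) to new rows."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != t.center.shape[0]:
        raise ValueError(
            f"dimension mismatch: transform fit on {t.center.shape[0]} features, got {X.shape[1]}"
        )
    Z = (X - t.center) @ t.linear_map.T
    return Z[0] if single else Z
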