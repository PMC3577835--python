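"""One-hidden-layer perceptron for phonotactic-score regression, trained with RProp.

The model maps a vector of (whitened) temporal song features x to a scalar
score prediction

    y = c + sum_j v_j * sigmoid(b_j + sum_i W_ji x_i)

with logistic hidden units and a linear output.  Training minimizes the mean
squared error against the behaviorally measured scores with resilient
backpropagation (RProp): a full-batch, gradient-sign-based scheme in which
every weight owns an adaptive step size that grows geometrically while the
gradient sign is stable and shrinks when it flips.  The variant here
suppresses the weight update on a sign flip (no backtracking).

Biases are included for hidden and output units: with whitened (zero-mean)
inputs a bias-free network is needlessly restricted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Raised when training produces non-finite parameters."""


@dataclass
class NetworkParams:
    """Weights and biases of an n_in -> n_hidden -> 1 perceptron."""

    input_hidden_weights: np.ndarray  # (n_hidden, n_in)
    hidden_biases: np.ndarray         # (n_hidden,)
    hidden_output_weights: np.ndarray # (n_hidden,)
    output_bias: float

    def __post_init__(self) -> None:
        W = np.asarray(self.input_hidden_weights, dtype=float)
        if W.ndim != 2:
            raise ValueError("input_hidden_weights must be 2-D")
        self.input_hidden_weights = W
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float).reshape(-1)
        self.hidden_output_weights = np.asarray(self.hidden_output_weights, dtype=float).reshape(-1)
        self.output_bias = float(self.output_bias)
        h, _ = W.shape
        if self.hidden_biases.shape != (h,) or self.hidden_output_weights.shape != (h,):
            raise ValueError("inconsistent parameter shapes")

    @property
    def n_in(self) -> int:
        return self.input_hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.input_hidden_weights.shape[0]

    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.input_hidden_weights).all()
            and np.isfinite(self.hidden_biases).all()
            and np.isfinite(self.hidden_output_weights).all()
            and np.isfinite(self.output_bias)
        )

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [
                self.input_hidden_weights.ravel(),
                self.hidden_biases,
                self.hidden_output_weights,
                [self.output_bias],
            ]
        )

    @classmethod
    def from_flat(cls, theta: np.ndarray, n_in: int, n_hidden: int) -> "NetworkParams":
        theta = np.asarray(theta, dtype=float)
        k = n_hidden * n_in
        return cls(
            input_hidden_weights=theta[:k].reshape(n_hidden, n_in).copy(),
            hidden_biases=theta[k : k + n_hidden].copy(),
            hidden_output_weights=theta[k + n_hidden : k + 2 * n_hidden].copy(),
            output_bias=float(theta[-1]),
        )

    def save(self, path: str | Path) -> None:
        """Flat key-value serialization (one ``name=value`` per line)."""
        lines = [f"n_in={self.n_in}", f"n_hidden={self.n_hidden}"]
        for i, v in enumerate(self.flatten()):
            lines.append(f"theta_{i}={float(v)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        kv = dict(
            line.split("=", 1)
            for line in Path(path).read_text().splitlines()
            if line.strip()
        )
        n_in, n_hidden = int(kv["n_in"]), int(kv["n_hidden"])
        n = n_hidden * (n_in + 2) + 1
        theta = np.array([float(kv[f"theta_{i}"]) for i in range(n)])
        return cls.from_flat(theta, n_in, n_hidden)


@dataclass(frozen=True)
class RPropConfig:
    """RProp trainer settings (canonical step-adaptation constants)."""

    cycles: int = 10_000
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_init: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    init_weight_range: tuple[float, float] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        if not (0.0 < self.eta_minus < 1.0 < self.eta_plus):
            raise ValueError("require 0 < eta_minus < 1 < eta_plus")
        if not (0.0 < self.delta_min <= self.delta_init <= self.delta_max):
            raise ValueError("require 0 < delta_min <= delta_init <= delta_max")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")


@dataclass(frozen=True)
class FitReport:
    initial_train_mse: float
    final_train_mse: float
    cycles_run: int


def init_network(
    n_in: int,
    n_hidden: int,
    rng: np.random.Generator,
    init_weight_range: tuple[float, float] = (-0.5, 0.5),
) -> NetworkParams:
    """Random network: all weights/biases i.i.d. uniform on ``init_weight_range``."""
    if n_in < 1 or n_hidden < 1:
        raise ValueError("n_in and n_hidden must be >= 1")
    lo, hi = init_weight_range
    theta = rng.uniform(lo, hi, size=n_hidden * (n_in + 2) + 1)
    return NetworkParams.from_flat(theta, n_in, n_hidden)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def forward(p: NetworkParams, x: np.ndarray) -> np.ndarray | float:
    """Network output for one feature vector or a batch (rows = samples)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != p.n_in:
        raise ValueError(f"expected {p.n_in} inputs, got {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    S = _sigmoid(X @ p.input_hidden_weights.T + p.hidden_biases)
    y = S @ p.hidden_output_weights + p.output_bias
    return float(y[0]) if single else y


def _mse_gradient(
    W: np.ndarray, b: np.ndarray, v: np.ndarray, c: float,
    X: np.ndarray, y: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, np.ndarray, float]:
    """Value and gradient of the mean squared error, full batch."""
    n = X.shape[0]
    S = _sigmoid(X @ W.T + b)
    pred = S @ v + c
    resid = pred - y
    err = float(resid @ resid) / n
    gy = (2.0 / n) * resid           # dE/dpred
    gv = S.T @ gy
    gc = float(gy.sum())
    back = np.outer(gy, v) * S * (1.0 - S)
    gW = back.T @ X
    gb = back.sum(axis=0)
    return err, gW, gb, gv, gc


def train_rprop(
    p: NetworkParams,
    X: np.ndarray,
    y_target: np.ndarray,
    cfg: RPropConfig | None = None,
) -> tuple[NetworkParams, FitReport]:
    """Full-batch RProp minimization of the training MSE.

    Runs for the fixed cycle budget (no early stopping).  Per-parameter step
    sizes start at ``delta_init``; on two consecutive gradients of equal sign
    the step is multiplied by ``eta_plus`` (capped at ``delta_max``), on a
    sign change it is multiplied by ``eta_minus`` (floored at ``delta_min``)
    and that parameter's update is suppressed for the cycle.  Parameters move
    against the gradient sign by their step size.
    """
    cfg = cfg or RPropConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_target, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y_target length")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("NaN or Inf in training data")

    W = p.input_hidden_weights.copy()
    b = p.hidden_biases.copy()
    v = p.hidden_output_weights.copy()
    c = p.output_bias
    n_in, n_hidden = p.n_in, p.n_hidden

    initial_mse, *_ = _err_only(W, b, v, c, X, y)
    if cfg.cycles == 0:
        return NetworkParams.from_flat(p.flatten(), n_in, n_hidden), FitReport(
            initial_mse, initial_mse, 0
        )

    n_par = n_hidden * (n_in + 2) + 1
    delta = np.full(n_par, cfg.delta_init)
    prev_g = np.zeros(n_par)
    theta = np.concatenate([W.ravel(), b, v, [c]])
    k = n_hidden * n_in
    final_err = initial_mse
    # overflow inside a diverging run is detected and raised below
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(cfg.cycles):
            W = theta[:k].reshape(n_hidden, n_in)
            b = theta[k : k + n_hidden]
            v = theta[k + n_hidden : k + 2 * n_hidden]
            c = theta[-1]
            err, gW, gb, gv, gc = _mse_gradient(W, b, v, c, X, y)
            final_err = err
            g = np.concatenate([gW.ravel(), gb, gv, [gc]])
            sign_prod = g * prev_g
            grow = sign_prod > 0
            shrink = sign_prod < 0
            delta[grow] = np.minimum(delta[grow] * cfg.eta_plus, cfg.delta_max)
            delta[shrink] = np.maximum(delta[shrink] * cfg.eta_minus, cfg.delta_min)
            g_eff = g.copy()
            g_eff[shrink] = 0.0  # suppress update on sign change
            theta = theta - np.sign(g_eff) * delta
            prev_g = g_eff
            if not np.isfinite(theta).all():
                raise TrainingDivergedError("non-finite parameters during RProp training")

    out = NetworkParams.from_flat(theta, n_in, n_hidden)
    final_err, *_ = _err_only(*_unpack(theta, n_in, n_hidden), X, y)
    return out, FitReport(initial_mse, final_err, cfg.cycles)


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int):
    k = n_hidden * n_in
    return (
        theta[:k].reshape(n_hidden, n_in),
        theta[k : k + n_hidden],
        theta[k + n_hidden : k + 2 * n_hidden],
        float(theta[-1]),
    )


def _err_only(W, b, v, c, X, y):
    S = _sigmoid(X @ W.T + b)
    resid = S @ v + c - y
    return (float(resid @ resid) / X.shape[0],)


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error."""
    pred = np.asarray(pred, dtype=float).reshape(-1)
    target = np.asarray(target, dtype=float).reshape(-1)
    if pred.shape != target.shape:
        raise ValueError("length mismatch")
    return float(np.mean((pred - target) ** 2))


def pearson_r(pred: np.ndarray, target: np.ndarray) -> float:
    """Linear (Pearson) correlation coefficient."""
    pred = np.asarray(pred, dtype=float).reshape(-1)
    target = np.asarray(target, dtype=float).reshape(-1)
    if pred.shape != target.shape or len(pred) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(pred) == 0 or np.ptp(target) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(pred, target)[0, 1])
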