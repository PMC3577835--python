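"""Synthetic behavioral datasets for the phonotaxis modelling pipeline.

The original trackball measurements (218 artificial song patterns, each
scored by several females) are not publicly deposited.  This module
generates datasets with the statistical structure that the downstream
analyses assume, so the whole pipeline can be exercised and its recovery
properties quantified:

* a smooth ground-truth attractiveness surface peaked at a pulse period of
  40 ms (duty cycle band 0.4-0.7) and a chirp period band of 250-500 ms
  (duty cycle band 0.3-0.7), with the two time scales fused either
  multiplicatively (AND-like, the default) or by a maximum (OR-like);
* per-pattern female panels with a right-skewed size distribution
  (mean 31, range 8-225) and inter-individual score noise;
* a default design of 218 patterns over the feature planes the analyses
  probe, calibrated so the mean-score composition approximates 35%
  unattractive (< 0.2), 48% intermediate, 17% attractive (> 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .song_features import (
    FEATURE_NAMES,
    SongPattern,
    complete_pattern,
    validate_pattern,
)

DATASET_COLUMNS: tuple[str, ...] = FEATURE_NAMES + ("mean_score", "score_sd", "n_females")


@dataclass(frozen=True)
class TuningConfig:
    """Ground-truth attractiveness surface.

    The pulse factor is a Gaussian in pulse period (sd ``pulse_period_width``,
    maximum at ``pulse_period_optimum``) times a smoothed top-hat band
    response in pulse duty cycle; the chirp factor is a band response in the
    chirp feature named by ``chirp_axis`` times one in chirp duty cycle.
    Bands are (lo, hi, flank) triples with raised-cosine flanks of the given
    width; a band set to ``None`` removes that dependency.  ``fusion_mode``
    combines the two factors as a product (AND-like) or a maximum (OR-like),
    and the combined response is mapped affinely onto
    [``floor_score``, ``peak_score``].
    """

    pulse_period_optimum: float = 40.0
    pulse_period_width: float = 8.0  # Gaussian sd; keeps f >= 0.5 on 35-45 ms
    pulse_dc_band: tuple[float, float, float] | None = (0.4, 0.7, 0.3)
    chirp_period_band: tuple[float, float, float] | None = (250.0, 500.0, 200.0)
    chirp_dc_band: tuple[float, float, float] | None = (0.3, 0.7, 0.3)
    peak_score: float = 0.9
    floor_score: float = 0.0
    fusion_mode: str = "product"
    chirp_axis: str = "chirp_period"

    def __post_init__(self) -> None:
        if self.fusion_mode not in ("product", "max"):
            raise ValueError(f"fusion_mode must be 'product' or 'max', got {self.fusion_mode!r}")
        if not (self.floor_score < self.peak_score):
            raise ValueError("peak_score must exceed floor_score")
        if not (-1.0 <= self.floor_score <= 0.0 and 0.0 < self.peak_score <= 1.0):
            raise ValueError("scores must satisfy floor in [-1,0], peak in (0,1]")
        if self.chirp_axis not in ("chirp_period", "chirp_pause"):
            raise ValueError("chirp_axis must be 'chirp_period' or 'chirp_pause'")
        for name in ("pulse_dc_band", "chirp_period_band", "chirp_dc_band"):
            band = getattr(self, name)
            if band is not None:
                lo, hi, flank = band
                if not (lo < hi and flank > 0):
                    raise ValueError(f"{name} must be (lo < hi, flank > 0), got {band}")


@dataclass(frozen=True)
class NoiseConfig:
    """Female-panel noise: panel-size distribution and per-female score sd."""

    female_sd: float = 0.2
    n_females_mean: float = 31.0
    n_females_range: tuple[int, int] = (8, 225)
    lognormal_sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.female_sd < 0:
            raise ValueError("female_sd must be >= 0")
        lo, hi = self.n_females_range
        if not (lo <= self.n_females_mean <= hi):
            raise ValueError("n_females_range must contain n_females_mean")


class BehavioralDataset:
    """Song patterns paired with mean phonotactic scores and panel statistics.

    Thin wrapper over a DataFrame with the canonical columns (eight features,
    ``mean_score``, ``score_sd``, ``n_females``).  Construction validates the
    feature-consistency invariants of every row.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        frame = frame.loc[:, list(DATASET_COLUMNS)].reset_index(drop=True)
        bad_rows = []
        for i, p in enumerate(_patterns_from_frame(frame)):
            problems = validate_pattern(p)
            if problems:
                bad_rows.append(f"row {i}: {'; '.join(problems)}")
        scores = frame["mean_score"].to_numpy()
        if np.any((scores < -1) | (scores > 1)):
            bad_rows.append("mean_score outside [-1, 1]")
        if bad_rows:
            raise ValueError("invalid dataset: " + " | ".join(bad_rows))
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["mean_score"].to_numpy(dtype=float)

    def patterns(self) -> list[SongPattern]:
        return _patterns_from_frame(self.frame)

    def feature_matrix(self, names: Sequence[str]) -> np.ndarray:
        return self.frame.loc[:, list(names)].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int]) -> "BehavioralDataset":
        return BehavioralDataset(self.frame.iloc[list(indices)])


def _patterns_from_frame(frame: pd.DataFrame) -> list[SongPattern]:
    return [
        SongPattern(**{name: float(row[name]) for name in FEATURE_NAMES})
        for _, row in frame.iterrows()
    ]


def _band_response(x: np.ndarray | float, band: tuple[float, float, float] | None):
    """Smoothed top-hat: 1 on [lo, hi], raised-cosine flanks of width ``flank``."""
    if band is None:
        return np.ones_like(np.asarray(x, dtype=float))
    lo, hi, w = band
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    below = x < lo
    above = x > hi
    out[below] = 0.5 * (1.0 + np.cos(np.pi * np.clip((lo - x[below]) / w, 0.0, 1.0)))
    out[above] = 0.5 * (1.0 + np.cos(np.pi * np.clip((x[above] - hi) / w, 0.0, 1.0)))
    return out


def pulse_factor(p: SongPattern, cfg: TuningConfig) -> float:
    """Short-time-scale attractiveness in [0, 1]."""
    g = np.exp(-0.5 * ((p.pulse_period - cfg.pulse_period_optimum) / cfg.pulse_period_width) ** 2)
    return float(g * _band_response(p.pulse_duty_cycle, cfg.pulse_dc_band))


def chirp_factor(p: SongPattern, cfg: TuningConfig) -> float:
    """Long-time-scale attractiveness in [0, 1]."""
    axis_value = p[cfg.chirp_axis]
    b = _band_response(axis_value, cfg.chirp_period_band)
    return float(b * _band_response(p.chirp_duty_cycle, cfg.chirp_dc_band))


def ground_truth_score(p: SongPattern, cfg: TuningConfig | None = None) -> float:
    """Noise-free phonotactic score of a pattern under the tuning config."""
    cfg = cfg or TuningConfig()
    f_p = pulse_factor(p, cfg)
    f_c = chirp_factor(p, cfg)
    fused = f_p * f_c if cfg.fusion_mode == "product" else max(f_p, f_c)
    return cfg.floor_score + (cfg.peak_score - cfg.floor_score) * fused


def draw_n_females(noise: NoiseConfig, rng: np.random.Generator, size: int | None = None):
    """Right-skewed panel sizes: rounded log-normal clipped to the printed range."""
    sigma = noise.lognormal_sigma
    # choose mu so the untruncated log-normal mean matches n_females_mean
    mu = np.log(noise.n_females_mean) - 0.5 * sigma**2
    draw = rng.lognormal(mean=mu, sigma=sigma, size=size)
    lo, hi = noise.n_females_range
    return np.clip(np.rint(draw), lo, hi).astype(int)


def simulate_female_scores(
    p: SongPattern,
    cfg: TuningConfig,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-female scores: ground truth + N(0, female_sd) noise, clipped to [-1, 1]."""
    gt = ground_truth_score(p, cfg)
    n = int(draw_n_females(noise, rng))
    return np.clip(gt + rng.normal(0.0, noise.female_sd, size=n), -1.0, 1.0)


# ---------------------------------------------------------------------------
# Pattern designs


def default_design() -> list[SongPattern]:
    """The default placement of 218 patterns.

    Mirrors the planes the analyses probe: a pulse duration x pause grid at an
    attractive chirp (200/333 ms), a chirp duration x pause grid at an
    attractive pulse (20/20 ms), a period x period grid at duty cycles 0.5,
    and off-optimum probe patterns.  Grid placement was calibrated once so
    that, with the default tuning and noise configs, the mean-score class
    composition approximates 35% / 48% / 17%.
    """
    patterns: list[SongPattern] = []
    # pulse duration x pause plane at a fixed attractive chirp (49 points)
    for pdur in (8.0, 11.0, 15.0, 18.0, 20.0, 33.0, 35.0):
        for ppau in (8.0, 11.0, 15.0, 18.0, 20.0, 33.0, 35.0):
            patterns.append(
                complete_pattern(
                    pulse_duration=pdur, pulse_pause=ppau,
                    chirp_duration=200.0, chirp_period=333.0,
                )
            )
    # chirp duration x pause plane at a fixed attractive pulse (49 points)
    for cdur in (50.0, 100.0, 260.0, 290.0, 440.0, 710.0, 980.0):
        for cpau in (50.0, 100.0, 260.0, 290.0, 440.0, 710.0, 980.0):
            patterns.append(
                complete_pattern(
                    pulse_duration=20.0, pulse_pause=20.0,
                    chirp_duration=cdur, chirp_pause=cpau,
                )
            )
    # pulse period x chirp period plane at duty cycles 0.5 (56 points)
    for pper in (30.0, 33.0, 41.0, 45.0, 49.0, 53.0, 65.0, 107.0):
        for cper in (170.0, 200.0, 340.0, 400.0, 430.0, 570.0, 680.0):
            patterns.append(
                complete_pattern(
                    pulse_period=pper, pulse_duty_cycle=0.5,
                    chirp_period=cper, chirp_duty_cycle=0.5,
                )
            )
    # far off-optimum scale probes (6 points)
    for pper in (100.0, 150.0, 200.0):
        patterns.append(
            complete_pattern(
                pulse_period=pper, pulse_duty_cycle=0.5,
                chirp_duration=200.0, chirp_period=333.0,
            )
        )
    for cper in (1000.0, 1500.0, 2000.0):
        patterns.append(
            complete_pattern(
                pulse_duration=20.0, pulse_pause=20.0,
                chirp_period=cper, chirp_duty_cycle=0.5,
            )
        )
    # pulse-period flank probes at an attractive chirp (10 points)
    for pper in (27.2, 28.5, 29.7, 30.7, 31.8, 48.2, 49.3, 50.3, 51.5, 52.8):
        patterns.append(
            complete_pattern(
                pulse_period=pper, pulse_duty_cycle=0.5,
                chirp_duration=200.0, chirp_period=333.0,
            )
        )
    # chirp-period flank probes at an attractive pulse (10 points)
    for cper in (121.0, 131.0, 141.0, 151.0, 161.0, 589.0, 599.0, 609.0, 619.0, 629.0):
        patterns.append(
            complete_pattern(
                pulse_duration=20.0, pulse_pause=20.0,
                chirp_period=cper, chirp_duty_cycle=0.6,
            )
        )
    # pulse duty-cycle flank probes (10 points)
    for pdc in (0.206, 0.222, 0.237, 0.252, 0.267, 0.833, 0.848, 0.863, 0.878, 0.894):
        patterns.append(
            complete_pattern(
                pulse_period=40.0, pulse_duty_cycle=pdc,
                chirp_duration=200.0, chirp_period=333.0,
            )
        )
    # chirp duty-cycle flank probes (10 points)
    for cdc in (0.106, 0.122, 0.137, 0.152, 0.167, 0.833, 0.848, 0.863, 0.878, 0.894):
        patterns.append(
            complete_pattern(
                pulse_period=40.0, pulse_duty_cycle=0.5,
                chirp_period=340.0, chirp_duty_cycle=cdc,
            )
        )
    # mildly detuned period x period ring (16 points)
    for pper in (32.0, 34.0, 46.0, 48.0):
        for cper in (180.0, 210.0, 540.0, 580.0):
            patterns.append(
                complete_pattern(
                    pulse_period=pper, pulse_duty_cycle=0.5,
                    chirp_period=cper, chirp_duty_cycle=0.5,
                )
            )
    # fully attractive reference patterns (2 points)
    for pper, cper in ((40.0, 340.0), (42.0, 380.0)):
        patterns.append(
            complete_pattern(
                pulse_period=pper, pulse_duty_cycle=0.55,
                chirp_period=cper, chirp_duty_cycle=0.6,
            )
        )
    return patterns


def random_design(
    n_patterns: int,
    rng: np.random.Generator,
    pulse_duration_range: tuple[float, float] = (5.0, 60.0),
    pulse_pause_range: tuple[float, float] = (0.5, 60.0),
    chirp_duration_range: tuple[float, float] = (50.0, 600.0),
    chirp_pause_range: tuple[float, float] = (20.0, 600.0),
) -> list[SongPattern]:
    """Uniformly random patterns; every feature varies (useful for recovery tests)."""
    return [
        complete_pattern(
            pulse_duration=rng.uniform(*pulse_duration_range),
            pulse_pause=rng.uniform(*pulse_pause_range),
            chirp_duration=rng.uniform(*chirp_duration_range),
            chirp_pause=rng.uniform(*chirp_pause_range),
        )
        for _ in range(n_patterns)
    ]


def generate_dataset(
    n_patterns: int = 218,
    design: Sequence[SongPattern] | None = None,
    cfg: TuningConfig | None = None,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> BehavioralDataset:
    """Generate a behavioral dataset: patterns, female panels, score statistics.

    ``design`` defaults to :func:`default_design`.  If the design provides
    more than ``n_patterns`` distinct patterns, a random subset is taken;
    fewer is an error.  Fully reproducible given (configs, seed).
    """
    cfg = cfg or TuningConfig()
    noise = noise or NoiseConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    design = list(design) if design is not None else default_design()
    distinct = {tuple(round(v, 9) for v in p.as_dict().values()) for p in design}
    if len(distinct) < n_patterns:
        raise ValueError(
            f"design yields {len(distinct)} distinct patterns, fewer than n_patterns={n_patterns}"
        )
    if len(design) > n_patterns:
        keep = rng.choice(len(design), size=n_patterns, replace=False)
        design = [design[i] for i in sorted(keep)]

    rows = []
    for p in design:
        scores = simulate_female_scores(p, cfg, noise, rng)
        row = p.as_dict()
        row["mean_score"] = float(np.clip(scores.mean(), -1.0, 1.0))
        row["score_sd"] = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
        row["n_females"] = len(scores)
        rows.append(row)
    return BehavioralDataset(pd.DataFrame(rows))
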