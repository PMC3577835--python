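"""Temporal descriptors of an artificial cricket calling song.

A calling song of *Gryllus bimaculatus* is an amplitude-modulated tone whose
envelope is fully determined by four independent parameters: duration and
pause on the short (pulse) and on the long (chirp) time scale.  Four further
descriptors are conventional in the field and redundant with those: the
period (duration + pause) and the duty cycle (duration / period) of each
time scale.  This module defines the canonical eight-feature schema, pattern
completion from any non-redundant 2+2 parameterization, validation, and
vectorization into model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical feature names, fixed order.  Abbreviations in figures/tables:
#: Pdur, Ppau, Pper, Pdc, Cdur, Cpau, Cper, Cdc.
FEATURE_NAMES: tuple[str, ...] = (
    "pulse_duration",
    "pulse_pause",
    "pulse_period",
    "pulse_duty_cycle",
    "chirp_duration",
    "chirp_pause",
    "chirp_period",
    "chirp_duty_cycle",
)

_SCALES = {"pulse": FEATURE_NAMES[:4], "chirp": FEATURE_NAMES[4:]}

_REL_TOL = 1e-9


class PatternError(ValueError):
    """Raised for inconsistent, redundant, or out-of-range song parameters."""


@dataclass(frozen=True)
class SongPattern:
    """One artificial calling song described by all eight temporal features.

    Durations, pauses and periods are in milliseconds; duty cycles are
    dimensionless ratios in (0, 1].  The eight values are redundant: on each
    time scale ``period = duration + pause`` and
    ``duty_cycle = duration / period``.
    """

    pulse_duration: float
    pulse_pause: float
    pulse_period: float
    pulse_duty_cycle: float
    chirp_duration: float
    chirp_pause: float
    chirp_period: float
    chirp_duty_cycle: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def __getitem__(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class FeatureSet:
    """An ordered selection of canonical feature names, no duplicates."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("feature set must be non-empty")
        unknown = [n for n in names if n not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature names: {unknown}")
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


def _close(a: float, b: float, rel: float = _REL_TOL) -> bool:
    return abs(a - b) <= rel * max(1.0, abs(a), abs(b))


def _complete_scale(scale: str, given: Mapping[str, float]) -> dict[str, float]:
    """Solve duration/pause/period/duty-cycle on one time scale from two of them."""
    prefix = scale + "_"
    vals = {}
    for key, v in given.items():
        short = key.removeprefix(prefix)
        if short not in ("duration", "pause", "period", "duty_cycle"):
            raise PatternError(f"unknown {scale} descriptor {key!r}")
        vals[short] = float(v)
    if len(vals) != 2:
        raise PatternError(f"exactly two {scale} descriptors required, got {sorted(vals)}")

    dur = vals.get("duration")
    pau = vals.get("pause")
    per = vals.get("period")
    dc = vals.get("duty_cycle")

    if dc is not None and not (0.0 < dc <= 1.0):
        raise PatternError(f"{scale} duty cycle {dc} outside (0, 1]")

    if dur is not None and pau is not None:
        per = dur + pau
    elif dur is not None and per is not None:
        pau = per - dur
    elif dur is not None and dc is not None:
        per = dur / dc
        pau = per - dur
    elif pau is not None and per is not None:
        dur = per - pau
    elif pau is not None and dc is not None:
        if dc == 1.0:
            if pau != 0.0:
                raise PatternError(f"{scale}: duty cycle 1 requires zero pause")
            raise PatternError(f"{scale}: pause 0 with duty cycle 1 leaves the period free (redundant pair)")
        per = pau / (1.0 - dc)
        dur = per - pau
    else:  # per and dc
        dur = per * dc
        pau = per - dur
    assert dur is not None and pau is not None and per is not None

    if dur <= 0:
        raise PatternError(f"{scale} duration {dur:g} must be positive")
    if pau < 0:
        raise PatternError(f"{scale} pause {pau:g} must be non-negative")
    if per <= 0:
        raise PatternError(f"{scale} period {per:g} must be positive")
    dc = dur / per
    return {
        prefix + "duration": dur,
        prefix + "pause": pau,
        prefix + "period": per,
        prefix + "duty_cycle": dc,
    }


def complete_pattern(**given: float) -> SongPattern:
    """Build a full :class:`SongPattern` from a non-redundant 2+2 parameterization.

    Exactly two pulse descriptors and two chirp descriptors must be given by
    canonical name, e.g. ``complete_pattern(pulse_duration=20, pulse_pause=20,
    chirp_duration=200, chirp_period=333)``.  The remaining features are
    derived from the algebraic identities; the given values are reproduced
    exactly in the result.

    Raises
    ------
    PatternError
        If a pair is redundant or implies a non-positive duration, a negative
        pause, or a duty cycle outside (0, 1].
    """
    pulse = {k: v for k, v in given.items() if k.startswith("pulse_")}
    chirp = {k: v for k, v in given.items() if k.startswith("chirp_")}
    extra = set(given) - set(pulse) - set(chirp)
    if extra:
        raise PatternError(f"unknown parameters: {sorted(extra)}")
    out = _complete_scale("pulse", pulse)
    out.update(_complete_scale("chirp", chirp))
    return SongPattern(**out)


def validate_pattern(p: SongPattern) -> list[str]:
    """Return a list of human-readable invariant violations (empty if consistent).

    A zero pulse pause (a continuous tone within the chirp) is legal but
    reported as an advisory-free boundary case; only genuine violations are
    listed.
    """
    problems: list[str] = []
    for scale in ("pulse", "chirp"):
        dur = p[f"{scale}_duration"]
        pau = p[f"{scale}_pause"]
        per = p[f"{scale}_period"]
        dc = p[f"{scale}_duty_cycle"]
        if not np.isfinite([dur, pau, per, dc]).all():
            problems.append(f"{scale}: non-finite value")
            continue
        if dur <= 0:
            problems.append(f"{scale} duration {dur:g} not > 0")
        if pau < 0:
            problems.append(f"{scale} pause {pau:g} negative")
        if not (0.0 < dc <= 1.0):
            problems.append(f"{scale} duty cycle {dc:g} outside (0, 1]")
        if not _close(per, dur + pau):
            problems.append(f"{scale} period {per:g} != duration + pause = {dur + pau:g}")
        if per > 0 and not _close(dc, dur / per):
            problems.append(f"{scale} duty cycle {dc:g} != duration / period = {dur / per:g}")
    return problems


def vectorize(p: SongPattern, fs: FeatureSet | Sequence[str]) -> np.ndarray:
    """Extract the features named in ``fs`` from ``p``, in order."""
    if not isinstance(fs, FeatureSet):
        fs = FeatureSet(tuple(fs))
    problems = validate_pattern(p)
    if problems:
        raise PatternError("; ".join(problems))
    return np.array([p[name] for name in fs], dtype=float)


def vectorize_many(patterns: Iterable[SongPattern], fs: FeatureSet | Sequence[str]) -> np.ndarray:
    """Stack :func:`vectorize` over patterns into an (n, len(fs)) matrix."""
    return np.array([vectorize(p, fs) for p in patterns], dtype=float)
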