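"""Dataset/config I/O and seeded end-to-end pipeline orchestration.

A single YAML config drives a full run (generate -> split -> search ->
evaluate -> fields -> calibrate); every stochastic stage receives a child
seed spawned from the master seed, so runs are bit-reproducible.  Datasets
travel as CSV with the canonical column schema: the eight feature columns,
``mean_score``, ``score_sd`` and ``n_females``.  Feature columns that are
derivable (period, duty cycle) may be omitted; they are completed on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import network as nw
from .preprocessing import classify_scores, stratified_split
from .response_analysis import (
    build_ensemble,
    evaluate,
    fit_calibration,
    fusion_index,
    predict,
    response_field,
)
from .selection import ModelSpec, SearchBudget, search
from .song_features import FEATURE_NAMES, FeatureSet, complete_pattern
from .synthetic_data import (
    BehavioralDataset,
    NoiseConfig,
    TuningConfig,
    generate_dataset,
)

logger = logging.getLogger("phonotaxnet")

_PAIRS = {
    "pulse": ("pulse_duration", "pulse_pause", "pulse_period", "pulse_duty_cycle"),
    "chirp": ("chirp_duration", "chirp_pause", "chirp_period", "chirp_duty_cycle"),
}


def write_dataset(ds: BehavioralDataset, path: str | Path) -> None:
    ds.frame.to_csv(path, index=False)


def read_dataset(path: str | Path) -> BehavioralDataset:
    """Read a dataset CSV, completing derivable feature columns if absent.

    Each time scale needs at least two non-redundant descriptors; rows whose
    stated features violate the consistency invariants are reported with
    their row index (via :class:`BehavioralDataset` validation).
    """
    frame = pd.read_csv(path)
    for col in ("mean_score", "score_sd", "n_females"):
        if col not in frame.columns:
            raise ValueError(f"dataset missing column {col!r}")
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        for scale, names in _PAIRS.items():
            present = [n for n in names if n in frame.columns]
            if len(present) < 2:
                raise ValueError(
                    f"cannot complete {scale} features from columns {present}"
                )
        logger.info("completing missing feature columns on read: %s", missing)
        completed = []
        for idx, row in frame.iterrows():
            given = {}
            for scale, names in _PAIRS.items():
                present = [n for n in names if n in frame.columns][:2]
                given.update({n: float(row[n]) for n in present})
            try:
                completed.append(complete_pattern(**given).as_dict())
            except Exception as exc:
                raise ValueError(f"row {idx}: {exc}") from exc
        feat = pd.DataFrame(completed)
        for c in FEATURE_NAMES:
            if c not in frame.columns:
                frame[c] = feat[c]
    return BehavioralDataset(frame)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with desk-scale defaults.

    The full study settings are k=5, repeats=100, cycles=10000, 100 ensemble
    members; the defaults here keep a complete run in the minutes range.
    """

    tuning: TuningConfig = field(default_factory=TuningConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_patterns: int = 218
    n_test: int = 18
    unattractive_below: float = 0.2
    attractive_above: float = 0.6
    rprop: nw.RPropConfig = field(default_factory=lambda: nw.RPropConfig(cycles=2000))
    budget: SearchBudget = field(default_factory=lambda: SearchBudget(repeats=1, cycles=300, n_max=2))
    n_members: int = 20
    field_features: tuple[str, ...] = (
        "pulse_duration", "pulse_pause", "chirp_duration", "chirp_period"
    )
    field_n_hidden: int = 4
    pulse_period_grid: tuple[float, float, float] = (10.0, 80.0, 2.5)   # start, stop, step
    chirp_period_grid: tuple[float, float, float] = (50.0, 900.0, 10.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.unattractive_below < self.attractive_above:
            raise ValueError("class thresholds out of order")
        if not 0 <= self.n_test < self.n_patterns:
            raise ValueError("need 0 <= n_test < n_patterns")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key, sub in (("tuning", TuningConfig), ("noise", NoiseConfig),
                         ("rprop", nw.RPropConfig), ("budget", SearchBudget)):
            if key in d and isinstance(d[key], dict):
                sub_d = d[key]
                for k, v in sub_d.items():
                    if isinstance(v, list):
                        sub_d[k] = tuple(v)
                d[key] = sub(**sub_d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    package_version: str
    outputs: dict[str, str]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _grid(spec: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = spec
    return np.arange(start, stop + step / 2, step)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute generate -> split -> search -> evaluate -> fields -> calibrate.

    Each stage draws its own child seed from the master seed; outputs are
    written under ``outdir`` and listed in the returned manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.master_seed)
    stage_names = ("generate", "split", "search", "evaluate", "fields", "calibrate")
    children = ss.spawn(len(stage_names))
    seeds = {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(stage_names, children)}
    outputs: dict[str, str] = {}

    logger.info("stage generate (seed %d)", seeds["generate"])
    ds = generate_dataset(
        cfg.n_patterns, cfg=cfg.tuning, noise=cfg.noise,
        rng=np.random.default_rng(seeds["generate"]),
    )
    write_dataset(ds, outdir / "dataset.csv")
    outputs["dataset"] = str(outdir / "dataset.csv")

    logger.info("stage split (seed %d)", seeds["split"])
    labels = classify_scores(ds.scores)
    split = stratified_split(labels, cfg.n_test, np.random.default_rng(seeds["split"]))
    pd.DataFrame({
        "index": np.concatenate([split.train_indices, split.test_indices]),
        "role": ["train"] * len(split.train_indices) + ["test"] * len(split.test_indices),
    }).to_csv(outdir / "split.csv", index=False)
    outputs["split"] = str(outdir / "split.csv")
    train = ds.subset(split.train_indices)
    test = ds.subset(split.test_indices)

    logger.info("stage search (seed %d)", seeds["search"])
    ranking = search(train, budget=cfg.budget, rng=np.random.default_rng(seeds["search"]),
                     rprop=cfg.rprop)
    pd.DataFrame([
        {
            "rank": e.rank,
            "features": "+".join(e.spec.feature_set.names),
            "n_hidden": e.spec.n_hidden,
            "mse_val_mean": e.cv.mse_val_mean if e.cv else np.nan,
            "mse_val_sd": e.cv.mse_val_sd if e.cv else np.nan,
            "failed": e.failed,
        }
        for e in ranking
    ]).to_csv(outdir / "ranking.csv", index=False)
    outputs["ranking"] = str(outdir / "ranking.csv")

    logger.info("stage evaluate (seed %d)", seeds["evaluate"])
    spec = ModelSpec(FeatureSet(cfg.field_features), cfg.field_n_hidden)
    report = evaluate(train, test, spec, n_members=cfg.n_members, rprop=cfg.rprop,
                      rng=np.random.default_rng(seeds["evaluate"]))
    perf = {
        "mse_test": report.mse_test,
        "pearson_r": report.pearson_r,
        "regression_slope": report.regression_slope,
    }
    (outdir / "performance.json").write_text(json.dumps(perf, indent=2) + "\n")
    outputs["performance"] = str(outdir / "performance.json")

    logger.info("stage fields (seed %d)", seeds["fields"])
    ens = build_ensemble(ds, spec, n_members=cfg.n_members, rprop=cfg.rprop,
                         rng=np.random.default_rng(seeds["fields"]))
    fld = response_field(
        ens, ("pulse_period", "chirp_period"),
        (_grid(cfg.pulse_period_grid), _grid(cfg.chirp_period_grid)),
        {"pulse_duty_cycle": 0.5, "chirp_duty_cycle": 0.5},
    )
    rows = []
    for i, a in enumerate(fld.axis_grids[0]):
        for j, b in enumerate(fld.axis_grids[1]):
            rows.append({"pulse_period": a, "chirp_period": b,
                         "mean": fld.mean_scores[i, j], "sd": fld.sd_scores[i, j]})
    pd.DataFrame(rows).to_csv(outdir / "period_field.csv", index=False)
    outputs["period_field"] = str(outdir / "period_field.csv")
    fi = fusion_index(ens)
    (outdir / "fusion_index.json").write_text(json.dumps(asdict(fi), indent=2) + "\n")
    outputs["fusion_index"] = str(outdir / "fusion_index.json")

    logger.info("stage calibrate (seed %d)", seeds["calibrate"])
    train_ens = build_ensemble(train, spec, n_members=cfg.n_members, rprop=cfg.rprop,
                               rng=np.random.default_rng(seeds["calibrate"]))
    train_pred, _ = predict(train_ens, train.patterns())
    calib = fit_calibration(train_pred, train.scores)
    test_pred, _ = predict(train_ens, test.patterns())
    from .response_analysis import apply_calibration
    calib_out = {
        "slope": calib.slope,
        "midpoint": calib.midpoint,
        "identity_fallback": calib.identity_fallback,
        "train_mse_raw": nw.mse(train_pred, train.scores),
        "train_mse_calibrated": nw.mse(apply_calibration(calib, train_pred), train.scores),
        "test_mse_raw": nw.mse(test_pred, test.scores),
        "test_mse_calibrated": nw.mse(apply_calibration(calib, test_pred), test.scores),
    }
    (outdir / "calibration.json").write_text(json.dumps(calib_out, indent=2) + "\n")
    outputs["calibration"] = str(outdir / "calibration.json")

    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        master_seed=cfg.master_seed,
        stage_seeds=seeds,
        package_version=__version__,
        outputs=outputs,
    )
    manifest.save(outdir / "manifest.json")
    return manifest
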