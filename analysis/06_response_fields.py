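#!/usr/bin/env python
"""Pulse and chirp response fields of the 4-feature and 2-feature models.

Trains ensembles on all 218 patterns and evaluates:
  * the pulse field (pulse duration x pulse pause) of the 4-feature model at
    a fixed attractive chirp (duration 200 ms, period 333 ms);
  * the chirp field (chirp duration x chirp period) of the 4-feature model
    at a fixed attractive pulse (duration 20 ms, pause 20 ms);
  * the pulse field of the 2-feature model {pulse period, chirp pause} at a
    fixed chirp (duration 200 ms, pause 133 ms) — expected to be constant
    along diagonals of equal pulse period (no duty-cycle information).
Writes results/pulse_field_4f.csv, chirp_field_4f.csv, pulse_field_2f.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phonotaxnet import network as nw
from phonotaxnet.response_analysis import build_ensemble, response_field
from phonotaxnet.selection import ModelSpec
from phonotaxnet.song_features import FeatureSet
from phonotaxnet.synthetic_data import generate_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
FOUR = FeatureSet(("pulse_duration", "pulse_pause", "chirp_duration", "chirp_period"))
TWO = FeatureSet(("pulse_period", "chirp_pause"))


def dump(fld, path):
    f1, f2 = fld.axis_features
    rows = [
        {f1: a, f2: b, "mean": fld.mean_scores[i, j], "sd": fld.sd_scores[i, j]}
        for i, a in enumerate(fld.axis_grids[0])
        for j, b in enumerate(fld.axis_grids[1])
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(SEED).spawn(3)
    ds = generate_dataset(218, rng=np.random.default_rng(ss[0]))
    rprop = nw.RPropConfig(cycles=2000)

    ens4 = build_ensemble(ds, ModelSpec(FOUR, 4), n_members=10, rprop=rprop,
                          rng=np.random.default_rng(ss[1]))
    pulse_axes = (np.arange(5.0, 45.1, 2.5), np.arange(5.0, 45.1, 2.5))
    fld = response_field(ens4, ("pulse_duration", "pulse_pause"), pulse_axes,
                         {"chirp_duration": 200.0, "chirp_period": 333.0})
    dump(fld, OUT / "pulse_field_4f.csv")
    print(f"4-feature pulse field maximum at (duration, pause) = "
          f"{fld.argmax_coordinates()}")

    fld = response_field(
        ens4, ("chirp_duration", "chirp_period"),
        (np.arange(50.0, 500.1, 25.0), np.arange(100.0, 900.1, 25.0)),
        {"pulse_duration": 20.0, "pulse_pause": 20.0},
    )
    dump(fld, OUT / "chirp_field_4f.csv")
    print(f"4-feature chirp field maximum at (duration, period) = "
          f"{fld.argmax_coordinates()}")

    ens2 = build_ensemble(ds, ModelSpec(TWO, 2), n_members=10, rprop=rprop,
                          rng=np.random.default_rng(ss[2]))
    fld = response_field(ens2, ("pulse_duration", "pulse_pause"), pulse_axes,
                         {"chirp_duration": 200.0, "chirp_pause": 133.0})
    dump(fld, OUT / "pulse_field_2f.csv")
    d, p = fld.argmax_coordinates()
    print(f"2-feature pulse field maximum on the diagonal pulse period = {d + p:g} ms")
    print(f"-> {OUT}/pulse_field_4f.csv, chirp_field_4f.csv, pulse_field_2f.csv")


if __name__ == "__main__":
    main()
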