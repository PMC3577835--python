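#!/usr/bin/env python
"""Choose the hidden-layer size for the 4-feature model with the 1% rule.

Cross-validates networks with 1..10 hidden units on the 200-pattern training
split (stratified 5-fold CV, reduced to 5 repeats x 2000 cycles) and applies
the 1% rule: the selected n is the smallest whose successor improves the
validation error by no more than 1% of the 1-unit error.  Writes
results/hidden_units.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phonotaxnet import network as nw
from phonotaxnet.preprocessing import classify_scores, stratified_split
from phonotaxnet.selection import ModelSpec, cross_validate, select_n_hidden
from phonotaxnet.song_features import FeatureSet
from phonotaxnet.synthetic_data import generate_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
FOUR = FeatureSet(("pulse_duration", "pulse_pause", "chirp_duration", "chirp_period"))
N_MAX = 10


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(SEED).spawn(3)
    ds = generate_dataset(218, rng=np.random.default_rng(ss[0]))
    split = stratified_split(classify_scores(ds.scores), 18, np.random.default_rng(ss[1]))
    train = ds.subset(split.train_indices)

    rng = np.random.default_rng(ss[2])
    rows = []
    errors = {}
    for n in range(1, N_MAX + 1):
        cv = cross_validate(ModelSpec(FOUR, n), train, k=5, repeats=5,
                            rprop=nw.RPropConfig(cycles=2000), rng=rng)
        errors[n] = cv.mse_val_mean
        rows.append({
            "n_hidden": n,
            "mse_val_mean": cv.mse_val_mean,
            "mse_val_sd": cv.mse_val_sd,
            "mse_train_mean": cv.mse_train_mean,
        })
        print(f"n={n}: validation MSE {cv.mse_val_mean:.4f} +- {cv.mse_val_sd:.4f}")

    selected, capped = select_n_hidden(errors)
    pd.DataFrame(rows).to_csv(OUT / "hidden_units.csv", index=False)
    note = " (capped at scan maximum)" if capped else ""
    print(f"1% rule selects n = {selected}{note} -> {OUT / 'hidden_units.csv'}")


if __name__ == "__main__":
    main()
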