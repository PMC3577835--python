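#!/usr/bin/env python
"""Held-out performance of the 4-feature model on the 18-pattern test split.

Trains a 20-member ensemble on the 200 training patterns (whitened features,
2000 RProp cycles per member), averages predictions on the 18 held-out
patterns, and reports test MSE, Pearson r, and the regression slope of
observed on predicted scores.  Writes results/performance.json and the
per-pattern predictions to results/test_predictions.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from phonotaxnet import network as nw
from phonotaxnet.preprocessing import classify_scores, stratified_split
from phonotaxnet.response_analysis import evaluate
from phonotaxnet.selection import ModelSpec
from phonotaxnet.song_features import FeatureSet
from phonotaxnet.synthetic_data import generate_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
FOUR = FeatureSet(("pulse_duration", "pulse_pause", "chirp_duration", "chirp_period"))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(SEED).spawn(3)
    ds = generate_dataset(218, rng=np.random.default_rng(ss[0]))
    split = stratified_split(classify_scores(ds.scores), 18, np.random.default_rng(ss[1]))
    train, test = ds.subset(split.train_indices), ds.subset(split.test_indices)

    report = evaluate(train, test, ModelSpec(FOUR, 4), n_members=20,
                      rprop=nw.RPropConfig(cycles=2000),
                      rng=np.random.default_rng(ss[2]))
    summary = {
        "mse_test": report.mse_test,
        "pearson_r": report.pearson_r,
        "regression_slope": report.regression_slope,
        "n_train": len(train),
        "n_test": len(test),
        "n_members": 20,
    }
    (OUT / "performance.json").write_text(json.dumps(summary, indent=2) + "\n")
    pd.DataFrame({
        "observed": test.scores,
        "predicted_mean": report.pred_mean,
        "predicted_sd": report.pred_sd,
        "female_sd": test.frame["score_sd"],
    }).to_csv(OUT / "test_predictions.csv", index=False)
    print(f"test MSE {report.mse_test:.4f}, Pearson r {report.pearson_r:.3f}, "
          f"slope {report.regression_slope:.2f} -> {OUT / 'performance.json'}")


if __name__ == "__main__":
    main()
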