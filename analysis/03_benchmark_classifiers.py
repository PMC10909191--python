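#!/usr/bin/env python
"""Run the six-classifier benchmark grid on the extracted features.

Trains KNN, LDA, RBF-SVM, random forest, AdaBoost and gradient boosting on
every combination of feature family (DWT/PSD) × labeling scheme
(SAM/HAM-A) × SMOTE (on/off) — 48 cells — with a stratified 80/20 holdout,
and writes the tidy metric table to results/benchmark.csv plus the
best-per-condition summary to results/benchmark_summary.json.

Requires analysis/02_extract_features.py to have run first.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from anxeeg.features import LabeledFeatureTable
from anxeeg.models import run_comparison
from anxeeg.pipeline import reports_to_frame

ROOT = Path(__file__).resolve().parents[1]
PROV = ["subject_id", "trial_id", "epoch_index", "synthetic"]
LABEL_COLS = ["sam_anxious", "hama_anxious"]


def load_table(method: str) -> tuple[LabeledFeatureTable, np.ndarray, np.ndarray]:
    path = ROOT / "scratch" / f"features_{method}.csv"
    if not path.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    df = pd.read_csv(path)
    table = LabeledFeatureTable(
        features=df.drop(columns=PROV + LABEL_COLS),
        labels=df["hama_anxious"].to_numpy(bool),
        provenance=df[PROV],
    )
    return table, df["sam_anxious"].to_numpy(bool), df["hama_anxious"].to_numpy(bool)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table_dwt, sam, hama = load_table("dwt")
    table_psd, _, _ = load_table("psd")

    records = run_comparison(table_dwt, table_psd, sam, hama, seed=args.seed)
    frame = reports_to_frame(records)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    frame.to_csv(results / "benchmark.csv", index=False)

    summary = {}
    for (features, labeling, smote_on), group in frame.groupby(["features", "labeling", "smote"]):
        best = group.loc[group["accuracy"].idxmax()]
        key = f"{features}/{labeling}/{'smote' if smote_on else 'raw'}"
        summary[key] = {
            "best_classifier": best["classifier"],
            "accuracy": round(float(best["accuracy"]), 4),
            "auc": None if pd.isna(best["auc"]) else round(float(best["auc"]), 4),
            "kappa": round(float(best["kappa"]), 4),
        }
        print(
            f"{key:18s} best={best['classifier']:14s} "
            f"acc={best['accuracy']:.3f} kappa={best['kappa']:.3f}"
        )
    (results / "benchmark_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    print(f"\nwrote {len(frame)} grid cells to results/benchmark.csv")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
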