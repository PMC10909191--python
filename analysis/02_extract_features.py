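#!/usr/bin/env python
"""Preprocess the cohort and extract both feature families.

Band-pass 4–45 Hz, keep the 10 anxiety-related channels, cut 1-s epochs,
then extract the 608-column wavelet table (600 DWT statistics + 8 affect
features) and the 68-column spectral table (60 band powers + 8 affect
features), each with SAM and HAM-A epoch labels attached. Tables go to
scratch/ (one row per epoch); a shape/label summary goes to results/.

Requires analysis/01_simulate_cohort.py to have run first.
"""

import argparse
import json
from pathlib import Path

from anxeeg.features import extract_features
from anxeeg.io import read_recording
from anxeeg.labeling import label_dataset
from anxeeg.pipeline import PipelineConfig, preprocess_dataset
from anxeeg.simulate import SimulatedDataset, SimulationConfig, SubjectAnnotation

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def load_cohort():
    cohort_dir = ROOT / "scratch" / "cohort"
    if not cohort_dir.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first (scratch/cohort/ missing)")
    recordings = []
    for path in sorted(cohort_dir.glob("S*_trial*.csv")):
        subject_id, _, trial = path.stem.partition("_trial")
        recordings.append(read_recording(path, subject_id=subject_id, trial_id=trial))
    annotations_df = pd.read_csv(ROOT / "results" / "cohort_annotations.csv")
    annotations, flags = [], []
    for subject_id, group in annotations_df.groupby("subject_id"):
        group = group.sort_values("trial")
        annotations.append(
            SubjectAnnotation(
                subject_id=str(subject_id),
                hama_score=int(group["hama_score"].iloc[0]),
                sam_ratings=tuple((int(r.valence), int(r.arousal)) for r in group.itertuples()),
            )
        )
        flags.append(bool(group["anxious_truth"].iloc[0]))
    summary = json.loads((ROOT / "results" / "cohort_summary.json").read_text())
    config = SimulationConfig(
        n_subjects=summary["n_subjects"],
        trial_seconds=summary["trial_seconds"],
        effect_size=summary["effect_size"],
        seed=summary["seed"],
    )
    return SimulatedDataset(config, recordings, annotations, tuple(flags))


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    dataset = load_cohort()
    pipe = PipelineConfig(seed=dataset.config.seed, simulation=dataset.config)
    epochs = preprocess_dataset(dataset, pipe)
    labels_sam = label_dataset(epochs, dataset.annotations, "sam")
    labels_hama = label_dataset(epochs, dataset.annotations, "hama")

    out = ROOT / "scratch"
    summary = {"n_epochs": len(epochs)}
    for method in ("dwt", "psd"):
        table = extract_features(epochs, method=method)
        df = table.provenance.join(table.features)
        df["sam_anxious"] = labels_sam
        df["hama_anxious"] = labels_hama
        df.to_csv(out / f"features_{method}.csv", index=False)
        summary[method] = {
            "n_features": int(table.features.shape[1]),
            "sam_anxious": int(labels_sam.sum()),
            "hama_anxious": int(labels_hama.sum()),
        }
        print(
            f"{method}: {table.features.shape[1]} features × {len(epochs)} epochs "
            f"(SAM {int(labels_sam.sum())} anxious, HAM-A {int(labels_hama.sum())} anxious)"
        )
    (ROOT / "results" / "feature_summary.json").write_text(json.dumps(summary, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
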