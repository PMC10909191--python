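#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the anxiety-elicitation recording structure: subjects × 6 trials
on the 14-channel EPOC montage at 128 Hz, with per-subject HAM-A totals
and per-trial SAM ratings consistent with each subject's class. Signal
matrices go to scratch/ (they are bulky); the annotation table and a
cohort summary go to results/.

Run from the repository root:  python analysis/01_simulate_cohort.py --seed 1
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from anxeeg.io import write_recording_csv
from anxeeg.simulate import SimulationConfig, generate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--subjects", type=int, default=6)
    parser.add_argument("--trial-seconds", type=float, default=10.0)
    parser.add_argument("--effect-size", type=float, default=1.0)
    args = parser.parse_args()

    config = SimulationConfig(
        n_subjects=args.subjects,
        trial_seconds=args.trial_seconds,
        effect_size=args.effect_size,
        seed=args.seed,
    )
    dataset = generate_dataset(config)

    out = ROOT / "scratch" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    for rec in dataset.recordings:
        write_recording_csv(rec, out / f"{rec.subject_id}_trial{rec.trial_id}.csv")

    rows = []
    for annotation, flag in zip(dataset.annotations, dataset.anxious_flags):
        for trial, (valence, arousal) in enumerate(annotation.sam_ratings):
            rows.append(
                {
                    "subject_id": annotation.subject_id,
                    "trial": trial,
                    "valence": valence,
                    "arousal": arousal,
                    "hama_score": annotation.hama_score,
                    "anxious_truth": flag,
                }
            )
    annotations = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    annotations.to_csv(results / "cohort_annotations.csv", index=False)

    summary = {
        "n_subjects": config.n_subjects,
        "n_recordings": len(dataset.recordings),
        "anxious_subjects": int(sum(dataset.anxious_flags)),
        "effect_size": config.effect_size,
        "seed": config.seed,
        "trial_seconds": config.trial_seconds,
    }
    (results / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"cohort: {summary['n_subjects']} subjects ({summary['anxious_subjects']} anxious), "
        f"{summary['n_recordings']} trials of {config.trial_seconds:g} s -> scratch/cohort/"
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
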