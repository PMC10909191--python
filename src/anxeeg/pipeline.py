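"""End-to-end orchestration: simulate → preprocess → label → extract → balance → evaluate.

One :class:`PipelineConfig` drives the whole run; every random stage's
seed appears in the config and is echoed into the run manifest, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from anxeeg import __version__
from anxeeg.features import LabeledFeatureTable, extract_features
from anxeeg.io import DEFAULT_CHANNELS, ConfigurationError, Epoch, bandpass, epoch_signal, select_channels
from anxeeg.labeling import Scheme, label_dataset
from anxeeg.models import default_specs, run_comparison
from anxeeg.simulate import SimulatedDataset, SimulationConfig, generate_dataset


@dataclass(frozen=True)
class PipelineConfig:
    """Full-run parameters; JSON-serializable."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band_low: float = 4.0
    band_high: float = 45.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    epoch_seconds: float = 1.0
    fz_surrogate: str = "mean_f3_f4"
    smote_k: int = 5
    smote_before_split: bool = False
    train_fraction: float = 0.8
    stack_bins: bool = False

    _REQUIRED = ("seed",)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in cls._REQUIRED:
            if key not in data:
                raise ConfigurationError(f"missing required config key: {key!r}")
        data = dict(data)
        sim = data.pop("simulation", {})
        if not isinstance(sim, SimulationConfig):
            sim = SimulationConfig(**{**sim, "seed": sim.get("seed", data["seed"])})
        return cls(simulation=sim, **data)

    def to_dict(self) -> dict[str, Any]:
        out = asdict(self)
        out["channels"] = list(out["channels"])
        out["simulation"]["channel_names"] = list(out["simulation"]["channel_names"])
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def preprocess_dataset(dataset: SimulatedDataset, config: PipelineConfig) -> list[Epoch]:
    """Band-pass 4–45 Hz, keep the 10 anxiety-related channels, cut 1-s epochs."""
    epochs: list[Epoch] = []
    for rec in dataset.recordings:
        rec = bandpass(rec, config.band_low, config.band_high)
        rec = select_channels(rec, config.channels)
        epochs.extend(epoch_signal(rec, config.epoch_seconds))
    return epochs


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None, write_features: bool = False) -> dict[str, Any]:
    """Run the full benchmark and return (and optionally write) the result.

    The result maps stage names to their outputs: epoch/label counts, the
    48-cell report grid, and a manifest (config, hash, versions). With
    ``out_dir`` set, reports, label tables, the manifest and (optionally)
    the feature tables are written under it.
    """
    dataset = generate_dataset(config.simulation)
    epochs = preprocess_dataset(dataset, config)

    labels_sam = label_dataset(epochs, dataset.annotations, Scheme.SAM)
    labels_hama = label_dataset(epochs, dataset.annotations, Scheme.HAMA)

    table_dwt = extract_features(epochs, method="dwt", fz_surrogate=config.fz_surrogate)
    table_psd = extract_features(
        epochs, method="psd", stack_bins=config.stack_bins, fz_surrogate=config.fz_surrogate
    )

    records = run_comparison(
        table_dwt,
        table_psd,
        labels_sam,
        labels_hama,
        specs=default_specs(),
        seed=config.seed,
        smote_k=config.smote_k,
        smote_before_split=config.smote_before_split,
    )

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "package_version": __version__,
        "python_version": platform.python_version(),
        "n_epochs": len(epochs),
        "label_counts": {
            "sam": {"anxious": int(labels_sam.sum()), "non_anxious": int((~labels_sam).sum())},
            "hama": {"anxious": int(labels_hama.sum()), "non_anxious": int((~labels_hama).sum())},
        },
    }
    result = {"manifest": manifest, "reports": records}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out_dir / "reports.json").write_text(json.dumps(records, indent=2, sort_keys=True))
        labels = table_dwt.provenance[["subject_id", "trial_id", "epoch_index"]].copy()
        labels["sam_anxious"] = labels_sam
        labels["hama_anxious"] = labels_hama
        labels.to_csv(out_dir / "labels.csv", index=False)
        if write_features:
            for name, table in (("dwt", table_dwt), ("psd", table_psd)):
                df = table.provenance.join(table.features)
                df.to_csv(out_dir / f"features_{name}.csv", index=False)
    return result


def reports_to_frame(records: list[dict[str, Any]]):
    """Flatten the report grid into a tidy DataFrame (one row per cell)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {k: v for k, v in rec.items() if k != "confusion"}
            for rec in records
        ]
    )


def render_confusion(report: dict[str, Any], path: str | Path) -> Path:
    """Optional: draw one report's 2×2 confusion matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    confusion = np.asarray(report["confusion"])
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.imshow(confusion, cmap="Blues")
    for (i, j), count in np.ndenumerate(confusion):
        ax.text(j, i, str(count), ha="center", va="center")
    ax.set_xticks([0, 1], ["non-anxious", "anxious"])
    ax.set_yticks([0, 1], ["non-anxious", "anxious"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    ax.set_title(report.get("classifier", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
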