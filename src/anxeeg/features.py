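"""Assembly of labeled feature tables from epochs.

Joins the extractor output (DWT or PSD) with the eight affect features and
per-epoch provenance (subject, trial, epoch index) into a single table —
the unit that balancing and classification operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from anxeeg.affect import AFFECT_NAMES, affect_features
from anxeeg.dwt import dwt_band_powers, extract_dwt_features
from anxeeg.io import ConfigurationError, Epoch, InputError
from anxeeg.psd import extract_psd_features, psd_band_powers

PROVENANCE_COLUMNS = ("subject_id", "trial_id", "epoch_index", "synthetic")


@dataclass(frozen=True)
class LabeledFeatureTable:
    """Feature matrix with aligned binary labels and per-row provenance.

    ``features`` is an epochs × features DataFrame with named columns;
    ``labels`` is boolean (True = anxious); ``provenance`` carries
    subject/trial/epoch plus a ``synthetic`` flag marking oversampled rows.
    """

    features: pd.DataFrame
    labels: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))
        if len(self.features) != len(self.labels) or len(self.features) != len(self.provenance):
            raise InputError("features, labels and provenance must have aligned rows")
        if not np.isfinite(self.features.to_numpy()).all():
            raise InputError("feature table contains non-finite values")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    def class_counts(self) -> tuple[int, int]:
        """(non_anxious, anxious) row counts."""
        n_anx = int(self.labels.sum())
        return self.n_rows - n_anx, n_anx

    def subset(self, index: np.ndarray) -> "LabeledFeatureTable":
        return LabeledFeatureTable(
            features=self.features.iloc[index].reset_index(drop=True),
            labels=self.labels[index],
            provenance=self.provenance.iloc[index].reset_index(drop=True),
        )

    def with_labels(self, labels: np.ndarray) -> "LabeledFeatureTable":
        return replace(self, labels=np.asarray(labels, dtype=bool))


def extract_features(
    epochs: list[Epoch],
    method: str = "dwt",
    labels: np.ndarray | None = None,
    stack_bins: bool = False,
    fz_surrogate: str = "mean_f3_f4",
) -> LabeledFeatureTable:
    """Extract per-epoch features plus the eight affect features.

    ``method='dwt'`` yields 600 + 8 = 608 columns; ``method='psd'`` yields
    60 + 8 = 68 (more with ``stack_bins``). Affect features use band
    powers from the same extractor: wavelet coefficient power in DWT mode,
    integrated periodogram power in PSD mode.
    """
    if method not in ("dwt", "psd"):
        raise ConfigurationError(f"method must be 'dwt' or 'psd', got {method!r}")
    if not epochs:
        raise InputError("no epochs to extract features from")
    if labels is None:
        labels = np.zeros(len(epochs), dtype=bool)

    rows, names = [], None
    for ep in epochs:
        if method == "dwt":
            base_names, base_values = extract_dwt_features(ep)
            bandpowers = dwt_band_powers(ep)
        else:
            base_names, base_values = extract_psd_features(ep, stack_bins=stack_bins)
            bandpowers = psd_band_powers(ep)
        aff = affect_features(bandpowers, fz_surrogate=fz_surrogate).as_array()
        rows.append(np.concatenate([base_values, aff]))
        names = base_names + list(AFFECT_NAMES)

    provenance = pd.DataFrame(
        {
            "subject_id": [ep.subject_id for ep in epochs],
            "trial_id": [ep.trial_id for ep in epochs],
            "epoch_index": [ep.epoch_index for ep in epochs],
            "synthetic": False,
        }
    )
    return LabeledFeatureTable(
        features=pd.DataFrame(np.vstack(rows), columns=names),
        labels=np.asarray(labels, dtype=bool),
        provenance=provenance,
    )
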