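"""SMOTE oversampling of the minority anxiety class.

Synthetic Minority Oversampling Technique: each synthetic sample is
``x + u·(x_nn − x)`` with ``u ~ Uniform(0, 1)``, ``x`` a minority row and
``x_nn`` one of its k nearest minority neighbors under Euclidean distance.
The minority class is raised to exactly the majority count; original rows
are preserved verbatim and synthetic rows are flagged in the provenance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from anxeeg.features import LabeledFeatureTable
from anxeeg.io import InputError


def smote(table: LabeledFeatureTable, k: int = 5, seed: int = 0) -> LabeledFeatureTable:
    """Equalize class counts by interpolated minority oversampling.

    ``k`` is clipped to ``minority_size − 1`` when the minority class is
    small, so any minority of ≥ 2 rows is accepted. An already balanced
    table is returned unchanged.
    """
    labels = table.labels
    n_anx = int(labels.sum())
    n_non = labels.size - n_anx
    if n_anx == 0 or n_non == 0:
        raise InputError("SMOTE needs both classes present")
    if n_anx == n_non:
        return table
    minority_label = n_anx < n_non
    minority_idx = np.flatnonzero(labels == minority_label)
    if minority_idx.size < 2:
        raise InputError("SMOTE needs a minority class of at least 2 rows")

    X = table.features.to_numpy()
    X_min = X[minority_idx]
    k_eff = min(k, minority_idx.size - 1)
    # +1 then drop the self-neighbor
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    n_new = abs(n_non - n_anx)
    base = rng.integers(0, minority_idx.size, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = X_min[base]
    x_nn = X_min[neighbor_idx[base, pick]]
    synthetic = x + u[:, None] * (x_nn - x)

    features = pd.concat(
        [table.features, pd.DataFrame(synthetic, columns=table.features.columns)],
        ignore_index=True,
    )
    new_labels = np.concatenate([labels, np.full(n_new, minority_label, dtype=bool)])
    new_provenance = pd.DataFrame(
        {
            "subject_id": "synthetic",
            "trial_id": "",
            "epoch_index": -1,
            "synthetic": True,
        },
        index=range(n_new),
    )
    provenance = pd.concat([table.provenance, new_provenance], ignore_index=True)
    return LabeledFeatureTable(features=features, labels=new_labels, provenance=provenance)
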