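"""Binary anxiety labels from SAM ratings and HAM-A totals.

Two labeling schemes are supported:

* **SAM** (per trial): anxious iff valence ≤ 5 and arousal ≥ 5, except the
  rating rectangle valence ∈ {4, 5} × arousal ∈ {5, 6}, which is
  non-anxious (the carve-out overlaps the anxious rule and wins). On the
  9×9 rating grid this leaves 25 − 4 = 21 anxious cells.
* **HAM-A** (per subject): anxious iff the total score exceeds 20;
  0–20 is non-anxious.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from anxeeg.io import Epoch, InputError
from anxeeg.simulate import SubjectAnnotation


class LabelValue(str, Enum):
    ANXIOUS = "anxious"
    NON_ANXIOUS = "non_anxious"


class Scheme(str, Enum):
    SAM = "sam"
    HAMA = "hama"


@dataclass(frozen=True)
class AnxietyLabel:
    value: LabelValue
    scheme: Scheme

    @property
    def is_anxious(self) -> bool:
        return self.value is LabelValue.ANXIOUS


def label_sam(valence: int, arousal: int, carve_out_wins: bool = True) -> AnxietyLabel:
    """Label one trial from its SAM valence/arousal ratings (each 1–9).

    ``carve_out_wins`` controls the overlap between the anxious rule and
    the non-anxious carve-out rectangle {4,5}×{5,6}; the default treats the
    carve-out as non-anxious.
    """
    if not (1 <= valence <= 9 and 1 <= arousal <= 9):
        raise InputError(f"SAM ratings must be integers in 1..9, got ({valence}, {arousal})")
    anxious = valence <= 5 and arousal >= 5
    if carve_out_wins and 4 <= valence <= 5 and 5 <= arousal <= 6:
        anxious = False
    return AnxietyLabel(LabelValue.ANXIOUS if anxious else LabelValue.NON_ANXIOUS, Scheme.SAM)


def label_hama(score: int) -> AnxietyLabel:
    """Label one subject from the HAM-A total (0–56); anxious iff score > 20."""
    if not 0 <= score <= 56:
        raise InputError(f"HAM-A total must be in 0..56, got {score}")
    value = LabelValue.ANXIOUS if score > 20 else LabelValue.NON_ANXIOUS
    return AnxietyLabel(value, Scheme.HAMA)


def label_dataset(
    epochs: list[Epoch],
    annotations: list[SubjectAnnotation],
    scheme: Scheme | str,
) -> np.ndarray:
    """Broadcast trial/subject labels to every epoch.

    Under SAM every epoch inherits its trial's rating-based label; under
    HAM-A every epoch inherits its subject's score-based label. Returns a
    boolean array aligned with ``epochs`` (True = anxious).

    Raises an input error naming the subject/trial if an epoch has no
    covering annotation.
    """
    scheme = Scheme(scheme)
    if not annotations:
        raise InputError("empty annotation table")
    by_subject = {a.subject_id: a for a in annotations}
    labels = np.empty(len(epochs), dtype=bool)
    for i, ep in enumerate(epochs):
        annotation = by_subject.get(ep.subject_id)
        if annotation is None:
            raise InputError(f"no annotation for subject {ep.subject_id!r}")
        if scheme is Scheme.HAMA:
            labels[i] = label_hama(annotation.hama_score).is_anxious
        else:
            trial = int(ep.trial_id)
            if not 0 <= trial < len(annotation.sam_ratings):
                raise InputError(
                    f"no SAM rating for subject {ep.subject_id!r} trial {ep.trial_id!r}"
                )
            valence, arousal = annotation.sam_ratings[trial]
            labels[i] = label_sam(valence, arousal).is_anxious
    return labels
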