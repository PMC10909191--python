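"""Valence/arousal affect features from frontal alpha and beta band power.

Eight features derived from frontal-asymmetry emotion research, computed
from per-channel alpha and beta power (either wavelet- or
periodogram-based):

    V1 = β(AF3,F3)/α(AF3,F3) − β(AF4,F4)/α(AF4,F4)
    V2 = ln α(Fz,AF3,F3) − ln α(Fz,AF4,F4)
    V3 = α(F4) − β(F3)
    V4 = α(F4)/β(F4) − α(F3)/β(F3)
    A1 = α(AF3+AF4+F3+F4) / β(AF3+AF4+F3+F4)
    A2 = 1 / A1
    A3 = log2[ β(Fz,AF4,F4,AF3,F3) / α(Fz,AF4,F4,AF3,F3) ]
    A4 = −( ln α(Fz,AF4,F4) + ln α(Fz,AF3,F3) )

where a band symbol over several channels means the band's power summed
over them. The Emotiv EPOC montage has no midline Fz electrode; by default
its band power is surrogated as the mean of F3 and F4 (midline
interpolation from the nearest lateral frontal sites). The surrogate
policy is configurable and recorded in the feature provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from anxeeg.io import ConfigurationError, InputError

AFFECT_NAMES: tuple[str, ...] = (
    "valence1", "valence2", "valence3", "valence4",
    "arousal1", "arousal2", "arousal3", "arousal4",
)

FZ_SURROGATES = ("mean_f3_f4", "af3_af4", "drop_term")


class ComputationError(ArithmeticError):
    """A ratio or logarithm was requested of a non-positive band power."""


@dataclass(frozen=True)
class AffectFeatures:
    valence1: float
    valence2: float
    valence3: float
    valence4: float
    arousal1: float
    arousal2: float
    arousal3: float
    arousal4: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in AFFECT_NAMES])


def group_power(
    bandpowers: dict[str, dict[str, float]],
    channels: list[str] | tuple[str, ...],
    band: str,
) -> float:
    """Band power summed over the named channels."""
    total = 0.0
    for ch in channels:
        if ch not in bandpowers:
            raise InputError(f"channel {ch!r} missing from band-power table")
        if band not in bandpowers[ch]:
            raise InputError(f"band {band!r} missing for channel {ch!r}")
        total += bandpowers[ch][band]
    return total


def _with_fz(bandpowers: dict[str, dict[str, float]], surrogate: str) -> tuple[dict[str, dict[str, float]], list[str]]:
    if surrogate not in FZ_SURROGATES:
        raise ConfigurationError(f"fz_surrogate must be one of {FZ_SURROGATES}, got {surrogate!r}")
    if "Fz" in bandpowers:
        return bandpowers, ["Fz"]
    if surrogate == "drop_term":
        return bandpowers, []
    pair = ("F3", "F4") if surrogate == "mean_f3_f4" else ("AF3", "AF4")
    fz = {
        band: (bandpowers[pair[0]][band] + bandpowers[pair[1]][band]) / 2.0
        for band in bandpowers[pair[0]]
    }
    return {**bandpowers, "Fz": fz}, ["Fz"]


def _checked_ratio(num: float, den: float, equation: str) -> float:
    if den <= 0:
        raise ComputationError(f"non-positive band power in denominator of {equation}")
    return num / den


def _checked_log(value: float, equation: str, base: float = math.e) -> float:
    if value <= 0:
        raise ComputationError(f"non-positive band power under the log of {equation}")
    return math.log(value) / math.log(base)


def affect_features(
    bandpowers: dict[str, dict[str, float]],
    fz_surrogate: str = "mean_f3_f4",
) -> AffectFeatures:
    """The eight valence/arousal features from per-channel alpha/beta power.

    ``bandpowers`` maps channel → {"alpha": power, "beta": power}; AF3,
    AF4, F3 and F4 must be present with strictly positive powers wherever
    a ratio or logarithm is taken.
    """
    bp, fz = _with_fz(bandpowers, fz_surrogate)

    def a(*channels: str) -> float:
        return group_power(bp, channels, "alpha")

    def b(*channels: str) -> float:
        return group_power(bp, channels, "beta")

    left = (*fz, "AF3", "F3")
    right = (*fz, "AF4", "F4")
    five = (*fz, "AF4", "F4", "AF3", "F3")
    quad = ("AF3", "AF4", "F3", "F4")

    v1 = _checked_ratio(b("AF3", "F3"), a("AF3", "F3"), "valence1") - _checked_ratio(
        b("AF4", "F4"), a("AF4", "F4"), "valence1"
    )
    v2 = _checked_log(a(*left), "valence2") - _checked_log(a(*right), "valence2")
    v3 = a("F4") - b("F3")
    v4 = _checked_ratio(a("F4"), b("F4"), "valence4") - _checked_ratio(a("F3"), b("F3"), "valence4")
    a1 = _checked_ratio(a(*quad), b(*quad), "arousal1")
    a2 = _checked_ratio(b(*quad), a(*quad), "arousal2")
    a3 = _checked_log(_checked_ratio(b(*five), a(*five), "arousal3"), "arousal3", base=2.0)
    a4 = -(_checked_log(a(*right), "arousal4") + _checked_log(a(*left), "arousal4"))
    return AffectFeatures(v1, v2, v3, v4, a1, a2, a3, a4)
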