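"""Discrete-wavelet-transform feature extraction.

Each 1-s epoch channel is decomposed with a 4-level Daubechies-4 (db4)
filter bank into detail coefficients D1–D4 and approximation A4. At
128 Hz the dyadic bands are D1 ↔ 32–64 Hz (gamma), D2 ↔ 16–32 Hz (beta),
D3 ↔ 8–16 Hz (alpha), D4 ↔ 4–8 Hz (theta), A4 ↔ 0–4 Hz (delta).

Per channel, ten statistical attributes are computed for six component
series — the five coefficient arrays plus one entropy-derived series —
giving 10 channels × 6 components × 10 attributes = 600 features; the
pipeline appends the 8 valence/arousal affect features for 608 total.

The entropy component: Shannon entropy of an epoch is a single number, so
summary statistics of "the entropy" need a series to summarize. Here the
sixth series is the per-bin information sequence {−p_i log2 p_i} of the
channel's amplitude histogram, whose sum is exactly the Shannon entropy.
This convention is isolated in :func:`entropy_series` so alternatives can
be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from anxeeg.io import Epoch, InputError

#: Component order used in feature names; band mapping at 128 Hz in module docstring.
COMPONENTS: tuple[str, ...] = ("D1", "D2", "D3", "D4", "A4", "ENT")

#: Attribute order, matching the ten statistical attributes as listed.
ATTRIBUTES: tuple[str, ...] = (
    "mean", "median", "p25", "p75", "variance",
    "std", "rms", "zcr", "mcr", "mean_deriv",
)

#: Dyadic band edges (Hz) of each coefficient at a 128 Hz sampling rate.
COEFF_BANDS_128: dict[str, tuple[float, float]] = {
    "D1": (32.0, 64.0),
    "D2": (16.0, 32.0),
    "D3": (8.0, 16.0),
    "D4": (4.0, 8.0),
    "A4": (0.0, 4.0),
}

DEFAULT_ENTROPY_BINS = 16


@dataclass(frozen=True)
class WaveletDecomposition:
    """Single-channel db4 pyramid: coefficients keyed D1..D4, A4."""

    coefficients: dict[str, np.ndarray]
    wavelet_name: str
    levels: int
    sampling_rate: float

    def energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.coefficients.values()))


def dwt_decompose(
    epoch_channel: np.ndarray,
    wavelet: str = "db4",
    levels: int = 4,
    mode: str = "periodization",
    sampling_rate: float = 128.0,
) -> WaveletDecomposition:
    """Decompose one channel into ``levels`` detail arrays plus one approximation.

    The default ``periodization`` boundary treatment keeps the transform
    orthonormal: the inverse reconstructs the input to machine precision
    and coefficient energy equals signal energy (Parseval).
    """
    x = np.asarray(epoch_channel, dtype=float).ravel()
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(x.size, wav.dec_len)
    if max_level < levels:
        min_len = wav.dec_len // 2 * 2**levels  # smallest n with dwt_max_level ≥ levels
        raise InputError(
            f"input of length {x.size} supports only {max_level} {wavelet} levels; "
            f"need ≥ {min_len} samples for {levels} levels"
        )
    coeff_list = pywt.wavedec(x, wav, mode=mode, level=levels)  # [A_L, D_L, ..., D_1]
    coefficients = {"A4" if levels == 4 else f"A{levels}": coeff_list[0]}
    for k, detail in enumerate(coeff_list[1:]):
        coefficients[f"D{levels - k}"] = detail
    return WaveletDecomposition(
        coefficients=coefficients,
        wavelet_name=wavelet,
        levels=levels,
        sampling_rate=sampling_rate,
    )


def reconstruct(decomposition: WaveletDecomposition, mode: str = "periodization") -> np.ndarray:
    """Inverse transform; exact to ~1e−12 under the orthonormal default mode."""
    levels = decomposition.levels
    coeff_list = [decomposition.coefficients[f"A{levels}"]] + [
        decomposition.coefficients[f"D{k}"] for k in range(levels, 0, -1)
    ]
    return pywt.waverec(coeff_list, decomposition.wavelet_name, mode=mode)


def _histogram_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Probability mass over equal-width bins spanning the data range.

    A constant signal puts all mass in one bin (entropy 0). Bin edges are
    data-relative, so adding a constant to the signal changes nothing.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-300:
        probs = np.zeros(n_bins)
        probs[0] = 1.0
        return probs
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts / x.size


def entropy_series(x: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> np.ndarray:
    """Per-bin information sequence {−p_i log2 p_i}; sums to Shannon entropy."""
    probs = _histogram_probs(np.asarray(x, dtype=float).ravel(), n_bins)
    out = np.zeros_like(probs)
    nz = probs > 0
    out[nz] = -probs[nz] * np.log2(probs[nz])
    return out


def shannon_entropy(signal: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Histogram-estimate Shannon entropy S = −Σ p_i log2 p_i, in bits.

    Bounded by [0, log2 n_bins]; empty bins contribute zero.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise InputError("cannot compute entropy of an empty signal")
    if n_bins < 2:
        raise InputError(f"n_bins must be ≥ 2, got {n_bins}")
    return float(np.sum(entropy_series(x, n_bins)))


def _crossing_rate(x: np.ndarray, threshold: float) -> float:
    # strict sign changes of (x − threshold); samples exactly on the
    # threshold break a crossing
    s = np.sign(x - threshold)
    return float(np.sum(s[:-1] * s[1:] < 0)) / (x.size - 1)


def stat_attributes(series: np.ndarray) -> dict[str, float]:
    """The ten per-series summary statistics, in canonical order.

    Variance is the population variance (divide by n); percentiles use
    linear interpolation; the derivative is the first difference; crossing
    rates count strict sign changes of (x − 0) and (x − mean) per
    transition, so both lie in [0, 1].
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise InputError(f"need ≥ 2 samples for the attribute set, got {x.size}")
    mean = float(np.mean(x))
    variance = float(np.var(x))
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "variance": variance,
        "std": float(np.sqrt(variance)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "zcr": _crossing_rate(x, 0.0),
        "mcr": _crossing_rate(x, mean),
        "mean_deriv": float(np.mean(np.diff(x))),
    }


def dwt_band_powers(epoch: Epoch, mode: str = "periodization") -> dict[str, dict[str, float]]:
    """Per-channel alpha/beta band power from the wavelet pyramid.

    Power of a band = mean squared coefficient of the matching array
    (D3 for alpha, D2 for beta); feeds the affect equations in DWT mode.
    """
    powers: dict[str, dict[str, float]] = {}
    for ch, name in enumerate(epoch.channel_names):
        dec = dwt_decompose(epoch.signal[ch], mode=mode, sampling_rate=epoch.sampling_rate)
        powers[name] = {
            "alpha": float(np.mean(dec.coefficients["D3"] ** 2)),
            "beta": float(np.mean(dec.coefficients["D2"] ** 2)),
        }
    return powers


def dwt_feature_names(channel_names: tuple[str, ...]) -> list[str]:
    return [
        f"dwt_{ch}_{comp}_{attr}"
        for ch in channel_names
        for comp in COMPONENTS
        for attr in ATTRIBUTES
    ]


def extract_dwt_features(
    epoch: Epoch,
    n_bins: int = DEFAULT_ENTROPY_BINS,
    mode: str = "periodization",
    expected_channels: int = 10,
) -> tuple[list[str], np.ndarray]:
    """600-dimensional named DWT feature vector for a 10-channel epoch.

    Order: channels in montage order, components D1, D2, D3, D4, A4, ENT,
    then the ten attributes. The pipeline appends 8 affect features for a
    608-dimensional vector.
    """
    if epoch.signal.shape[0] != expected_channels:
        raise InputError(
            f"expected {expected_channels}-channel epochs, got {epoch.signal.shape[0]}"
        )
    values = np.empty(len(epoch.channel_names) * len(COMPONENTS) * len(ATTRIBUTES))
    k = 0
    for ch in range(epoch.signal.shape[0]):
        x = epoch.signal[ch]
        dec = dwt_decompose(x, mode=mode, sampling_rate=epoch.sampling_rate)
        series_by_component = {**dec.coefficients, "ENT": entropy_series(x, n_bins)}
        for comp in COMPONENTS:
            attrs = stat_attributes(series_by_component[comp])
            for attr in ATTRIBUTES:
                values[k] = attrs[attr]
                k += 1
    return dwt_feature_names(epoch.channel_names), values
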