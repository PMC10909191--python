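"""Power-spectral-density feature extraction.

Each epoch channel gets a single-segment Hann periodogram (a 1-s epoch at
128 Hz is too short for multi-segment Welch averaging), from which band
powers are integrated for theta (4–8 Hz), alpha (8–13), beta (13–30) and
gamma (30–40). Per channel the extractor stacks the four band powers plus
an average and a total power — 60 features over the 10-channel montage —
and the pipeline appends the 8 affect features (68 total). A config flag
additionally stacks the raw per-bin spectrum of every channel.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import periodogram

from anxeeg.io import ConfigurationError, Epoch, InputError

#: Band edges in Hz, half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

MIN_SAMPLES = 64


def psd_estimate(epoch_channel: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann periodogram over the full epoch.

    Returns ``(frequencies, density)`` with resolution sampling_rate / n.
    """
    x = np.asarray(epoch_channel, dtype=float).ravel()
    if x.size < MIN_SAMPLES:
        raise InputError(f"need ≥ {MIN_SAMPLES} samples for a spectrum, got {x.size}")
    freqs, density = periodogram(x, fs=sampling_rate, window="hann", detrend=False)
    return freqs, density


def band_power(
    spectrum: tuple[np.ndarray, np.ndarray],
    low: float,
    high: float,
) -> float:
    """Integrated power over ``low ≤ f < high`` (rectangle rule).

    Half-open bands make adjacent bands additive without double counting.
    """
    freqs, density = spectrum
    if not 0 <= low < high:
        raise ConfigurationError(f"band must satisfy 0 ≤ low < high, got ({low}, {high})")
    if high > freqs[-1] + 1e-9:
        raise ConfigurationError(f"band edge {high} Hz exceeds Nyquist {freqs[-1]} Hz")
    df = freqs[1] - freqs[0]
    mask = (freqs >= low) & (freqs < high)
    if high >= freqs[-1]:  # band reaches Nyquist: include the endpoint bin
        mask |= freqs == freqs[-1]
    return float(np.sum(density[mask]) * df)


def total_power(spectrum: tuple[np.ndarray, np.ndarray]) -> float:
    freqs, density = spectrum
    return float(np.sum(density) * (freqs[1] - freqs[0]))


def psd_band_powers(epoch: Epoch) -> dict[str, dict[str, float]]:
    """Per-channel powers of the four bands plus average/total.

    ``average`` is the mean of the four band powers; ``total`` integrates
    the whole one-sided spectrum.
    """
    out: dict[str, dict[str, float]] = {}
    for ch, name in enumerate(epoch.channel_names):
        spectrum = psd_estimate(epoch.signal[ch], epoch.sampling_rate)
        powers = {band: band_power(spectrum, lo, hi) for band, (lo, hi) in BANDS.items()}
        powers["average"] = float(np.mean([powers[b] for b in BANDS]))
        powers["total"] = total_power(spectrum)
        out[name] = powers
    return out


def psd_feature_names(channel_names: tuple[str, ...], stack_bins: bool = False, n_samples: int = 128, sampling_rate: float = 128.0) -> list[str]:
    names = [
        f"psd_{ch}_{quantity}"
        for ch in channel_names
        for quantity in (*BANDS, "average", "total")
    ]
    if stack_bins:
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
        names += [f"psd_{ch}_bin_{f:g}Hz" for ch in channel_names for f in freqs]
    return names


def extract_psd_features(
    epoch: Epoch,
    stack_bins: bool = False,
    expected_channels: int = 10,
) -> tuple[list[str], np.ndarray]:
    """Named spectral feature vector: 6 per channel, optional raw bins."""
    if epoch.signal.shape[0] != expected_channels:
        raise InputError(
            f"expected {expected_channels}-channel epochs, got {epoch.signal.shape[0]}"
        )
    powers = psd_band_powers(epoch)
    values = [
        powers[ch][quantity]
        for ch in epoch.channel_names
        for quantity in (*BANDS, "average", "total")
    ]
    if stack_bins:
        for ch in range(epoch.signal.shape[0]):
            _, density = psd_estimate(epoch.signal[ch], epoch.sampling_rate)
            values.extend(density.tolist())
    names = psd_feature_names(
        epoch.channel_names, stack_bins, epoch.signal.shape[1], epoch.sampling_rate
    )
    return names, np.asarray(values)
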