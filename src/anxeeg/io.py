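"""Recording I/O, band-pass filtering, channel selection, and epoching.

Recordings are plain ``channels × samples`` float matrices with named
channels. Two on-disk formats are supported: headered CSV (first column =
channel name, one row per channel) and EDF. EDF reading goes through MNE;
a minimal 16-bit EDF writer is provided so round trips can be exercised
without binary fixtures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

#: 14-channel Emotiv EPOC montage, in headset order.
EPOC_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: The ten channels retained for anxiety detection.
DEFAULT_CHANNELS: tuple[str, ...] = ("AF3", "F7", "F3", "F4", "F8", "AF4", "FC6", "FC5", "P7", "P8")

#: Reference sampling rate assumed by the frequency-band layout downstream.
DEFAULT_SFREQ = 128.0


class InputError(ValueError):
    """A file or in-memory input violates the expected structure."""


class ConfigurationError(ValueError):
    """A parameter is outside its valid range."""


@dataclass(frozen=True)
class EEGRecording:
    """Continuous multi-channel EEG signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in µV-scale arbitrary units.
    sampling_rate : float
        Sampling rate in Hz.
    channel_names : tuple of str
        One name per signal row, montage order.
    subject_id, trial_id : str
        Provenance identifiers.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if sig.ndim != 2:
            raise InputError(f"signal must be 2-D (channels × samples), got shape {sig.shape}")
        if len(self.channel_names) != sig.shape[0]:
            raise InputError(
                f"{len(self.channel_names)} channel names for {sig.shape[0]} signal rows"
            )
        if self.sampling_rate <= 0:
            raise ConfigurationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.isfinite(sig).all():
            raise InputError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class Epoch:
    """Fixed-length segment cut from a recording (default 1 s / 128 samples)."""

    signal: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    subject_id: str
    trial_id: str
    epoch_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))


def write_recording_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as headered CSV (first column = channel name)."""
    path = Path(path)
    df = pd.DataFrame(recording.signal, index=list(recording.channel_names))
    df.index.name = "channel"
    df.to_csv(path, float_format="%.8g")
    return path


def _read_csv(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise InputError(f"cannot parse CSV recording {path}: {exc}") from exc
    if df.index.dtype != object or df.empty:
        raise InputError(f"{path}: expected a channel-name column followed by samples")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.index)


def _read_edf(path: Path) -> tuple[np.ndarray, tuple[str, ...], float]:
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse EDF recording {path}: {exc}") from exc
    # recordings are µV-scale throughout; undo MNE's conversion to volts
    return raw.get_data(units="uV"), tuple(raw.ch_names), float(raw.info["sfreq"])


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    sampling_rate: float = DEFAULT_SFREQ,
    subject_id: str = "",
    trial_id: str = "",
) -> EEGRecording:
    """Read a recording from ``csv`` or ``edf``.

    ``fmt`` is inferred from the file suffix when omitted. CSV carries no
    rate metadata, so ``sampling_rate`` applies to CSV only; EDF supplies
    its own. Non-finite samples are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such recording file: {path}")
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        signal, names = _read_csv(path)
    elif fmt == "edf":
        signal, names, sampling_rate = _read_edf(path)
    else:
        raise InputError(f"unknown recording format {fmt!r} for {path} (expected csv or edf)")
    return EEGRecording(signal, sampling_rate, names, subject_id=subject_id, trial_id=trial_id)


def write_recording_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as EDF (16-bit samples, one data record per second).

    Minimal standard-compliant writer used for round-trip tests and
    optional export; physical scaling spans the per-channel data range, so
    quantization error is bounded by range/2^16.
    """
    path = Path(path)
    sig = recording.signal
    n_ch = recording.n_channels
    spr = int(round(recording.sampling_rate))  # samples per 1-s record
    n_rec = sig.shape[1] // spr
    if n_rec < 1:
        raise InputError("recording shorter than one EDF data record (1 s)")
    sig = sig[:, : n_rec * spr]

    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad(f"subject {recording.subject_id or 'X'}", 80),
            pad(f"trial {recording.trial_id or 'X'}", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    header += b"".join(pad(name, 16) for name in recording.channel_names)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(pad("uV", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{phys_min[i]:.6g}", 8) for i in range(n_ch))
    header += b"".join(pad(f"{phys_max[i]:.6g}", 8) for i in range(n_ch))
    header += b"".join(pad(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(pad(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))
    header += b"".join(pad(str(spr), 8) for _ in range(n_ch))
    header += b"".join(pad("", 32) for _ in range(n_ch))

    digital = np.rint((sig - phys_min[:, None]) * gain[:, None] + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            fh.write(digital[:, rec * spr : (rec + 1) * spr].tobytes())
    return path


def bandpass(recording: EEGRecording, low: float = 4.0, high: float = 45.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter (default 4–45 Hz, order 4).

    Applied forward-backward (``sosfiltfilt``) so the output has no phase
    shift and the same length as the input.
    """
    nyq = recording.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ConfigurationError(
            f"band corners must satisfy 0 < low < high < Nyquist ({nyq} Hz); got ({low}, {high})"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, recording.signal, axis=1)
    return replace(recording, signal=filtered)


def select_channels(recording: EEGRecording, keep: list[str] | tuple[str, ...] = DEFAULT_CHANNELS) -> EEGRecording:
    """Restrict a recording to ``keep``, in the order given."""
    missing = [name for name in keep if name not in recording.channel_names]
    if missing:
        raise InputError(f"channels not in montage: {missing}")
    idx = [recording.channel_names.index(name) for name in keep]
    return replace(recording, signal=recording.signal[idx], channel_names=tuple(keep))


def epoch_signal(recording: EEGRecording, duration: float = 1.0) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing partial window is discarded; ``epoch_index`` is 0-based.
    """
    if duration <= 0:
        raise ConfigurationError(f"epoch duration must be > 0 s, got {duration}")
    n = int(round(duration * recording.sampling_rate))
    if recording.n_samples < n:
        raise InputError(
            f"recording has {recording.n_samples} samples, shorter than one {duration}-s epoch ({n})"
        )
    if recording.sampling_rate != DEFAULT_SFREQ:
        logger.warning(
            "sampling rate %.6g Hz differs from the reference %.6g Hz; "
            "wavelet band edges shift accordingly",
            recording.sampling_rate,
            DEFAULT_SFREQ,
        )
    return [
        Epoch(
            signal=recording.signal[:, k * n : (k + 1) * n],
            sampling_rate=recording.sampling_rate,
            channel_names=recording.channel_names,
            subject_id=recording.subject_id,
            trial_id=recording.trial_id,
            epoch_index=k,
        )
        for k in range(recording.n_samples // n)
    ]
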