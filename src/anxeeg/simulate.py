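"""Synthetic DASPS-like EEG cohorts with controllable class structure.

Emulates the structure of the anxiety-elicitation study the pipeline
targets: N subjects × 6 one-minute trials on the 14-channel Emotiv EPOC
montage at 128 Hz, with per-subject HAM-A totals and per-trial SAM
valence/arousal ratings. Each trial is a sum of band-limited oscillations
(theta/alpha/beta/gamma sinusoids at the band centers) plus white Gaussian
noise; the anxious class raises beta and lowers alpha amplitude on the
frontal channels by a configurable effect size.

Oscillation phases are redrawn independently every second (phase
decoherence). Real cortical rhythms hold phase for well under a second, and
keeping trials phase-coherent for a full minute would stamp each trial with
a waveform fingerprint that classifiers could exploit even with no class
effect; per-second phases keep the null case (effect_size = 0) genuinely
uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from anxeeg.io import DEFAULT_SFREQ, EPOC_CHANNELS, ConfigurationError, EEGRecording

#: Band-center frequencies (Hz) of the synthesized oscillations.
BAND_FREQS: dict[str, float] = {"theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 35.0}

#: Baseline oscillation amplitudes (signal units); alpha-dominant at rest.
BAND_AMPLITUDES: dict[str, float] = {"theta": 1.0, "alpha": 1.5, "beta": 1.0, "gamma": 0.5}

#: Channels carrying the anxiety effect (frontal set used by the affect equations).
EFFECT_CHANNELS: tuple[str, ...] = ("AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6")

# SAM rating cells labeled anxious: valence ≤ 5 and arousal ≥ 5, minus the
# {4,5}×{5,6} carve-out that the labeling rules treat as non-anxious.
ANXIOUS_SAM_CELLS: tuple[tuple[int, int], ...] = tuple(
    (v, a)
    for v, a in product(range(1, 10), range(1, 10))
    if v <= 5 and a >= 5 and not (4 <= v <= 5 and 5 <= a <= 6)
)
NON_ANXIOUS_SAM_CELLS: tuple[tuple[int, int], ...] = tuple(
    cell for cell in product(range(1, 10), range(1, 10)) if cell not in ANXIOUS_SAM_CELLS
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters.

    Defaults mirror the emulated study: 23 subjects, 6 trials of 60 s at
    128 Hz on the 14 EPOC channels, with ~65% of subjects anxious (the
    epoch-level class share of the emulated dataset).
    """

    n_subjects: int = 23
    trials_per_subject: int = 6
    trial_seconds: float = 60.0
    sampling_rate: float = DEFAULT_SFREQ
    channel_names: tuple[str, ...] = EPOC_CHANNELS
    effect_size: float = 1.0
    noise_sd: float = 1.0
    anxious_fraction: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be ≥ 1, got {self.n_subjects}")
        if self.trials_per_subject < 1:
            raise ConfigurationError(f"trials_per_subject must be ≥ 1, got {self.trials_per_subject}")
        if self.trial_seconds <= 0:
            raise ConfigurationError(f"trial_seconds must be > 0, got {self.trial_seconds}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel_names must be unique")
        if self.sampling_rate <= 2 * max(BAND_FREQS.values()):
            raise ConfigurationError(
                f"sampling_rate must exceed twice the highest synthesized band "
                f"frequency ({max(BAND_FREQS.values())} Hz); got {self.sampling_rate}"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be ≥ 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.anxious_fraction <= 1:
            raise ConfigurationError(f"anxious_fraction must be in [0, 1], got {self.anxious_fraction}")


@dataclass(frozen=True)
class SubjectAnnotation:
    """HAM-A total and per-trial SAM ratings for one subject."""

    subject_id: str
    hama_score: int
    sam_ratings: tuple[tuple[int, int], ...]  # (valence, arousal) per trial

    def __post_init__(self) -> None:
        object.__setattr__(self, "sam_ratings", tuple(tuple(r) for r in self.sam_ratings))
        if not 0 <= self.hama_score <= 56:
            raise ConfigurationError(f"hama_score must be in 0..56, got {self.hama_score}")
        for valence, arousal in self.sam_ratings:
            if not (1 <= valence <= 9 and 1 <= arousal <= 9):
                raise ConfigurationError(f"SAM ratings must be in 1..9, got ({valence}, {arousal})")


@dataclass(frozen=True)
class SimulatedDataset:
    """A full synthetic cohort: recordings plus annotations and ground truth."""

    config: SimulationConfig
    recordings: list[EEGRecording]
    annotations: list[SubjectAnnotation]
    anxious_flags: tuple[bool, ...]  # per subject, generation ground truth

    def subject_flag(self, subject_id: str) -> bool:
        for annotation, flag in zip(self.annotations, self.anxious_flags):
            if annotation.subject_id == subject_id:
                return flag
        raise KeyError(subject_id)


def subject_label(index: int) -> str:
    return f"S{index:02d}"


def generate_recording(
    config: SimulationConfig,
    subject_index: int,
    anxious: bool,
    trial_index: int = 0,
) -> EEGRecording:
    """Synthesize one trial for one subject.

    The signal is ``Σ_b A_b sin(2π f_b t + φ)`` over the four bands plus
    ``N(0, noise_sd²)`` white noise, with a fresh phase per channel, band
    and second. When ``anxious`` is true the frontal channels get beta
    amplitude scaled by ``1 + effect_size/2`` and alpha divided by the same
    factor; ``effect_size = 0`` makes the classes identical by construction.

    The random stream depends only on ``(config.seed, subject_index,
    trial_index)``, so any trial can be regenerated in isolation.
    """
    rng = np.random.default_rng([config.seed, subject_index, trial_index])
    n_channels = len(config.channel_names)
    n_seconds = int(np.floor(config.trial_seconds))
    residue = config.trial_seconds - n_seconds
    sec_samples = int(round(config.sampling_rate))
    n_samples = int(round(config.trial_seconds * config.sampling_rate))

    scale = 1.0 + config.effect_size / 2.0
    frontal = np.array([name in EFFECT_CHANNELS for name in config.channel_names])

    signal = np.zeros((n_channels, n_samples))
    t_sec = np.arange(sec_samples) / config.sampling_rate
    for band, freq in BAND_FREQS.items():
        amp = np.full(n_channels, BAND_AMPLITUDES[band])
        if anxious:
            if band == "beta":
                amp = np.where(frontal, amp * scale, amp)
            elif band == "alpha":
                amp = np.where(frontal, amp / scale, amp)
        # one independent phase per channel per second: phase decoherence
        n_blocks = n_seconds + (1 if residue > 0 else 0)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, n_blocks))
        for block in range(n_blocks):
            start = block * sec_samples
            stop = min(start + sec_samples, n_samples)
            wave = np.sin(2.0 * np.pi * freq * t_sec[: stop - start][None, :] + phases[:, block, None])
            signal[:, start:stop] += amp[:, None] * wave
    signal += rng.normal(0.0, config.noise_sd, size=signal.shape)

    return EEGRecording(
        signal=signal,
        sampling_rate=config.sampling_rate,
        channel_names=config.channel_names,
        subject_id=subject_label(subject_index),
        trial_id=str(trial_index),
    )


def generate_annotations(config: SimulationConfig, anxious_flags: list[bool] | tuple[bool, ...]) -> list[SubjectAnnotation]:
    """Draw HAM-A totals and per-trial SAM ratings consistent with the flags.

    Anxious subjects get HAM-A in 21..56 and their trials SAM ratings from
    the anxious rating region (valence ≤ 5, arousal ≥ 5, carve-out
    excluded); non-anxious subjects get HAM-A in 0..20 and ratings from the
    complement. Labeling the output therefore recovers the flags exactly,
    under both schemes.
    """
    if len(anxious_flags) != config.n_subjects:
        raise ConfigurationError(
            f"need one flag per subject: got {len(anxious_flags)} flags for {config.n_subjects} subjects"
        )
    annotations = []
    for subject_index, anxious in enumerate(anxious_flags):
        rng = np.random.default_rng([config.seed, 99991, subject_index])
        hama = int(rng.integers(21, 57)) if anxious else int(rng.integers(0, 21))
        cells = ANXIOUS_SAM_CELLS if anxious else NON_ANXIOUS_SAM_CELLS
        picks = rng.integers(0, len(cells), size=config.trials_per_subject)
        annotations.append(
            SubjectAnnotation(
                subject_id=subject_label(subject_index),
                hama_score=hama,
                sam_ratings=tuple(cells[p] for p in picks),
            )
        )
    return annotations


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full cohort: all trials of all subjects plus annotations.

    Exactly ``round(n_subjects × anxious_fraction)`` subjects are anxious;
    which ones is a seed-determined permutation.
    """
    rng = np.random.default_rng([config.seed, 424243])
    n_anxious = int(round(config.n_subjects * config.anxious_fraction))
    flags = np.zeros(config.n_subjects, dtype=bool)
    flags[rng.permutation(config.n_subjects)[:n_anxious]] = True
    flags_tuple = tuple(bool(f) for f in flags)

    recordings = [
        generate_recording(config, subject_index, flags_tuple[subject_index], trial_index)
        for subject_index in range(config.n_subjects)
        for trial_index in range(config.trials_per_subject)
    ]
    annotations = generate_annotations(config, flags_tuple)
    return SimulatedDataset(config=config, recordings=recordings, annotations=annotations, anxious_flags=flags_tuple)
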