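# Methods

## Problem setting

The package targets binary anxiety detection ("anxious" vs "non-anxious")
from short consumer-grade EEG recordings. The emulated study design is an
anxiety-elicitation protocol: 23 subjects, 6 one-minute trials each,
recorded on the 14-channel Emotiv EPOC headset at 128 Hz, annotated with a
per-subject clinician scale (HAM-A, 0–56) and per-trial pictorial
self-ratings (SAM valence and arousal, 1–9). Classification operates on
1-s epochs, so each trial contributes 60 samples that inherit their
trial's (SAM) or subject's (HAM-A) label.

## Synthetic cohort generator

Real recordings of this kind cannot be redistributed, so the generator
produces structurally matched surrogates. Each trial is

    x_c(t) = Σ_b A_b sin(2π f_b t + φ_{c,b,s}) + ε,   ε ~ N(0, noise_sd²)

summed over four band-center oscillations (θ = 6, α = 10, β = 20,
γ = 35 Hz) with baseline amplitudes (1.0, 1.5, 1.0, 0.5) signal units —
an alpha-dominant resting spectrum — and white Gaussian noise
(noise_sd = 1.0). For anxious recordings the frontal channels (AF3, AF4,
F3, F4, F7, F8, FC5, FC6 — the channel set the affect equations use) get
β amplitude multiplied and α amplitude divided by 1 + effect_size/2;
effect_size = 0 makes the classes identical by construction. This encodes
the frontal beta-up/alpha-down signature that motivates band-power
features for anxiety.

**Phase handling.** A fresh uniform phase φ is drawn per channel, band and
second (index s above) rather than once per trial. Cortical rhythms hold
phase for well under a second, so minute-long phase coherence is
unrealistic; more importantly, trial-constant phases stamp every trial
with a waveform fingerprint that epoch-level splits turn into label
leakage. Measured on a balanced 6-subject cohort with effect_size = 0,
trial-constant phases let 1-NN on wavelet statistics reach 0.98 accuracy
purely by recognizing which trial an epoch came from; per-second phases
bring it to 0.46, i.e. chance. The per-second design keeps the null case
honest for phase-sensitive features.

**Annotations.** Class flags are assigned per subject
(round(n_subjects × anxious_fraction) anxious; default fraction 0.65,
matching the emulated study's epoch-level anxious share of roughly
2,700/4,140). Anxious subjects draw HAM-A uniformly from 21–56 and their
trials' SAM ratings uniformly from the 21 anxious rating cells;
non-anxious subjects draw from 0–20 and the 60-cell complement. Labeling
the generated annotations therefore recovers the generating flags exactly,
under both schemes — a property the tests check exhaustively.

**What the generator does not emulate:** ocular/muscle artifacts, 1/f
spectral background, volume conduction, inter-subject amplitude
variability, and rating noise (annotations are perfectly consistent with
the class flag). Passing tests on synthetic cohorts therefore demonstrate
pipeline correctness and calibration, not expected accuracy on clinical
recordings — with deterministic per-class amplitudes the default cohort is
far more separable than real data.

## Preprocessing

4th-order Butterworth band-pass, 4–45 Hz, applied forward–backward
(zero-phase, no sample shift; verified by cross-correlation on a test
tone). Only the band edges are part of the emulated protocol; the filter
family and order are this package's choice. Ten channels are kept (AF3,
F7, F3, F4, F8, AF4, FC6, FC5, P7, P8) and epochs are non-overlapping 1-s
windows with the trailing remainder discarded. Other sampling rates are
accepted with a logged warning, since the dyadic wavelet band map below
assumes 128 Hz.

## Wavelet features

Each epoch channel is decomposed with Daubechies-4 (db4) at 4 levels. At
128 Hz the coefficient arrays map to D1 ↔ 32–64 Hz (γ), D2 ↔ 16–32 (β),
D3 ↔ 8–16 (α), D4 ↔ 4–8 (θ), A4 ↔ 0–4 (δ). Boundary handling is
periodized, which keeps the transform orthonormal: the inverse reconstructs
the input to machine precision and coefficient energy equals signal energy
(both are enforced at 1e−8/1e−6 in the tests). Padded extension modes
remain available as an argument but are redundant at the boundaries and do
not conserve energy.

Ten statistics summarize each series: mean, median, 25th/75th percentiles
(linear interpolation), population variance, SD, RMS, zero- and
mean-crossing rates (strict sign changes of x − threshold per transition,
so both lie in [0, 1]; a sample exactly on the threshold breaks a
crossing), and the mean first difference.

**The entropy series.** Shannon entropy S = −Σ p_i log2 p_i is estimated
from a 16-bin equal-width histogram over the epoch's amplitude range
(data-relative bins, so S is shift-invariant; 16 bins is a stable choice
at 128 samples and is configurable). Summary statistics of "the entropy"
need a series, not a scalar; the package summarizes the per-bin
information sequence {−p_i log2 p_i}, whose sum is exactly S. This
convention is isolated in one function (`entropy_series`) so alternatives
can be swapped. With it, the DWT vector is 10 channels × (5 coefficient
arrays + 1 entropy series) × 10 statistics = 600 features, and 608 after
the affect block.

## Spectral features

A single-segment Hann periodogram per epoch channel (128 samples is too
short for multi-segment Welch averaging). Band powers integrate the
density by rectangle rule over half-open bands θ [4, 8), α [8, 13),
β [13, 30), γ [30, 40) Hz — half-open so adjacent bands are additive; a
band reaching Nyquist includes the endpoint bin so that the full-range
band equals total power. `average` is the mean of the four band powers
(the underlying protocol names but does not define it — documented
choice), `total` integrates the whole one-sided spectrum. 6 features × 10
channels = 60, 68 with the affect block; a flag can additionally stack the
raw per-bin spectra.

## Affect features

Eight valence/arousal quantities from frontal α/β power (formulas in the
README). Both extractors feed them: in DWT mode band power is the mean
squared coefficient of the matching array (D3 → α, D2 → β), in PSD mode
the integrated band power. The EPOC montage has no midline Fz electrode,
which three formulas reference; by default Fz power is the mean of F3 and
F4 (midline interpolation from the nearest lateral frontal sites), with
`af3_af4` and `drop_term` as alternative surrogates surfaced in
configuration rather than chosen silently. Identities enforced by tests:
A1·A2 = 1; equal band powers zero out all asymmetry features; swapping
hemispheres flips the sign of V1/V2 and fixes A1–A3.

## Balancing

SMOTE with k = 5 (clipped to minority_size − 1): synthetic rows are
uniform interpolations toward one of the k nearest minority neighbors, the
minority count is raised exactly to the majority count, originals are kept
verbatim and synthetic rows are flagged in provenance. By default SMOTE is
applied to the training split only — oversampling before splitting leaks
interpolations of test rows into training — with an explicit
`smote_before_split` option for the leakier variant.

## Classification and evaluation

Stratified 80/20 holdout (single split; a seed controls it and is recorded
in every report). All models sit behind a per-feature z-score scaler
fitted on the training split only. Hyperparameters: KNN k = 1, LDA 1
component, SVM with RBF kernel, random forest 500 trees, AdaBoost 100 tree
estimators, gradient boosting 100 tree estimators; the two boosted
ensembles can be swapped for bagged trees via `ensemble_variant` for
sensitivity analysis. Metrics: accuracy; micro-averaged recall (identically
accuracy — reported for interface compatibility); support-weighted
precision (micro precision would also collapse to accuracy); a 2×2
confusion matrix (rows = actual); ROC AUC computed as the Mann–Whitney
rank statistic of the model's continuous scores (decision function where
available, positive-class probability otherwise), undefined and reported
as missing on a single-class test set; and Cohen's κ = (p_o − p_e)/(1 −
p_e), returning 1 with a warning in the degenerate all-agree single-class
case. The full grid is 6 classifiers × {DWT, PSD} × {SAM, HAM-A} ×
{SMOTE, none} = 48 evaluations.

## Problem sizes and numerical choices

Calibration experiments (tests and the analysis drivers) use 6 subjects ×
6 trials × 10 s — 360 epochs — with PSD features and the random forest:
large enough for stable holdout estimates, small enough that the whole
suite runs in minutes on one CPU. Under those conditions the null case
(effect_size = 0, balanced cohort) yields mean test accuracy ≈ 0.52 over
20 seeds, and a strong effect (effect_size = 2) yields RF accuracy and AUC
of 1.0. The SMOTE count check uses the emulated study's printed class
sizes (1,440/2,700) directly.

Degenerate inputs are rejected rather than coerced: non-finite samples on
read, epochs shorter than the wavelet support, single-class tables for
splitting or SMOTE, non-positive band powers where the affect equations
take ratios or logarithms (the offending equation is named).

## Known limitations

- Synthetic separability is optimistic (see generator non-goals); results
  on the synthetic cohort do not forecast clinical accuracy.
- The HAM-A scheme labels every epoch of a subject identically, so
  epoch-level holdout mixes epochs of the same subject across train and
  test; a subject-level (grouped) split would be the stricter design and
  is not implemented here because the emulated protocol evaluates at
  epoch level.
- The PSD extractor's dimensionality (68) reflects the stacking actually
  defined above; the optional raw-bin stacking exists for high-dimensional
  experiments but no specific published feature count is claimed.
- Entropy summary statistics depend on the chosen per-bin information
  series; other readings of "statistics of the entropy" are plausible and
  can be swapped in via `entropy_series`.
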