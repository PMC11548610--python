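# Methods

## Signal model and preprocessing

A trial is a 6-channel inertial record of a walk with a cane: tri-axial
acceleration (m/s², VT/AP/ML) and angular velocity (deg/s) at a nominal
120 Hz. Channels are assumed already expressed in the anatomical frame;
no orientation estimation is attempted, because none is defined by the
measurement protocol and sensor fusion would add invented structure.
The reader infers the sample rate from the median time step and rejects
files whose rate disagrees with the declared one by more than 1 %, as
well as files with gaps, NaNs or non-monotonic time.

All channels pass through a 4th-order Butterworth low-pass at 10 Hz
applied forward–backward (`sosfiltfilt`). Zero-phase filtering was
chosen so that detected event times are not shifted against ground
truth; the effective amplitude response is then the *squared*
single-pass magnitude (for the digital, bilinear-transformed filter —
at 30 Hz the residual is 1/(1+3.732⁸) ≈ 2.7·10⁻⁵, not the analog
prototype's 1.5·10⁻⁴).

**Contact detection.** The jerk norm is the Euclidean norm of the
per-axis backward first difference of the filtered acceleration, scaled
by the sample rate; a backward (not centered) difference keeps impact
spikes sharp, and the first value is duplicated to preserve length.
Cane ground contacts are local maxima above mean + k·sd of the series
(k = 3 by default), accepted greedily in descending height under a
0.5 s refractory period (stride times are ≈ 1.1 s, so 0.5 s can never
merge consecutive strides) and re-sorted by time. On simulated trials
the detected peak sits one sample before the injected contact instant
(the backward difference attains its maximum on the rising edge), well
inside the ±3-sample tolerance used for validation.

**Windowing.** 512 samples (4.27 s) are cut from the first detected
contact; trials too short for that are excluded with a typed error and
counted, never silently dropped. Gait cycles are the half-open
intervals between consecutive contacts inside the window; only complete
cycles are used (a trailing partial cycle is discarded — the
alternative of padding with the partial segment was rejected because it
biases per-cycle RMS toward whatever phase the window happens to cut).

## Features

Per axis: RMS per cycle and peak |ω| per cycle, each averaged over
cycles; MPF once per trial on the full 512-sample window; plus the mean
cycle duration (stride time). The per-axis window mean is removed
before both RMS and FFT (toggleable, `remove_mean`): the VT channel
carries the ≈ 9.8 m/s² gravity component, which would otherwise
dominate the RMS and leak into the lowest spectral bins. Peak angular
velocity is unsigned (max |ω|), leaving the sign convention of the
swing irrelevant.

The power spectrum is |DFT|² of the signal multiplied by a *periodic*
Hamming window w[n] = 0.54 − 0.46·cos(2πn/L), one-sided with interior
bins doubled; bin spacing is 120/512 = 0.234375 Hz. MPF is the
power-weighted mean frequency over bins with 0.5 ≤ f ≤ 10 Hz, endpoints
inclusive — bins 3–42, so a flat spectrum has centroid 5.2734 Hz. MPF
is scale-invariant by construction, which the tests exploit (doubling
the signal doubles RMS, leaves MPF fixed).

## Group statistics

Each of the 10 features is compared between frail and robust trials
with the Mann–Whitney U test: midranks for ties, tie-corrected normal
approximation, no continuity correction (the convention of the common
commercial statistics packages), U reported as min(U₁, U₂), and effect
size r = |Z|/√N banded negligible/small/moderate/large at 0.1/0.3/0.5.
Shapiro–Wilk is computed as a screen only; the nonparametric path is
taken regardless, and no multiple-testing correction is applied across
the 10 features (protocol choice, flagged in the API docs).

For validation an exact permutation p is computed by full enumeration
of all C(n₁+n₂, n₁) labelings. Comparing a continuous normal tail with
a discrete permutation distribution is only meaningful with the
*mid-p* convention (labelings attaining the observed U contribute half
their mass); with the standard convention the gap is dominated by the
point mass at the observed value and reaches 0.05–0.09 even where the
approximation is excellent. One lattice artifact remains: when n₁·n₂ is
even, U can sit exactly at its null mean, where the asymptotic p is
exactly 1 but the discrete mid-p is 1 − P(U = μ)/2 (a ≈ 0.03 gap at
n = 12–14). Validation fixtures therefore use odd per-group sizes
(5/7/9), for which the worst gap over *all* achievable U values is
0.0194 (exhaustively verified at n₁ = n₂ = 5).

## Classification

Five families, matching the stated protocol hyperparameters: decision
tree with at most 5 splits (6 leaves), LDA, k-NN (k = 5 default), RBF
SVM, and logistic-loss gradient boosting of depth-1 trees with 243
cycles at learning rate 0.59256. k-NN and SVM see z-scored features
(sample sd, n−1), with the scaler fitted on each training split only —
a deliberate deviation from whole-dataset normalization, which leaks
test-fold statistics; a caller can reproduce whole-dataset scaling by
pre-transforming the table.

Folds are tenfold, trial-random by default: trials of one subject may
land in training and test folds, reproducing the reference protocol.
The subject-grouped mode is the methodologically sound alternative, and
`experiments.leakage_comparison` measures the optimism gap between the
two (≈ 5 percentage points of accuracy on default synthetic cohorts
with a 1-NN probe). On *null* cohorts (identical group presets) the
same leakage lifts trial-random AUC slightly above chance (≈ 0.56 mean
across models); this is a property of the protocol, not a bug, and is
why the null-cohort tolerance is 0.5 ± 0.15.

Metrics: accuracy, precision, recall, F1 (harmonic mean), per fold and
averaged over folds, AUC per fold averaged over folds where the test
fold contains both classes; plus the aggregated confusion matrix over
all held-out predictions (its total is exactly the trial count) with
metrics recomputed from it, and a pooled ROC. Fold-averaged and
aggregated conventions disagree slightly on unbalanced folds, so both
are reported. Ratios with zero denominators are reported absent
(None), never coerced to 0. AUC uses the midrank form — the probability
a random positive outscores a random negative with ties counted ½ — so
a constant-score predictor yields exactly 0.5. The positive class
defaults to "frail"; the published confusion tables are oriented with
the majority (non-frail) class positive, and the arithmetic
cross-checks use that orientation.

Hyperparameter search is randomized (default budget 30 draws, seeded,
default configuration always evaluated first) minimizing mean CV
misclassification on the same folds used for reporting (non-nested, as
in the reference protocol); protocol-fixed values are never searched.

## Synthetic cane gait

Each acceleration axis is Σₖ wₖ·a_axis·sin(2πk·φ(t) + φₖ) with four
harmonic weights summing to 1, where the phase φ advances by one per
stride (piecewise-linear through the contact times); stride periods are
i.i.d. normal, truncated at ±3 sd (defaults 1.10 ± 0.05 s). At each
contact an exponentially decaying pulse (peak 12 m/s², τ = 50 ms,
coupled 1.0/0.35/0.20 into VT/AP/ML) models the cane strike; gravity is
added to VT; white Gaussian noise (0.15 m/s², 1.5 deg/s) models the
sensor. Angular velocity is a raised-cosine bump per stride scaled to
the per-axis peak (defaults 30/100/40 deg/s VT/AP/ML) — no cane
kinematic model is claimed, only a smooth unimodal swing. Every trial
carries its ground truth: contact indices, stride times, and features
computed by the reference pipeline on the noiseless twin signal.

Cohorts default to 14 frail / 31 robust subjects with 37 / 94 trials
(2–4 per subject). Subject-level log-normal multipliers (sd 0.1 on
amplitudes, 0.03 on stride time) correlate trials within a subject;
trial-level jitter (sd 0.05) keeps them from being identical. Group
labels follow the assigned preset; 5-item questionnaire responses are
drawn per subject (negative-answer probability 0.85 frail / 0.15
robust) so the ≥ 3-negative-answers rule reproduces the intended label
for ≈ 97 % of subjects, and the questionnaire-derived label is kept as
a separate column.

The frail preset (data/presets.yaml) has smaller VT/AP amplitudes and
impact, a smaller AP swing peak, and VT harmonic weight shifted upward.
The amplitude deltas are *calibrated, not fitted*: chosen once so that
default cohorts give a mean VT-RMS effect size near r = 0.36 with the
expected sign pattern (frail VT/AP RMS lower, VT MPF higher) in ≈ 98 %
of seeds. Two presets support testing: `zero_signal` (identical groups)
and `well_separated` (exaggerated differences, longer frail stride).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: cane–body coupled dynamics, turning,
terrain, within-trial fatigue drift, sensor bias/drift, or realistic
feature covariance beyond a shared amplitude factor. Two known
artifacts: (i) because the impact amplitude differs between groups
while a_ML does not, the impact's broadband contribution induces a
secondary group difference in ML/AP MPF that the real data does not
report; (ii) synthetic cohorts are more separable than the human
cohort, so absolute classification accuracies here say nothing about
clinical performance — only the relative behaviour (leakage ordering,
null calibration) transfers.

## Numerical and degenerate-input conventions

Indices are 0-based, intervals half-open. Windows shorter than the
filter pad length, empty segments, all-tied samples, single-class
training splits, zero in-band power and contactless trials all raise
typed errors. Feature tables round-trip at 12 significant digits
(≤ 1e-9 relative). Everything stochastic flows from explicit integer
seeds via `numpy` `SeedSequence` spawning (per subject, per trial, per
stage), so identical (config, seed) reproduce artifacts byte for byte.

## Validation problem sizes

The shipped validation suite uses 50 trials for contact recall, 100
cohorts at the reference composition for effect-size recovery, 100
two-sample fixtures for the exact-vs-asymptotic comparison, and 20
cohorts each for the null-AUC and leakage studies — sizes at which the
binomial/seed-to-seed uncertainty of each estimate is several times
smaller than the tolerance it is checked against.
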