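# Methods

## Problem and model

`ripsleep` estimates a three-class hypnogram — WAKE, REM, NREM at 30-s
epoch resolution — from three channels a home sleep apnea test records
without EEG: thoracic and abdominal respiratory inductance plethysmography
(RIP) belts and an actigraphy (movement) channel. The physiological basis
is that breathing is metronomic in NREM sleep, irregular in REM sleep, and
most variable in wake; thoraco-abdominal coupling weakens in REM; and
gross body movement is concentrated in wake. Accurate sleep/wake staging
in turn fixes the denominator of the summary metrics that drive clinical
decisions: total sleep time (TST), sleep efficiency (SE), and the
apnea-hypopnea index (AHI = respiratory events per hour of sleep).

The classifier is a sequence model over epochs. Each epoch contributes a
14-dimensional feature vector (below); the model input for target epoch
*i* is the window of epochs *i−22 … i+2* (22 past, the current epoch, 2
future; 25 steps). Three dense layers of 70 ReLU units are applied per
time step, a GRU with 50 units consumes the resulting 25-step embedding
sequence, and a 3-unit softmax layer on the final GRU state yields the
stage posterior for the target epoch (read at window position 23, giving
the recurrent state two epochs of lookahead). The GRU uses sigmoid
update/reset gates with a ReLU candidate activation, consistent with the
ReLU hidden layers; a `tanh` switch is provided. Dropout of 0.22 is
applied after each dense layer and on the GRU output during training only
— at prediction time the network is fully connected.

Record edges are replicate-padded so window count always equals epoch
count: every epoch of a night is classified, which matters because TST is
computed over the whole record.

## Features (fixed schema, 14 columns)

Per belt (thorax, abdomen): mean and SD of breath amplitude within the
epoch, the epoch's raw-signal SD, and the absolute change of mean breath
amplitude versus the previous epoch (0 for the first epoch, which has no
predecessor). Across belts: the Pearson correlation of the two raw
signals over the epoch (cos-of-phase-lag for ideal sinusoids, hence a
direct coupling readout). From thoracic breath timing: the SD of breath
duration and the respiratory rate (60 / mean breath duration, breaths per
minute — the mean duration itself would be exactly redundant with the
rate and is not a separate column). From actigraphy: epoch mean, SD and
maximum. Epochs are 0-based, half-open `[30i, 30(i+1))` seconds.

Breath detection: the belt signal is band-passed to 0.1–0.7 Hz
(order-2 Butterworth, zero-phase), and inspiratory peaks are picked with a
minimum spacing of 1.5 s and a prominence threshold of 10% of the local
30-s segment's robust (1st–99th percentile) range, with a floor of 2% of
the whole-record robust range. The per-segment threshold keeps detection
robust under strong slow amplitude modulation; the floor keeps near-flat
(apneic) stretches from promoting sensor noise to breaths. Breath
amplitude is peak minus preceding trough on the filtered signal; duration
is the peak-to-peak interval. Epochs with no detected breath get zero for
all breath-derived features; after normalization zero is simply a very low
value, which is informative (apnea), not a sentinel.

Normalization is per study: each feature column has its median subtracted
and is divided by its interquartile range (linear-interpolation
quartiles), which removes subject- and gain-dependence without being
dragged by movement outliers. A column with IQR = 0 is centered and left
at zero. A `normalized` flag guards against double application.

## Training recipe

Class-weighted categorical cross-entropy (wake 1.0, REM 0.7, NREM 0.6 —
down-weighting the prevalent sleep classes), Adam at learning rate 1e-4
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8, recorded in the training log), batch
size 120, a fixed number of training epochs with no early stopping
(default 50), and 5-fold cross-validation with 80/20 splits at the
*recording* level, so no night is ever split between training and
validation. The returned weights are the fold with the highest final
validation kappa. Gradients are clipped at global norm 5 — a guard the
ReLU-candidate GRU occasionally needs early in training. Weights use
Glorot-uniform initialization and float32 arithmetic; gradients are
hand-derived backpropagation-through-time, verified against central
finite differences in float64 in the test suite.

The network is implemented directly in NumPy (forward, BPTT, Adam,
dropout); it is a compact, dependency-light implementation sized for this
architecture rather than a general deep-learning layer library.

## Synthetic data: what it emulates, and what it does not

The generator provides ground-truthed recordings so every stage of the
pipeline is testable without patient data.

* **Architecture**: a first-order Markov chain over {WAKE, REM, NREM} at
  the epoch level. The default transition matrix has 0.9 self-transitions
  with wake resolving mostly into NREM and REM entered mostly from NREM,
  giving bout structure worth a recurrent model's while.
* **Breathing**: each breath is one sinusoidal cycle; its period and
  amplitude are redrawn per breath from the current stage's distribution.
  Defaults (breaths/min): WAKE 15 ± 2.8, REM 15.5 ± 1.8, NREM 13 ± 0.6 —
  ordering regularity NREM > REM > WAKE. Amplitudes ~1 a.u. with stage-
  dependent jitter. The abdominal belt lags the thoracic belt by a
  stage-dependent phase (NREM 0.15, WAKE 0.4, REM 1.1 rad — REM has the
  weakest coupling, a paradoxical-breathing analog).
* **Movement**: near-zero noise plus Poisson-timed Gaussian bursts; burst
  rates 6/min in WAKE versus 0.3 (REM) and 0.15 (NREM) per minute, so a
  single threshold on epoch activity variance separates wake from sleep —
  the learning problem is solvable by construction, and a test asserts it.
* **Events**: apneas/hypopneas are multiplicative amplitude dips on both
  belts (×0.05 apnea, ×0.5 hypopnea) lasting 10–30 s, placed uniformly in
  contiguous sleep with rejection of overlaps, with count pinned to
  `round(target_AHI × sleep_hours)`. Additive Gaussian sensor noise has
  SD equal to 5% of the stage's mean amplitude.
* **Cohorts**: per-subject target AHIs are spread linearly across the
  requested range (default 0–45/h, covering all four severity groups);
  per-subject seeds are spawned from the master seed, so cohorts are
  reproducible element-wise.

Not emulated: N1/N2/N3 substructure, body-position effects, cardiac or
oximetry signals, belt displacement artifacts, inter-subject anatomy, and
the scorer noise of real manual staging. Synthetic stages are therefore
*more* separable than real ones: passing the end-to-end checks shows the
pipeline — features, normalization, windowing, optimization, evaluation —
works as designed, not that the trained weights would transfer to
patients. Agreement statistics on synthetic cohorts are accordingly
higher than one should expect clinically.

## Evaluation battery

Pooled 3×3 confusion matrix and Cohen's kappa
(κ = (p_o − p_e)/(1 − p_e)) across all test epochs; one-vs-rest
sensitivity/specificity per stage; per-subject TST (0.5 min × sleep
epochs), SE (100 × TST / analysis duration) and AHI (events per hour of
sleep — the event list is an input; only the sleep-time denominator is the
algorithm's contribution, so the estimated AHI is scored events divided by
*estimated* TST). Method agreement per metric: Pearson r and Bland-Altman
bias ± 1.96 SD limits of agreement, with bias = estimate − reference
(positive = overestimation). AHI severity groups use half-open bins
[0,5), [5,15), [15,30), [30,∞) → 1–4, with per-group one-vs-rest
sensitivity/specificity. Sleep-onset agreement binarizes both hypnograms
to sleep/wake over the 21 epochs centered on the reference's first sleep
epoch (truncated at record boundaries, never padded) and reports the 2×2
table, sensitivity, specificity and F1. Mann-Whitney U (exact enumeration
for both n ≤ 8 without ties, else continuity-corrected normal
approximation with midranks) and Kruskal-Wallis (tie-corrected, χ²
reference) compare estimation errors across severity groups. Statistics
that are undefined — AHI at TST = 0, Pearson r below 3 pairs or at zero
variance, sensitivity of an empty group — are reported as explicit
undefined markers, never as 0.

## Numerical and design choices

* Stage order everywhere is (WAKE, REM, NREM); labels are upper-case
  strings at the API surface, integer indices internally.
* Dense layers are applied per time step (not on the flattened window);
  this is the reading under which a recurrent layer is meaningful.
* Per-sample class weights multiply the loss and are mean-reduced without
  renormalization.
* Network inputs are saturated at ±25 IQR units (training and prediction
  alike). Median/IQR scaling is robust to outliers in the *statistics*
  but passes the outliers themselves through: one movement burst in an
  otherwise motionless night can sit thousands of IQRs from the median,
  and values that large destabilize ReLU activations while carrying no
  information beyond "far out". Stored feature matrices are not clipped.
* Model files are a single zip archive holding the weight arrays (npz)
  plus JSON metadata: configuration, the ordered feature schema, and the
  training log. Save → load → predict is bit-identical, and prediction
  refuses features whose schema (names or order) differs from the model's.
* EDF: reading goes through MNE (channels located case-insensitively via
  a configurable channel map; mixed-rate files come back on the highest
  rate present). Writing is a minimal built-in EDF encoder (16-bit
  samples, 1-s records); physical ranges are stored as 8-character
  decimal strings and the *parsed-back* values are used for quantization,
  so a round trip is exact to 16-bit resolution.
* The default end-to-end study size is 20 subjects × 480 epochs (4 h)
  with 6 held out and 15 training epochs: the smallest configuration at
  which the recipe converges comfortably to substantial agreement on one
  CPU in a few minutes. Held-out subjects are taken at evenly spaced
  positions along the cohort's AHI ramp so the test population spans all
  four severity groups. Larger cohorts and the full 50-epoch recipe are a
  parameter change away.

## Known limitations

Half-hour-scale phenomena (sleep-onset REM, long wake after sleep onset)
occur only as often as the Markov chain happens to produce them; the
generator has no circadian trend or sleep-pressure dynamic, so a night's
"sleep onset" is occasionally an isolated two-epoch bout that a
temporal-context model rightly smooths over — per-cohort sleep-onset
summaries are therefore the most seed-volatile numbers the battery
produces. The breath-by-breath sinusoid has no
inspiratory/expiratory asymmetry, so flow-shape features would be
meaningless here — they are also out of scope. Training at learning rate
1e-4 needs a few hundred optimizer steps before validation kappa moves
away from chance; very small toy datasets will look like failures to
converge when they are merely short of steps.
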