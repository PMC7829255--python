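# Methods

This note documents the models, the synthetic data generator, the
numerical choices and the known limitations of `fuseload`.

## Problem setting

A participant solves a sequence of logic puzzles of graded difficulty
while four physiological streams are recorded through a multi-device
streaming layer, each with its own clock and nominal rate (GSR 256 Hz,
PPG 256 Hz, eye tracking 120 Hz, fNIRS 10 Hz), and the puzzle GUI emits
a marker for every user action. After each puzzle the participant rates
its difficulty on a 7-point scale. The task is to regress that
*perceived* workload from the 8 seconds of multimodal signal preceding
each action marker.

## Data path

**Containers.** Recordings are stored in a portable HDF5 layout with
XDF stream semantics: per-stream `timestamps`/`samples` datasets with
nominal-rate and channel metadata, plus a marker table. On read, the
realized rate ((n−1)/span) is compared against the declared rate; a
deviation beyond a configurable tolerance (default 1 %) triggers
de-jittering, which replaces the timestamps by their least-squares
uniform grid t₀ + k·Δ (deterministic, idempotent, values untouched).

**Clock audits.** Per-stream drift is defined as |realized span −
(n−1)/nominal rate|, reported in ms with session mean/SD. This is one
of several defensible definitions (pairwise stream offsets are another);
it was chosen because it is computable from any single recording.
Missing-data gaps are detected as inter-sample intervals exceeding both
an absolute floor (0.2 s) and 5× the median interval, so ordinary
jitter cannot trigger them.

**Segmentation.** A marker is usable only if (a) its nearest sample
index is unique among all markers in *every* signal stream — colliding
markers are all removed, symmetrically, since identical indices signal
clock drift or missing data; (b) every stream has a full window before
it; (c) its window does not straddle a detected gap. Windows are 8 s
because the haemodynamic response peaks 5–8 s after neuronal onset, and
they *precede* the marker because the contemplation happens before the
action. The window ends at the sample at-or-before the marker time
(whether the marker sample itself is included is unspecified in the
source design; at-or-before is this package's documented convention).
Row counts at native rates: 2048 (GSR), 2048 (PPG), 960 (ET), 80
(fNIRS). Overlapping windows from distinct non-colliding markers are
permitted. Quality statistics (per-channel mean/var/max/min) are
advisory; noisy samples are reported, never removed.

**Labels.** Individual scheme: label = (r − 1)/6 for rating r ∈ 1..7,
i.e. seven equidistant labels with level width 1/6. (The inverse — the
printed formula with a denominator of 7 in the source material — is
inconsistent with its own worked values, which this package follows.)
Group scheme: per-puzzle mean ratings min–max normalised, giving one
generally non-equidistant label per puzzle. Rating consistency is
summarised by Cronbach's α = k/(k−1)·(1 − Σ item variances / variance
of item sums), with sample variances and listwise deletion of missing
rows; either puzzles or participants can serve as items.

## Architectures

Layer widths follow the published table exactly; `S_` variants halve
every width (floor division). The per-modality projection widths are
PPG 256, GSR 256, ET 1024, fNIRS 2048, so the all-modality fused width
is 3584; the Head's first dense layer tracks the fused width of the
enabled subset. Concatenation order is fixed as (PPG, GSR, ET, fNIRS).

Details the published description leaves open, resolved as follows:

* 1-D convolutions along time (channels as feature maps), kernel 3,
  stride 1, 'same' padding; max-pool 2 after each conv block.
* Batch normalisation after each convolution, before the ReLU.
* Hidden activations are ReLU; only the output unit is sigmoid.
* The GSR LIT branch stacks two LSTMs: the first returns full
  sequences, the second its final state.
* The LIT Head's convolutions operate on the preceding dense output
  reshaped to a (length × 1) sequence — the only structure consistent
  with the printed layer order.
* Dropout (HPO-sampled rate) follows each hidden dense layer; the
  projections and output are never dropped.
* ET input is raw gaze coordinates; fNIRS input stacks the 54
  chromophore channels as features.

The network engine (dense/conv/pool/batch-norm/LSTM layers with
explicit backpropagation, SGD with classical momentum) is a compact
numpy implementation, verified against central-difference gradients to
~1e-10 relative error in float64.

## Training

Loss is MSE between sigmoid output and label — chosen over
cross-entropy because labels are ordinal, so the *distance* of a
misclassification matters. The 1Cycle policy is a single triangular
cycle across all training steps: linear ramp from lr_max/10 to lr_max
at the midpoint and symmetrically back. Defaults: lr_max 0.05, momentum
0.9, batch 32. Inputs are standardised per channel with training-set
statistics; the scaler travels with the trained model. Training is
deterministic given the seed (seeded shuffling and initialisation,
single-threaded BLAS).

Cross-validation is 5-fold with a fresh model and a fresh seed per
fold; the objective is the mean over folds of the test-fold mean
absolute label error. The holdout mode uses a seeded random 90–10
split. Hyperparameter search samples learning rate (log-uniform in
[1e-4, 1e-1]), dropout ([0, 0.5]), momentum ([0.5, 0.99]) and variant
(categorical) — ranges are conventional brackets, fully configurable —
using either a random sampler or a from-scratch Tree-structured Parzen
Estimator (quantile split γ = 0.25 after 5 random startup trials,
Gaussian Parzen mixtures with a uniform prior component, 24 candidates
scored by l(x)/g(x)).

## Evaluation

Mean absolute label error; LoW = 6 × error; within-k-level fractions;
signed-error histograms (bin width 1/24, i.e. four bins per level) with
μ and σ; nearest-label confusion matrices (ties snap to the lower
label) with row-relative proportions, accuracy and off-by-one accuracy.
Chance baselines come in two modes: the uniform approximation
(2k+1)/n — which gives the conventional 3/7 ≈ 43 % for off-by-one on
seven classes — and an exact edge-aware enumeration (19/49 ≈ 38.8 %)
that accounts for edge classes having fewer neighbours. The uniform
approximation is the default for report parity. The ablation runner
trains one model per (variant, modality subset) on the 90–10 holdout,
reusing tuned hyperparameters per variant, and always includes the
all-modality reference.

## The synthetic generator

The simulator produces sessions with the statistical structure the
pipeline assumes, *not* biophysically accurate signals:

* **GSR** — tonic level (8 µS) plus slow sinusoidal drift, plus
  Poisson-timed phasic SCRs (exponential rise 0.75 s / decay 3 s,
  log-normal amplitudes around 0.4 µS); both SCR rate
  (4 + 3·d events/min) and tonic level rise with difficulty d.
* **PPG** — two-harmonic pulse at instantaneous heart rate
  68 + 2.5·d bpm plus 1/f heart-rate variability; pulse amplitude
  shrinks slightly with d (sympathetic vasoconstriction).
* **fNIRS** — difficulty boxcar convolved with a peak-normalised
  double-gamma HRF (peak 6 s, undershoot ratio 1/6), per-channel
  sensitivities in [0.3, 1], HHb = −0.5 × O₂Hb plus noise. Noise has a
  deliberately *shared* systemic 1/f component across optodes (cardiac/
  respiratory/Mayer-wave physiology) plus per-channel instrumental 1/f
  noise, so spatial averaging cannot cancel it: per-trial SNR is low,
  as in naturalistic non-block designs.
* **ET** — fixation/saccade alternation; fixation rate rises and
  fixation scatter tightens with d; both eyes share the fixation point
  with a small interocular offset.

Markers are Poisson-timed within puzzle intervals at 3 + 0.8·d
actions/min, so a default session (5 puzzles × 10 min) yields on the
order of 100–300 markers, matching the per-participant sample range of
the motivating study. Ratings are a linear map of difficulty 1..5 onto
1..7 plus participant bias and Gaussian noise (SD 0.5), rounded and
clipped. Clock jitter, per-stream drift and missing gaps are applied
after clean generation, so ground truth refers to the undistorted
clock. Identical config + seed gives bit-identical output.

Effect sizes are free parameters (the study reports none); the defaults
were chosen once so that each modality carries *partial, noisy*
information about difficulty with roughly the qualitative unimodal
ordering the study observed (cardiovascular and electrodermal channels
informative, fNIRS weakest) — so that multimodal fusion has genuine
complementary structure to exploit. Consequently, passing learning
tests show that the pipeline can extract and fuse cross-modal workload
structure of this kind; they do not certify performance on real
recordings, whose artifacts (motion, optode decoupling, blinks,
nonstationarity) the generator does not emulate.

## Problem sizes used in tests

Unit tests run on seconds-long sessions and millimetre-scale networks.
The learning-behaviour tests use the package's reduced-scale study
conditions: 4 simulated participants × 5 puzzles × 240 s (~450
samples), S_MLP at one-quarter widths (`width_scale=0.5` on the
half-width variant), 10 epochs per fold, seeds 1–5. The overfit check
memorises 32 samples for 200 epochs. These sizes keep the full suite in
the minutes range on a single CPU while preserving the properties being
tested.

## Known limitations

* No artifact correction (motion, hair, blinks) and no per-modality
  asymmetric windows.
* The drift definition is one of several possible readings; absolute
  per-stream span deviation was chosen and documented.
* TPE here is the standard algorithm but a minimal implementation: no
  pruning, no multivariate kernels, no nested CV.
* Real-recording ingestion expects the package's HDF5 dialect; native
  XDF files must be converted first.
* LSTM training over long sequences is slow in pure numpy; LIT variants
  at full width are compute-hungry and best reserved for small studies.
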