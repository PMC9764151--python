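# Methods

## Problem and labelling

The package classifies single-lead ECG beats as hyperkalemic or
normokalemic, then aggregates beats to a record-level call by majority
vote. Labels come from the serum potassium paired with each record:
above 5.5 mEq/L is hyperkalemia, 3.5–5.0 mEq/L is normokalemia, and the
band (5.0, 5.5] is excluded so that no beat can plausibly belong to both
classes. Boundary conventions are explicit because the interval endpoints
are otherwise ambiguous: 5.0 is still normokalemic, 5.5 is excluded
("above 5.5" read strictly), and values below 3.5 (hypokalemia) are
excluded as out of scope.

## Synthetic cohort model

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T), parameterized
by amplitude (mV), center (fraction of the RR interval) and width
(seconds). This is deliberately simpler than full dynamical ECG
simulators: every severity effect has a closed-form consequence that
tests can check analytically (e.g. T-peak amplitude scales exactly by
1 + cT·s).

Potassium maps to a severity score s ∈ [0, 1], piecewise linear from 5.0
to 7.0 mEq/L. No quantitative ECG-versus-potassium dose–response is
established in the literature this emulates, so the map is a modelling
choice, flagged as such: its onset coincides with the exclusion band's
upper edge (so normokalemic records have s = 0) and it saturates at
7.0 mEq/L, consistent with per-record potassium draws being capped at
8.0 mEq/L (class means ~6.3 (SD 0.64) hyper, ~4.3 (SD 0.40) normo,
truncated to the class bands). At severity s the renderer applies the
classic hyperkalemic changes: T amplitude × (1 + 0.8 s), T width
× (1 − 0.3 s), QRS wave widths × (1 + 0.4 s), P amplitude × (1 − 0.6 s),
P-to-R spacing × (1 + 0.25 s). The coefficients are per-subject fields,
jittered log-normally like the rest of the profile.

Between-subject heterogeneity — the phenomenon personalization exists to
overcome — enters as multiplicative log-normal random effects (sd =
`subject_spread`) on wave amplitudes and widths, noise levels and severity
coefficients, and small additive shifts on wave centers (clamped to keep
the P < Q < R < S < T ordering). Records add a respiration-like baseline
wander sinusoid and white noise. Per-subject generators are spawned from
the master seed via `SeedSequence(seed, spawn_key=(subject_index,))`, so
cohorts are bitwise reproducible and growing the cohort never perturbs
existing subjects.

Two named regimes are used throughout the tests:

- `separable_config`: spread 0, noise 0 — classes separable from T
  morphology alone; used for pipeline sanity checks.
- `heterogeneous_config`: spread 0.5 — chosen so that the between-subject
  variance of the normokalemic T-peak amplitude clearly exceeds the
  within-subject variance (the package's operational definition of
  "strong heterogeneity", asserted as a generator invariant).

What the generator does **not** model: arrhythmias (excluded in the
study design anyway), respiration coupling of RR intervals, electrode
artefacts, drug effects, or any within-subject drift of baseline
morphology over time. Passing tests on this cohort therefore demonstrate
that the pipeline machinery is correct and that personalization recovers
subject-specific decision boundaries under controlled heterogeneity —
not that the trained weights transfer to clinical waveforms.

## Preprocessing

- Excerpt: the (up to) 600 s before each lab draw; shorter coverage is
  used in full and flagged.
- Filter: zero-phase (forward–backward) FIR band-pass 0.5–40 Hz, 255 taps,
  Hamming window — a standard monitoring band.
- Quality control replaces manual noise inspection with three rules on
  the raw excerpt: flat/clipped fraction > 0.1; out-of-band to in-band
  power ratio > 0.5; RR coefficient of variation > 0.25 (a surrogate for
  excluding rhythms without an identifiable beat cycle, e.g. atrial
  fibrillation). QC runs **before** filtering: after a 0.5–40 Hz
  band-pass there is no out-of-band power left to measure. The ratio is
  out-of-band over *in-band* power rather than over total power because at
  a 125 Hz sampling rate the monitoring band covers 63% of the Nyquist
  range, so the out-of-band share of total power saturates near 0.37 even
  for pure white noise and could never cross a 0.5 threshold.
- R-peak detection is a Pan–Tompkins-style chain (5–15 Hz band-pass,
  five-point derivative, squaring, 150 ms moving-window integration,
  adaptive signal/noise thresholds, 200 ms refractory period) with the
  fiducial refined to the local maximum of the input signal. On clean
  synthetic records it scores ≥ 0.99 precision and recall against
  generator ground truth.
- Beats are [r − 40, r + 80) windows of the **filtered** signal: 120
  samples, R peak at the 41st (1-based); peaks too close to a record edge
  are dropped. Indices are 0-based internally.

## Network

`resnet50_1d` follows the canonical ResNet-50 table with temporal
convolutions: stride-2 stem (kernel 7, width 64), 3×3-kernel max-pool,
four stages of pre-activation bottleneck blocks laid out (3, 4, 6, 3)
with base widths (64, 128, 256, 512) and 4× expansion, then a final
norm–ReLU, global average pooling and a 2-class fully connected head.
Counting stem + main-path convolutions + head gives 50 weighted layers
(projection shortcuts are not counted, per convention). Inside each block
the ordering is batch-norm → ReLU → convolution. A 120-sample beat
reaches temporal length 4 at the last stage, which sets the resolution of
the saliency maps.

`resnet18_1d` (basic blocks, 18 weighted layers, optional `width_scale`)
exists so that the full pipeline trains in minutes on one CPU; all
pipeline code is variant-agnostic. Desk-scale runs here use
`width_scale=0.25` (stage widths 16–128).

Everything is implemented over numpy in float32 with explicit backward
passes (im2col convolutions, batch-norm with running statistics, max-pool
argmax routing, Adam). Gradient correctness is enforced by
finite-difference checks in the test suite (run in float64). Batch-norm
statistics are frozen in evaluation mode, so majority-vote inference is
deterministic.

## Training

Defaults mirror the population-scale protocol: Adam with default moment
parameters at 5 × 10⁻⁵, mini-batch 1024, 50 epochs, rate halved when the
validation loss has not reached a new minimum for 3 consecutive epochs
(the stale counter resets on improvement and after each reduction), and
the checkpoint with minimal validation loss kept. The 6:2:2 split is at
subject level — the population counts reported for the original cohort
(881/280/278 patients) indicate patients, not beats — with sizes set by
largest remainder, so no subject contributes to two partitions. Beats are
class-balanced by seeded downsampling of the majority class.

Desk-scale runs (tests, reproduction script) override batch size, rate
and epoch budget to `batch_size=32, learning_rate=1e-3, max_epochs≤5`:
the scaled cohorts yield ~50–500 optimizer steps where the full protocol
assumes ~15,000, and Adam's default rate is the appropriate step size for
that budget. The study-protocol values remain the `TrainConfig` defaults.

## Personalization

Eligibility requires ≥ 8 records per class. Per class, ⌈0.25 · n⌉ records
are held out (so every eligible subject keeps ≥ 2 holdout records per
class, enough for record-level AUC). The pretrained head is replaced by a
freshly initialized one; the stem and first three residual stages are
frozen — weights, batch-norm affine parameters and running statistics
alike (frozen stages always run in evaluation mode), so frozen arrays are
bitwise invariant across rounds, which the tests assert. "First few
blocks" is not quantified in the protocol this follows; 3 of 4 stages is
the default and the knob is exposed (`frozen_stages`).

Each round draws one unused record per class (seeded order, without
replacement — no acquisition function is specified for the "active"
selection, so fixed paired rounds are used), fine-tunes for 5 epochs and
evaluates the fixed holdout; at most five rounds. The fine-tuning rate
defaults to Adam's 1e-3 rather than the generic 5 × 10⁻⁵: a random head
trained for a few dozen steps at 5 × 10⁻⁵ cannot leave its
initialization, and no fine-tuning rate is stated in the protocol.
Round 0 records the pretrained model's baseline on the same holdout.

## Evaluation and statistics

Hyperkalemia is the positive class. Record class = majority of beat
classes; an exact tie resolves to hyperkalemia (sensitivity-favouring —
a deliberate clinical asymmetry, and a knob reviewers should know about).
The record-level score for AUC is the mean per-beat hyperkalemia
probability (vote fraction available via `score_mode`). AUC uses the
rank (Mann–Whitney) formulation with ties counted ½; the Mann–Whitney U
test is exact by full enumeration of group assignments up to 12 pooled
observations (mid-ranks for ties) and a tie-corrected normal
approximation with continuity correction beyond. Round-versus-baseline
comparisons in `aggregate_rounds` use the unpaired test (matching the
named test; a paired alternative would also be computable from the same
table). Undefined ratios (no positives or no negatives in the truth) are
reported as missing, never as zero.

## Interpretation

Grad-CAM weights each last-stage channel by the temporal mean of the
class-score gradient, rectifies the weighted activation sum, linearly
interpolates the length-4 map to 120 samples and normalizes by the
maximum (skipped when the map is identically zero, e.g. a zeroed head).
The normalized map is invariant to positive scaling of the class logit
path. t-SNE of the global-average-pooled last-stage features is
delegated to scikit-learn with a fixed random state; this module owns
only the shape, precondition (n > 3 · perplexity) and determinism
contracts.

## Numerical and degenerate-input choices

- Truncated-normal potassium draws use rejection sampling; a
  mean/sd/band combination that rejects 10,000 consecutive draws is an
  error, not a silent fallback.
- `render_beat` refuses windows shorter than 20 samples; flatline input
  to the detector returns an empty peak list (not an error).
- Wave-center jitter is clamped to preserve strict P < Q < R < S < T.
- Checkpoints are a JSON spec plus one `.npy` file per named array;
  loading copies every array, so a model can never alias (and silently
  mutate) the checkpoint it came from.
- Determinism: all randomness flows through `numpy` generators seeded
  from explicit seeds (per-subject and per-stage sub-seeds via
  `SeedSequence` spawn keys); repeated runs reproduce waveforms and
  metrics bitwise in single-threaded execution.

## Scaled problem sizes

The bundled experiments use 30 s records at 125 Hz (≈ 35 beats per
record), a 24-subject generic population with 2 records per class, and an
8-subject personal cohort with 8 records per class — the smallest sizes
at which the phenomena of interest (heterogeneity-induced baseline
failure, round-two plateau) are stable across seeds. The record duration
and all cohort dimensions are configuration fields; the 10-minute excerpt
window and the 120-sample beat geometry are fixed by the study design.

## Known limitations

- The severity map is monotone and piecewise linear; real dose–response
  is patient-dependent and nonlinear, and severe hyperkalemia beyond
  8 mEq/L (sine-wave ECG) is outside the model.
- The generator's heterogeneity is stationary within subject; drift
  between a subject's records would make the round-based schedule harder
  than tested here.
- QC thresholds are surrogates for human review and were chosen for the
  synthetic noise model, not tuned on clinical artefacts.
- WFDB binary waveform files are not read or written; waveform exchange
  uses the package's documented CSV dialect.
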