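# Methods

## The screening problem and the data model

Each subject contributes four 201-point complex S-parameter spectra — the
transmission coefficient S21 and reflection coefficient S11, for the left
and right wrist — on a linear frequency grid from 300 kHz to 2 GHz, plus
age (years), BMI (kg/m²) and both wrist circumferences (cm). Instruments
record magnitude (linear) and phase (degrees); internally everything is a
complex array, phase in radians, never unwrapped (the complex
representation encodes the wrapped phase exactly, and downstream encodings
consume either the complex values or their wrapped argument). Only S21
feeds the classifier; S11 is carried so cohort files are complete
instrument exports. The grid start frequency is configurable; 300 kHz is
the default because that is the instrument's sweep start, and a
`n_points`/grid override on the readers accepts other layouts.

Classification is binary: group 1 (osteopenic/osteoporotic, DXA T-score
below −1) is the positive class; group 2 is healthy. All reported metrics
derive from TP/FP/TN/FN tallies under that convention.

## Feature assembly

Four encodings of a length-n complex spectrum: `magnitude` (n features),
`phase` (n, radians in (−π, π]), `mag_phase` (2n, magnitudes then phases),
`complex_reim` (2n, all real parts then all imaginary parts). Three arm
modes: `average` (pointwise complex mean across arms before encoding),
`concatenate` (left then right encoded spectra), `separate` (two vectors
per subject). Circumference, when included, is appended raw in cm — the
arm's own in separate mode, the mean in average mode, both in concatenate
mode — and is never scaled by the Age/BMI normalization.

The Age/BMI normalization multiplies the *complex* spectrum by the scalar
Age/BMI before encoding. Consequences asserted by tests: it commutes with
the magnitude and real/imaginary encodings (scale-covariant) and is a
no-op on phase features (the factor is real and positive). Applying it to
the complex values is the literal reading of the normalization's
definition; the alternative (scaling magnitude features only under a
mag/phase encoding) would give identical magnitude features and is not
separately exposed.

No feature standardization (z-scoring) is applied before training; the
training toolbox the original analysis used applies none by default
either. The assembled length satisfies a closed-form law (201…806
features) tested exhaustively over all 48 recipes.

## Classifier

A two-layer perceptron: input → dropout(p=0.5) → dense(N_in→N_hidden) →
ReLU → dropout(0.5) → dense(N_hidden→2) → softmax, with
N_hidden = nint(N_in/10) (nearest integer; exact .5 ties round away from
zero — no realizable feature length produces a tie, so the choice is a
documented convention, verified against an independent decimal-rounding
oracle over 201…806). Dense weights are Glorot-uniform initialized, biases
start at zero; the L2 penalty (coefficient 1e−4, added as
l2·Σw² to the loss) covers weights only, never biases.

Training minimizes softmax cross-entropy plus the weight penalty for a
fixed 1000 epochs — no early stopping, no checkpointing. The optimizer is
full-batch Adam at learning rate 1e−3: cohorts here are at most a few
hundred rows, full batch removes mini-batch ordering as a source of
nondeterminism, and Adam is robust across the 201–806-feature range
without per-recipe tuning. Dropout is inverted (activations divided by
1−p during training), so inference is a plain forward pass. One seeded
`numpy` Generator drives initialization and every dropout mask, making a
training run bit-reproducible; the analytic gradients are verified against
central finite differences to 1e−5 relative on a micro-model.

A softmax tie (p = 0.5 exactly) classifies as group 1: flagging the
possibly diseased subject is the conservative screening outcome.

## Cross-validation and bilateral fusion

Subjects are dealt into K = 7 stratified subsets (K configurable; 10 is
the documented secondary setting): within each class the subjects are
shuffled by seed, then one class is dealt round-robin across subsets
0…K−1 and the other in reverse order, so each class's remainder lands on
opposite ends. For 27 + 40 subjects this yields subset sizes
{9,9,9,10,10,10,10} with per-subset class counts within one of exact
proportionality; the invariants are re-checked on every construction and
property-tested over 500 random (n₁, n₂, k, seed) draws. Partitioning is
always over subjects — in separate-arm mode both arms of a subject share
its fold, so no subject straddles the train/validation boundary. Each
arm's truth label is its subject's group.

Per fold, a fresh network trains on the training subjects' vectors only
(per-fold seed derived from the CV seed) and predicts the held-out
subjects. In separate mode the 2×67 = 134 arm-level predictions are
tallied once as independent pseudo-subjects ("separate") and once per
fusion scheme: agreement keeps the shared label; a left/right conflict
resolves to the left arm, the right arm, group 1 (keep_osteo) or group 2
(keep_healthy). The 16-case fusion truth table is tested against an
independently written oracle. Note keep_osteo fused sensitivity can never
fall below arm-level sensitivity: a diseased subject is fused-correct iff
at least one arm is correct.

Reported metrics are arithmetic fold means (not pooled counts) of
sensitivity, specificity, accuracy and Youden's J. A fold whose validation
subset lacks one class leaves the affected metric undefined; undefined
values are excluded from the mean with a warning, never coerced to zero.
How ties and undefined folds were handled in the original analysis is not
recoverable; both choices here are explicit and tested.

## Synthetic cohort generator

No generative model is published for this instrument, so the generator is
this package's own construction, built so that the group difference lives
where a spectrum classifier must look — relative resonance-peak heights
and positions:

S21(f) = A_subj(arm) · env(f) · (c₀ + Σₖ aₖ Lₖ(f)) / Z,
Lₖ(f) = 1 / (1 + 2j(f − fₖ)/wₖ)

with n_peaks = 5 complex Lorentzians at fixed log-magnitude-descending
weights aₖ, centres spread across 0.3–1.9 GHz, widths 5% of centre
+30 MHz, an exponential broadband envelope (peak |S21| ≈ 0.02, decaying
with frequency — wrist transmission is tens of dB below unity), and a
fixed normalizer Z with ×3 headroom so |S21| ≤ 1 holds by construction (a
final hard rescale guards pathological settings). Group-1 subjects have
every peak weight multiplied by (1 + effect_amplitude) (default 0.2) and
every centre shifted by the factor (1 + effect_shift) (default 0.02).
Because every Lₖ has positive real part, the integrated |S21| group gap is
provably monotone in effect_amplitude (and tested at three effect levels).

Between-subject variation is a log-amplitude perturbation with sd
`subject_sd` (0.1), decomposed into shared + independent arm components so
the left/right correlation equals `arm_correlation` (0.9) exactly;
`arm_correlation=1` with zero noise makes the arms identical. Baseline
amplitude decreases exponentially with the subject's mean wrist
circumference (coupling 0.15 — a thicker wrist attenuates more);
circumference is group-independent by default, with a
`circumference_group_effect` knob. Measurement noise is independent
additive complex Gaussian, sd 1e−4 per point per arm. S11 is the
placeholder series 1 − |S21|, carried but unused.

Demographics: group sizes default to 27/40. Ages are truncated normals on
the printed ranges ([55, 90] and [23, 94]); the underlying (μ, σ) are
moment-matched numerically so the realized truncated moments meet the
printed targets (77.5 ± 10.1 and 60.2 ± 16.6). One caveat the matcher
exposes: at mean 77.5 on [55, 90] no truncated normal reaches sd 10.1 —
the family's sd at that mean is capped near 9.34 (the tilted-exponential
limit) — so the matcher weights the mean 10× and accepts the realized
group-1 sd of ≈9.3. The healthy group's moments are exactly achievable and
both are recovered. BMI is a truncated normal 26 ± 4 on [16, 45]
(untuned, group-independent); sex is not simulated because nothing
downstream consumes it.

What the generator does *not* emulate: the absolute spectral shapes of the
measured cohort, antenna/placement artefacts, age- or BMI-dependence of
the spectra (so the Age/BMI normalization is exercised mechanically, not
physiologically), and any circumference–group association. Passing tests
therefore demonstrate that the pipeline recovers a multi-peak spectral
group difference of known size under realistic noise and bilateral
correlation — not that the measured data contain such a difference.

## Problem sizes and numerical choices

The acceptance-level checks run the study-sized configuration: 27 + 40
subjects, 201-point grids, 1000 training epochs, 7 folds — strong-effect
recovery over 3 seeds (effect_amplitude 0.5), null calibration over 5
seeds (effect 0), and generator calibration at 10,000 subjects per group.
Unit and CLI tests use reduced grids (15–41 points) and epoch counts,
chosen as the smallest sizes that still exercise every code path. Round
trips are asserted at 1e−9 relative (file formats carry ~12 significant
digits or full repr precision); probability sums at 1e−9; gradient checks
at 1e−5 relative with 1e−6 central differences. Results JSON is written
with sorted keys and fixed indentation so a fixed seed reproduces output
byte-for-byte.

## Known limitations

- The original optimizer and learning-rate schedule are not recoverable
  from the analysis description (toolbox defaults); results on the
  measured cohort may differ from a toolbox re-run accordingly.
- The measured-data deposit is not bundled; the loaders accept its
  structure (packed CSV / Touchstone + sidecar) but reproduction of the
  published tables requires downloading it.
- Fold-mean metrics on 9–10-subject validation sets are coarse (one
  subject ≈ 10–25 percentage points of a fold's sensitivity).
- The null-calibrated classifier tends to collapse to the majority class
  (sens 0, spec 1, J 0) rather than fluctuating around chance — an honest
  consequence of class imbalance under no signal.
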