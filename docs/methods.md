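# Methods

`gazetune` classifies eye-movement events — fixations, saccades and
post-saccadic oscillations (PSOs) — from gaze-position time series, and
studies how a population metaheuristic tunes the classifier's training
hyperparameters. This note records the models, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Synthetic gaze model

Real annotated gaze corpora are large and license-bound, so every stage is
exercised on synthetic recordings with the statistical structure the
classifier relies on. Events alternate fixation → saccade → PSO. Fixations
hold a stationary position; saccades follow a sigmoidal ballistic
displacement; each saccade lands into an exponentially damped sinusoid along
the saccade direction (the PSO). Gaussian measurement noise is added to
every sample.

Defaults (all exposed on `GazeConfig`, durations uniform within range):

| parameter            | default       | rationale                          |
|----------------------|---------------|------------------------------------|
| sampling rate        | 500 Hz        | typical research eye tracker       |
| fixation duration    | 100–400 ms    | standard oculomotor range          |
| saccade duration     | 20–80 ms      | standard oculomotor range          |
| saccade amplitude    | 2–20°         | standard oculomotor range          |
| PSO duration         | 10–40 ms      | brief post-landing wobble          |
| PSO amplitude        | 0.3–1°        | small relative to saccades         |
| PSO frequency        | 80 Hz         | damped ringing time scale          |
| measurement noise    | 0.05° SD      | clean video-based tracker          |

The generator reproduces the *kinematic* separability of event classes
(speed and acceleration signatures) but none of the idiosyncrasies of real
recordings: no blinks, no smooth pursuit, no drift or microsaccades, no
tracker dropouts, and label boundaries are exact rather than
annotator-noisy. Passing the end-to-end benchmarks therefore shows the
pipeline is correctly assembled and tunable — not that it would reach the
same numbers on real corpora.

Synthetic eye images are rendered as three intensity plateaus (sclera disc
background, iris, pupil) plus optional Gaussian noise; the pupil offset is a
deterministic linear function of the gaze target and the head pose's
pitch/yaw, clipped to stay inside the frame. The pixels-per-degree gain
(size/64) is chosen so that displacements of a few degrees move the pupil by
visibly many pixels at 32×32 resolution.

## Fuzzy data augmentation

Tabular augmentation runs fuzzy C-means (FCM, fuzzifier m = 2, k-means++
seeding, alternating optimization until the maximum center displacement
drops below 1e-5) on the attribute table; each record's candidate augmented
row is the center of its highest-membership cluster, retained when that
membership is at least the α-cut. Augmented rows are labeled by the majority
class of their cluster's members — a choice the source procedure leaves
open. The default α = 0.25; because the optimal α is data-dependent, a
trial-and-error grid (`grid_alphas`) can score candidate α values by the
validation accuracy of a quick fit, with α = 1.0 (retain nothing) as the
fallback. In the pipeline, augmentation is applied to the *standardized*
flattened training windows only, after the train/test split — augmenting
before splitting would leak test structure into training.

Prototype augmentation helps in the small-sample, high-noise regime (the
cluster centers act as denoised archetypes) and is neutral-to-harmful on
large clean training sets; the α grid discovers this per run.

Image augmentation applies a rotation sampled within ±15° and one noise
type — Gaussian (σ ∈ [0.01, 0.05]) or salt-and-pepper (density ∈
[0.001, 0.01]) — with outputs clipped to [0, 1].

## Feature extraction

Two convolutional backbones sit behind one interface. The `vgg19` variant is
the standard stack — sixteen 3×3 convolutions in blocks of 64/128/256/512/512
channels, each block closed by 2×2 max-pooling — truncated at the first
4096-unit fully connected layer, whose ReLU activations form the feature
vector (the tap point among the two 4096-unit layers is a choice; the first
is used). The `tiny` variant (two small convolution blocks plus one
configurable fully connected layer) serves desk-scale experiments. Both run
forward-only in numpy with seeded He-initialized weights: only the feature
geometry (width, determinism, pooling behavior) is contracted, and
pretrained weights can be loaded from an `.npz` but are never required.
Grayscale inputs are replicated to three channels for `vgg19`.

In the pipeline, each window is rendered as one eye image whose pupil offset
encodes the window's gaze displacement vector (end − start), so the image
branch carries the same kind of kinematic information a real image sequence
would; its features are standardized, then broadcast across the window's
time steps and concatenated with the signal features.

## The bidirectional LSTM

Each direction is a standard LSTM cell written out gate by gate
(candidate `u = tanh`, input/forget/output gates sigmoid,
`C_t = f⊙C_{t-1} + i⊙u`, `h_t = O⊙tanh C_t`); the forward pass reads the
window left-to-right, the backward pass right-to-left. Per-step outputs are
combined by the weighted sum `HT = W_xh·fh + W_hh·bh + b_h` (a concatenation
combiner is available behind a flag), followed by dropout on HT and a linear
softmax head. Training minimizes cross-entropy plus an L2 penalty on weight
matrices (never biases) with plain mini-batch SGD; BPTT is hand-written and
verified against numerical gradients.

Numerical and design choices:

- **Windowing.** Continuous recordings are cut into fixed windows
  (library default 64 samples / stride 32; the pipeline's desk-scale default
  is 32/32, i.e. 64 ms at 500 Hz) with the window's label taken from its
  center sample.
- **Supervision.** Every synthetic sample carries a true label, so the
  pipeline supervises all time steps of a window (the per-step cross-entropy
  mean); with only window labels the loss attaches to the center step.
  Per-step supervision is what makes plain SGD reach high accuracy within
  the ≤ 20-epoch budget. Predictions are always read at the center step;
  ties break toward the lower class index.
- **L2 semantics.** The penalty is treated as a per-epoch objective term:
  its gradient `2·l2·W` is distributed uniformly over an epoch's mini-batch
  updates, giving an effective decay `exp(−2·lr·l2·epochs)` independent of
  batch count. Applying the full decay at every update would make nearly the
  whole tunable range [0.003, 0.1] degenerate at these problem sizes, which
  cannot be what a tunable range intends.
- **Features.** Per-sample inputs are position, velocity, speed and
  acceleration (`x, y, vx, vy, |v|, ax, ay, |a|`), standardized on the
  training partition. Velocity separates saccades from fixations;
  acceleration exposes the PSO's oscillatory signature.
- **Hot loops.** The sequential gate recurrences (forward and BPTT) are
  numba-compiled with a pure-numpy fallback; all surrounding matmuls are
  batched. Everything is float64 so the equation-transcription checks hold
  to 1e-10.
- Hidden width defaults to 32; batch size 16; forget-gate biases start at 1.

## LICRSA hyperparameter tuning

The optimizer evolves N "crocodiles" in the normalized unit cube over Tmax
iterations, scheduled in quartiles: high walking, belly walking (encircling,
exploration), hunting coordination and cooperation (exploitation), with
Lévy-flight step lengths (Mantegna method, γ = 1.5) replacing the uniform
draws of the base reptile search algorithm. The auxiliary coefficients use
the base-RSA definitions (hunting operator φ = y*·P, reduce function
RF = (y* − y_r1)/(y* + ε), evolutionary sense ES = 2·r₃·(1 − l/Tmax),
percentage difference P = 0.1 + (y − mean y)/(y* + ε)); μ = λ = 0.1.

After each phase update — and its greedy elimination (keep the better of old
and candidate; ties keep old) — the interactive crossover recombines the
*surviving population's current positions*: two random half-populations are
paired and pulled toward the best solution with strength
CF(l) = (1 − l/Tmax)^(2l/Tmax) plus a stochastic exchange term
c·(y_k1 − y_k2), c ~ U(0, 1), again followed by elimination. Applying the
crossover to the phase candidates instead collapses the population onto the
incumbent within a few iterations (the clipped candidates make the exchange
term vanish), which destroys convergence; recombining the population itself
is both the literal reading of the update equations and the variant that
converges (sphere-3d, N = 20, Tmax = 50: median best fitness ~1e-12 across
20 seeds, versus ~0.16 for the collapsing variant).

Positions are hard-clipped to [0, 1]; "stochastic integers in [0, 1]" for
c₁, c₂ are read as uniform reals (a `bernoulli_c` flag restores the literal
reading, which makes the term a coin flip). Defaults N = 20, Tmax = 40 for
generic use; the pipeline's tuning block uses N = 4, Tmax = 4 (36 fitness
evaluations, each a full BiLSTM training) as its desk-scale default.

The tuning domain is dropout [0.1, 0.4], learning rate [0.003, 0.1], L2
[0.003, 0.1] (continuous, affine decoding) and max-epoch {5, 10, 15, 20}
(categorical, equal-width bins). Fitness is 1 − validation accuracy of a
BiLSTM trained with the decoded candidate on an internal stratified 80/20
split of the training partition; the held-out test partition never enters
tuning (a hash guard asserts the test arrays are untouched through the
run). A fitness cache keyed by decoded hyperparameters skips duplicate
trainings.

## Evaluation

Per-class one-vs-rest confusion counts feed accuracy, precision,
sensitivity and F1 on the percent scale, macro-averaged over classes (the
source reports single values for 3-class problems without stating the
averaging; macro matches its own description of AUROC averaging).
Zero-denominator metrics report 0 with a warning. Macro AUROC uses the rank
statistic and macro AUPRC step-interpolated average precision, per class
one-vs-rest, skipping absent classes with a warning. Average precision is
bootstrapped (percentile method, B = 1000 default, degenerate single-class
resamples redrawn up to 10 times) to 2.5/50/97.5% quantiles, reported on
both the [0, 1] and percent scales; methods can be ranked by median AP.

## Benchmark sizes

The shipped benchmarks are sized for a single CPU: end-to-end runs use 600
synthetic events (~54 k samples, ~1 000 windows) with tuning budgets of
36 evaluations, the optimizer benchmarks use 20 seeds of N = 20 / Tmax = 50
runs, and the augmentation contrast uses 100-event, high-noise recordings.
These are scaled-down analogues: they preserve the qualitative orderings
(tuned ≥ default, full optimizer ≥ plain-RSA ablation, augmentation helps
small noisy sets) rather than any particular headline number.

## Known limitations

- The synthetic generator's simplifications (above) bound what the green
  benchmarks say about real recordings.
- The VGG-19 variant is a feature-geometry contract, not a trained
  recognizer; with random weights its features are a fixed random projection.
- Plain SGD with the small epoch budget leaves per-seed variance of a few
  macro-F1 points; conclusions are drawn on medians over seeds.
- The optimizer treats the categorical max-epoch dimension as binned
  continuous, which is the simplest sound decoding but makes its landscape
  piecewise constant along that axis.
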