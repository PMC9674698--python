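# Methods

## Inference protocol

A *conventional* model is trained without dropout layers and evaluated with a
single deterministic forward pass. An *MC* model contains spatial (channel)
dropout after each convolutional block; at test time the dropout layers stay
active while everything else remains in evaluation mode, N = 50 stochastic
passes are drawn, and the final prediction is the element-wise mean of the
draws in probability space (post-softmax/sigmoid). Averaging logits instead
was considered and rejected: the mean of probability vectors is itself a
probability vector, it is what a posterior-predictive average approximates,
and it preserves the linearity identity score(mean p) = mean score(p) that
the tests pin down exactly.

Dropout-mask randomness is organized as a frozen sequence: the mask RNG is
restarted from the configured seed at every inference call, with one child
stream per dropout layer. Consequences, each deliberate:

- a prediction depends only on (model weights, image, seed) — never on batch
  composition or iteration order;
- identical inputs receive identical MC predictions, so a model evaluated on
  pixel-identical test-retest views is exactly repeatable, as it should be —
  per-image mask streams would inject evaluation-side noise into the very
  quantity being measured;
- the first n draws of an N-draw sample are a valid n-draw sample, so the
  iteration sweep evaluates all grid points on common random numbers and the
  resulting curve is free of between-point resampling noise;
- per-layer child streams make those prefixes stable across different batch
  sizes (a single shared stream would entangle the layers' offsets).

## Severity scores and decisions

Multi-class: probability-weighted class index (range [0, k−1]). Ordinal:
sum of the k−1 cumulative sigmoid outputs. Binary: the positive probability.
Regression: the raw scalar, deliberately unclamped; equal-range thresholds
t_j = lo + j(hi−lo)/k bin it for class metrics, with interior intervals
left-open/right-closed and closed outer intervals (so the whole real line is
covered). Multiclass argmax ties break toward the lower class; binary and
ordinal decode at 0.5 per output. Classes are zero-based internally.

## Repeatability metrics

One Bland-Altman point per patient: x = mean of the per-view scores, y =
signed (first − second) difference for exactly two views, (max − min) for
more. The 95% LoA use a Shapiro-Wilk gate (α = 0.05) on the pooled
differences: parametric mean ± 1.96 SD when normality holds, empirical
2.5th/97.5th percentiles (linear interpolation between order statistics —
the convention is pinned by a sort-based oracle test) otherwise. The scalar
reported is the interval half-width normalized by the score range; the
half-width reading (rather than max |bound| or upper bound) matches the
symmetric-limits presentation of Bland-Altman plots. Within an MC-iteration
sweep the gate is decided once, from the full-sample differences, and applied
to every grid point — re-gating per grid point can flip conventions between
adjacent n and creates artifactual jumps in the curve.

The disagreement rate counts a patient as disagreeing iff its views' class
decisions are not all identical. Fewer than 20 Bland-Altman points flags the
LoA low-confidence; groups with fewer than 2 scores are skipped and counted.

The plateau statistic of the iteration sweep is the smallest grid n with
LoA(n) ≤ 1.05 × LoA(N_max). The tolerance is one-sided because the question
is when additional iterations stop *improving* repeatability; a grid point
already below the full-sample value has nothing left to gain.

## Classification, calibration, model comparison

Quadratic weighted κ uses w_ij = (i−j)²/(k−1)² with expected counts from the
outer product of marginals; degenerate single-class marginals return NaN
(undefined) rather than a number. The Brier score is mean (p − y)² for
binary and the sum-over-classes convention (range [0, 2]) for multi-class;
ordinal outputs are converted to a k-class distribution by differencing the
(monotonized) cumulative curve. Reliability curves pool (sample, class)
pairs one-vs-rest into 10 equal-width bins, each reporting the mean
prediction, observed frequency and the 2.5/97.5 percentile span of
predictions; empty bins are emitted with count 0.

Model comparisons resample patients (not images) with replacement — the
repeatability metrics are per-patient, so the patient is the exchangeable
unit — using the same 500 resample index sets for both models, and test the
paired replicate distributions with a two-sided t-test at 0.05. The t-test
on bootstrap replicates is known to be anti-conservative; it is kept as the
default deliberately to mirror the standard procedure, and the grouped
percentile CIs are reported alongside.

## Model zoo

The backbone is a compact, fully seeded numpy CNN (im2col convolutions,
float32 throughout, manual backpropagation): three 3×3 conv blocks
(8/16/32 channels, ReLU, 2×2 max-pool, channel dropout after each block),
flatten, a 64-unit dense layer, and the head. Channel dropout zeroes whole
feature channels per forward pass with inverted scaling. The dense stage
carries no dropout, mirroring the usual placement after convolutional/
residual blocks only. Heads: 1 logit (binary, BCE), k logits (multi-class,
cross-entropy), k−1 logits with one shared weight vector and rank-specific
biases (ordinal, CORAL: summed BCE against the cumulative prefix encoding,
importance weights 1 — the shared weight vector makes the sigmoid outputs
rank-monotone once the biases order), and 1 linear output (regression, MSE
against the zero-based class index, an encoding choice since regression
targets are otherwise unconstrained).

Training: Adam, reduce-on-plateau scheduler (factor 0.1, patience 10,
monitoring validation loss), augmentation of ±15° rotations and 50%
horizontal flips on the training split only, batch 32, 75 epochs, learning
rate 1e-3 (chosen for training a small CNN from scratch; published
per-dataset rates for fine-tuning large pretrained backbones are far lower
and do not transfer to this regime). Each model keeps its **final-epoch
weights** by default, matching the fixed-epoch, trained-once protocol of the
study design; a `best_val` snapshot (validation accuracy, latest epoch among
ties; validation loss for regression) is available but not the default — at
this data scale a best-validation snapshot systematically selects early,
well-calibrated epochs and thereby erases the late-training overconfidence
whose consequences for repeatability are the object of study. All eight
variants (4 heads × dropout/no-dropout) train from one config switch;
patient-level split discipline is asserted.

## Synthetic benchmark

Each patient has a latent severity s: a class c is drawn from the class
prior (uniform by default) and s ~ Uniform(c−0.5, c+0.5) clipped to
[0, k−1]. The 32×32 grayscale image contains ≈3s lesion-like Gaussian blobs
(±1 Poisson-style jitter; amplitude also grows with s), on a noisy
background — total lesion area and contrast increase in expectation with s,
and s = 0 renders a lesion-free texture. The observed label is the nearest
integer of s + ε with ε ~ N(0, 0.25), emulating inter-rater noise
concentrated at class boundaries; sd 0 is exact binning.

Per patient one base image is rendered and each of the ≥2 views is an
independently jittered copy (horizontal flip p = 0.5, rotation within ±10°,
brightness 0.92-1.08, ±2 px translation) — so zero jitter yields
pixel-identical pairs and a fully repeatable pipeline, a degenerate case the
tests exercise end-to-end. A flip-retest mode instead pairs each image with
its mirror (emulated retest for datasets with one image per visit); a
domain-shift mode transforms retest views with a fixed 25° rotation and
0.75 brightness, both outside the training augmentation family (unseen-view
setting). Patients are split 65/10/25 into train/val/test stratified by
label (largest-remainder allocation, within ±1 patient per class).

Reference benchmark conditions: k = 3, 300 patients, 2 views/patient,
boundary noise SD 0.25, seeds 0-4, dropout rate 0.1 (one of the two
standard spatial-dropout rates for this model family), N = 50 MC samples,
iteration grid {1, 2, 5, 10, 20, 30, 40, 50}. Sizes were chosen so the
full synth → train (both variants) → evaluate → sweep pipeline runs in a
few minutes per seed on one CPU. The jitter magnitudes are calibrated only
to make the MC-vs-conventional contrast detectable at this scale; they are
not fitted to any real dataset.

## What the synthetic benchmark does and does not show

It reproduces the *mechanisms*: score differences concentrate near class
boundaries (the Bland-Altman arch), MC averaging attenuates them, the MC
model's median disagreement rate, LoA and Brier score improve on the
conventional model's, and the LoA-vs-iterations curve saturates well before
20 draws. It does not reproduce — and is not meant to reproduce — absolute
metric values from clinical datasets: real cohort sizes, pretrained
backbones at full image resolution, true inter-view physiology and rater
behavior are all outside its scope, so effect sizes here are smaller and
noisier than published clinical deltas. Per-seed contrasts fluctuate; the
packaged claims are therefore medians over five seeded replicates.

## Numerical choices and degenerate inputs

float32 weights and activations (BLAS sgemm); exact-equality tests allow
1e-6 for float32 reassociation. Probability vectors validate to the simplex
within 1e-6. Constant difference sets short-circuit the normality gate to
the percentile path (Shapiro-Wilk is undefined there); LoA of constant
differences is 0. Empty prediction sets, empty validation splits, dropout-
free models under MC, grids exceeding the sample budget, and degenerate
score ranges raise explicit errors. κ on single-class marginals is NaN and
such bootstrap replicates are dropped and counted. Identical paired
replicate distributions report p = 1 (the t statistic is 0/0 otherwise).

## Known limitations

The CNN engine is minimal by design (no GPU, no batch-norm — normalization
statistics would otherwise need freezing at MC time; their interaction with
dropout is deliberately avoided). The bootstrap-t comparison inherits the
anti-conservatism noted above. The ordinal-to-distribution conversion for
the Brier score monotonizes the cumulative curve, which is exact only for
rank-consistent outputs (guaranteed by the shared-weight CORAL head, not by
arbitrary ordinal vectors). The benchmark's domain-shift mode applies one
fixed transform rather than a family of unseen views.
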