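# Methods

## Problem and model

The package classifies subjects from resting-state functional connectomes:
each subject is an `n × n` symmetric matrix of pairwise Pearson correlations
between regional fMRI time series (n = 116 for the packaged AAL atlas), with
two classes, schizophrenia spectrum disorders (SSD, the positive class) and
healthy controls (HC).

Treating the matrix as the weighted adjacency `E` of a complete graph over
brain regions, the classifier interleaves ordinary convolutions with a
**Net-GA block**, a squeeze–excitation module built from graph-aware
operators:

1. **E2E (edge-to-edge) cross filter.** For input `X ∈ R^{h×w×c}`, the
   response at edge `(i, j)` is a learned combination of the whole row `i`
   and column `j` across channels, squeezing channels `c → c'`:
   `out[i,j,o] = b_o + Σ_m ( ⟨row_o,m, X[i,:,m]⟩ + ⟨col_o,m, X[:,j,m]⟩ )`.
2. **Region reshape.** The `h × w × c'` tensor becomes an `h × M` matrix
   (`M = w·c'`); row `i` holds all features of region `i`. The flattening
   order is fixed: channel index fastest, then column (a C-order reshape,
   exactly invertible).
3. **Global covariance pooling.** Second-order pooling of the region-feature
   matrix: `x_cov = x A xᵀ` with `A = (1/M)(I − (1/M)JJᵀ)`, i.e. the
   1/M-normalized sample covariance of the mean-centered rows. Row `i` of
   `x_cov` encodes the statistical dependency of region `i` on every other
   region. The covariance is used raw — no matrix square root or power
   normalization.
4. **Row-wise group convolution (E2N).** Each region keeps its own length-`h`
   filter over its covariance row, giving one response per region. In the
   `no_gcp` ablation the covariance stage is skipped and the per-row filters
   act directly on the reshaped `h × M` rows.
5. **N2G excitation.** A bottleneck `h → d_hidden → h` (leaky-rectified
   inside, sigmoid outside) maps region responses to attention gates
   `a ∈ (0,1)^h`, which rescale the rows of the **original block input**:
   `out[i,:,:] = a_i · X[i,:,:]`. The block therefore preserves shape and can
   be inserted after any convolutional stage.

The full network repeats `[3×3 same-padded conv + leaky rectifier → Net-GA
block]` for `n_stages` stages and classifies with dropout + a linear map to
two logits. The 3×3/stride-1/same-padding choice keeps `h = w = n` so the
row index stays region-aligned, which the attention requires; the small
kernel acts as a local feature extractor that does not destroy the matrix's
topology. Defaults follow the ablation optimum: 2 stages, 64 conv channels,
1 E2E layer with c' = 16, 10 bottleneck units.

Variants: `no_gcp` (first-order squeeze), `no_netga` (plain conv net),
`brainnetcnn_style` (E2E → E2N → N2G feedforward without gating, as the
graph-CNN baseline).

## Numerical implementation

The network is float64 NumPy throughout, with analytically derived
backpropagation for every operator (cross filters, convolution via im2col
windows, covariance pooling, per-row filters, bottleneck, gating). Gradient
correctness is enforced in the test suite by central finite differences at
1e-4 relative tolerance. The sigmoid is clamped into the open interval
(0, 1) at float64 saturation so gates never degenerate exactly to 0/1.
Training minimizes softmax cross-entropy plus `l1·Σ|θ| + wd·Σθ²` with Adam
(β = 0.9/0.999); weights are He-uniform, biases zero, all randomness flows
from one seed, so runs are bit-reproducible. Optional early stopping
monitors validation cross-entropy with patience 10 and restores the best
epoch.

Activation choices the architecture description leaves open are leaky
rectifiers (slope 0.01) after the conv, the E2E layers and inside the
bottleneck; no batch/instance normalization is used anywhere. Ties in the
saliency edge ranking break toward the lexicographically smaller index pair.

## Evaluation protocol

`nested_cv` runs stratified `outer_folds`-fold cross-validation (default 10),
repeated `repeats` times (default 10) with fresh fold assignments from
derived seeds; every subject is scored exactly once per repeat.  An inner
stratified split (default 5 folds) selects the learning rate and L1 weight
when `search_budget > 1`; the search strategy is pluggable and defaults to
log-uniform random candidates (lr ∈ [1e-4, 1e-2], l1 ∈ [1e-6, 1e-3]).
Accuracy, sensitivity and specificity (SSD positive) are means over folds
and repeats; AUC is computed by pair counting with ties at 1/2, which equals
the trapezoidal area under the empirical ROC exactly.

`permutation_test` shuffles labels once per replicate before the CV split
and uses mean cross-validated accuracy as the statistic, with the add-one
estimate `p = (1 + #{null ≥ observed}) / (1 + n_perm)`.

## Synthetic data

The generator emulates two-class correlation matrices with a known answer: a
shared base correlation matrix from a rank-3 factor model, a symmetric
offset `effect_delta` added on a fixed set of planted edges for SSD subjects
only, then per-subject symmetric Gaussian noise, clipping to [−0.999, 0.999]
and a zero diagonal. Default conditions: 30 nodes, 100 subjects per class,
10 planted edges, delta 0.4, noise s.d. 0.1 — a strong, localized group
difference that a competent classifier should detect and a faithful saliency
method should localize. Noise is applied to correlations directly for speed
and controllability; clipping (not re-projection to PSD) is deliberate, as
the classifier treats the matrix as a feature grid. A separate time-series
mode builds latent factor signals with planted cross-loadings and runs them
through the package's own correlation step, exercising the full input path.

What the generator does **not** emulate: spatial autocorrelation of real
parcellations, site/scanner effects, motion artifacts, heavy-tailed subject
variability, and class differences that are diffuse rather than localized.
Passing tests on this data demonstrate that the architecture, training loop,
protocol and saliency chain are correct and can recover localized planted
effects; they say nothing about clinical effect sizes or accuracy on real
rsfMRI cohorts.

## Problem sizes used in checks

The end-to-end recovery check uses the default synthetic conditions above
with a scaled-down model (1 stage, 8 conv channels, c' = 4, 4 hidden units)
under 5-fold CV — small enough to run on one CPU core in minutes while
leaving every operator on its normal code path. Null calibration of the
permutation test uses 50 independent effect-free datasets (12 nodes, 12 per
class) with a minimal model and 99 permutations each; the observed rejection
fraction at α = 0.05 must stay within the binomial envelope [0, 0.12].

## Design choices on open points

- The study input is raw Pearson `r`; Fisher-z is available but off by
  default.
- Diagonal convention defaults to 0 (self-connections carry no information
  for edge filters); configurable to 1.
- Asymmetric matrices are rejected rather than silently symmetrized, to
  surface upstream pipeline errors.
- The excitation gates multiply the block's **input** tensor (not the E2E
  output), matching the composition `F_EX ∘ F_SE` acting on `X`.
- Saliency uses the absolute input-gradient of the pre-softmax target-class
  logit, symmetrized by averaging with its transpose, diagonal zeroed;
  per-subject maps from each CV fold's held-out subjects are pooled across
  folds and normalized once at the end (max = 1). A gradient×input variant
  is selectable.
- Hyperparameter search replaces Bayesian optimization with a pluggable
  strategy defaulting to log-uniform random search, since the procedure and
  priors of the original optimization are not specified anywhere usable.

## Known limitations

- Training is CPU NumPy; fine at the packaged problem sizes, slow for
  116-region cohorts with hundreds of subjects at full model width.
- The L1 penalty uses the subgradient at 0 (sign), not a proximal update, so
  weights oscillate at the learning-rate scale around 0 instead of landing
  exactly on it.
- Binary classification only; a single square matrix per subject (any n),
  no multi-atlas fusion.
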