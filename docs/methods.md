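# Methods

## Model

`jointcal` addresses single-source/single-target transfer for omics
feature tables: a labeled source batch X₁ (n₁ × d intensities, binary
labels y₁) and an unlabeled target batch X₂ (n₂ × d) measured under
different conditions. Three parameterized maps are trained jointly:

* **Calibrator C** — batch normalization, then
  affine → leaky ReLU → affine → leaky ReLU, every hidden width equal to
  d. The latent code Z = C(X) therefore has the same dimensionality as
  the input; compressing the latent width was deliberately avoided, as
  narrowing it costs classification accuracy on this kind of data.
* **Reconstructors R₁, R₂** — one per batch,
  affine → leaky → affine → leaky → affine, all widths d. They force the
  latent code to retain enough information to restore each batch's raw
  features, preventing the calibrator from solving its alignment task by
  collapsing the data.
* **Discriminator D** — affine layers d → 128 → 64 → 32 → 16 → 1 with
  leaky ReLUs between and a terminal sigmoid; a binary classifier on the
  latent space (multi-class labels are rejected at validation).

The objective is the weighted sum L = α·L_R + β·L_C + γ·L_D with

* L_R = mean over samples of ‖x − R(C(x))‖₂², summed over both batches
  (each decoded by its own reconstructor);
* L_C = squared maximum mean discrepancy between C(X₁) and C(X₂)
  minibatches (see *Calibration loss* below);
* L_D = binary cross entropy of D(C(x₁)) against y₁, source samples
  only. Target labels never enter any loss; the test suite verifies that
  deleting them changes nothing, bit for bit.

Default weights are α = β = γ = 1 (neutral; every run logs its
effective configuration, and the weights are plain config fields).
Optimization is Adam with the canonical moment-decay defaults
(0.9/0.999), learning rate 1e-3, minibatch 128, 200 epochs. Each step
draws one minibatch per batch; per epoch the larger batch is swept once
in shuffled order and the smaller batch is resampled with replacement
per step, so every source sample supervises the discriminator every
epoch. A single optimizer updates all parameters from the one total
loss — there is no alternating adversarial schedule. Runs are
bit-for-bit reproducible under a fixed seed.

## Calibration loss

Two interchangeable kinds are implemented (`KernelConfig.kind`):

* `multiscale_gaussian` (default): the biased V-statistic estimator of
  squared MMD with a sum of Gaussian kernels exp(−‖a−b‖²/h). Bandwidths
  follow the median heuristic — the median of pooled pairwise squared
  distances of the two minibatches — times multipliers {0.5, 1, 2},
  recomputed per minibatch and treated as constants (detached) in the
  gradient, the standard practice for MMD-matching objectives. The
  V-statistic is nonnegative for a positive-definite kernel and is
  clipped at zero against floating-point noise; the unbiased U-statistic
  is available behind a flag for evaluation parity studies (no gradient
  path).
* `linear_mean_l1`: the L1 distance between the two latent mean vectors
  — the literal per-pair-of-samples reading of the calibration
  objective, aggregated over the minibatch. It is kept as an auditable
  fallback; it only matches first moments, so it cannot penalize
  scale or shape mismatch, which is why the Gaussian kind is the
  training default.

The discrimination loss is the full two-sided binary cross entropy.
The printed one-sided form (positive-class term only) cannot train a
binary classifier — negative samples would carry no gradient — but is
available behind `one_sided_bce=True` for audit.

## Batch normalization at training and at evaluation

During training each minibatch — drawn within one batch — is
standardized against its own statistics, so the leading BN layer aligns
the two batches' first two moments per feature before the shared
nonlinear layers and the MMD act on the residual (nonlinear) mismatch.
This per-batch standardization is the backbone of the correction, which
has a consequence for evaluation: with frozen running statistics the BN
layer is a *fixed affine map shared by both batches*, and a shared fixed
map cannot remove any between-batch difference. The evaluation
protocols therefore calibrate each complete measurement batch
*transductively* (`batch_stats=True`): the batch being scored is
standardized against its own statistics, exactly as its minibatches were
during training. This is consistent with the training setup, where the
target batch is available (unlabeled) from the start. Frozen
running-statistics mode (`batch_stats=False`, the default of
`calibrate`/`predict`) remains available for streaming or per-sample
use, and is precisely how the *uncorrected baseline* is applied (see
below). Running buffers use momentum 0.1 and eps 1e-5 and are updated
only on training passes, source minibatch before target within each step.

## Implementation of the networks

No deep-learning framework is used: layers (affine, batch norm, leaky
rectifier, sigmoid), their reverse-mode gradients, and Adam are
implemented on NumPy arrays in `jointcal.nn`. All affine layers share
one initialization strategy (uniform Kaiming fan-in scaling, bound
1/√fan_in, matching the common default). The leaky-rectifier negative
slope defaults to 0.01. The entire joint objective's hand-derived
backward pass is checked against central finite differences in the test
suite (worst relative error observed ~1e-9). Checkpoints are a single
zip archive of `.npy` tensors plus a JSON manifest, auditable without
any framework.

## Evaluation protocols

* **Subsampled MMD**: each repeat draws 500 rows per side (with
  replacement if a side is smaller than that), computes the root of the
  clipped squared Gaussian MMD, and reports mean ± sd over 10 repeats.
  The **in-batch MMD** splits one batch into two random disjoint halves
  and is the empirical floor of the measure: no batch effect exists
  within one batch.
* **Classification metrics**: accuracy; F-score on class 1; AUC by the
  rank statistic (probability a random positive outscores a random
  negative, ties ½ — exact on small samples, equal to pair
  enumeration); MCC from the 2×2 confusion table with the
  zero-denominator → 0 convention. Single-class truth makes AUC
  undefined; it is reported as NaN, never silently as a number.
* **Subject ensembling**: subject diagnosis = median of the subject's
  per-sample probabilities, then ≥-threshold (ties at even replicate
  counts resolve to the positive class at threshold 0.5).
* **Permutation null**: shuffle the source labels, retrain the whole
  pipeline, score the target; repeat (default 100×, histogram bin width
  0.05). A sound model shows a chance-centered bell with the true-label
  run far outside it.
* **Embeddings**: raw and calibrated matrices are embedded jointly
  (one t-SNE/PCA fit over the concatenated rows) so panels share axes;
  the contract is the coordinate table with batch/label/stage
  provenance columns, not a figure.

The uncorrected **baseline** used in transfer comparisons is the same
architecture trained with α = β = 0 (discriminator-through-calibrator
only) on the source batch alone and applied to the target as a frozen
function — the conventional train-here/apply-there workflow against
which calibration is measured.

## Biomarker screen

Candidates must be stable *and* significant: selection frequency — the
fraction of 100 bootstrap refits of an L1-penalized logistic regression
(features standardized per fit, penalty chosen by 3-fold inner CV over
C ∈ {0.01, 0.1, 1}) in which a feature gets nonzero weight — must exceed
0.9, and a two-sided rank-sum test between classes must give p < 0.05.
No multiple-testing correction is applied to the univariate p-values:
the frequency filter is the primary gatekeeper, and the screen's
monotonicity (raising either threshold never adds candidates) is tested.
Single-class bootstraps are redrawn a bounded number of times.

## QC feature filter

Features pass when their signal-to-noise ratio strictly exceeds the
threshold (default 3) and their replicate relative standard deviation
satisfies the configured direction against the RSD threshold (default
5%). The default direction is `keep_above` — the literal protocol
wording this package follows — although most QC conventions keep *low*
RSD features; the direction is a config enum precisely because the
conventions disagree, and pipelines should set it explicitly.

## Synthetic study designs

The generator emulates replicate-based two-batch studies: per-feature
baseline intensities ~ U(2, 8); a random subset of features shifts by
±`class_effect` with the subject's phenotype; Gaussian subject random
effects (sd 0.5) and replicate noise (sd 0.5); 1–5 replicates per
subject; and a feature-wise target-batch corruption
x → scale·(x + s·sin(x/τ)) + shift with shift ~ N(0, batch_shift²),
log scale ~ N(0, batch_scale²), and a monotone sinusoid warp (s ≤ τ
keeps it invertible) that location-scale corrections cannot undo. Both
batches are soft-clipped to nonnegative intensities with a smooth
softplus, as MS intensities are nonnegative.

Preset designs:

| preset | d | subjects/batch | replicates | signal features | corruption |
|---|---|---|---|---|---|
| `cytof_like` | 25 | 1500 | 1 | 7 (±1.0) | shift 2.0, scale 0.4, warp 1.0 |
| `maldi_like` | 814 | 200 | 5 | 41 (±1.0) | shift 1.0, scale 0.3, warp 0.5 |
| `planted_signal` | 100 | 150 | 1 | 5 (±1.5) | none |
| `tiny` | 10 | 150 | 1–3 | 5 (±1.2) | shift 0.8, scale 0.2, warp 0.3 |

The `cytof_like` corruption magnitudes are set so that the raw
between-batch MMD sits an order of magnitude above the in-batch floor
and a source-only classifier visibly degrades on the target — the
regime the method exists for. The acceptance runs use `cytof_like` for
batch-effect removal and transfer, `tiny` for the permutation null and
subject ensembling (its replicate structure and small size keep 20+
retrainings cheap; 60 epochs suffice at that scale), and
`planted_signal` for the biomarker screen; these problem sizes are the
package's desk-scale defaults.

What the generator does *not* emulate: correlated feature blocks
(metabolite peaks from one compound), heavy-tailed intensity noise,
missingness, drift within a batch, or batch effects correlated with the
phenotype (confounding). Passing tests therefore show that the
machinery behaves as designed under clean, known-truth conditions — not
that it will resolve any particular real study, where those
complications decide the outcome.

## Numerical choices and degenerate inputs

* Probabilities are clamped to [1e-7, 1−1e-7] before the BCE during
  training; the loss functions themselves reject out-of-range inputs.
* Gaussian MMD requires ≥ 2 rows per side; a trailing size-1 minibatch
  chunk is merged into its predecessor.
* The in-batch MMD requires ≥ 4 rows; the subsample protocol draws with
  replacement when a side is smaller than the subsample size.
* Median-heuristic bandwidth falls back to 1.0 when the median pairwise
  distance is 0 (constant matrices).
* MCC is 0 whenever a confusion-table margin is empty; F-score is 0
  when precision and recall are both undefined.
* Stratified folds are used for in-batch cross-validation (plain
  "k-fold" leaves class balance to chance at these sample sizes), and
  metrics are pooled over held-out predictions rather than averaged per
  fold.
* Missing feature cells are rejected at load time by default;
  mean-imputation is opt-in, because the training pipeline assumes
  complete matrices.

## Known limitations

Single source, single target: multi-batch studies require pairwise runs.
Binary labels only. The transductive evaluation mode needs the whole
target batch at scoring time; truly streaming deployment falls back to
frozen statistics and will not enjoy the batch correction. Loss weights
α, β, γ were not tuned per dataset; applications with very different
feature counts may need to rebalance the reconstruction term, whose
scale grows with d.
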