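# Methods

## Problem

Sequencing-based spatial transcriptomics (ST) measures gene expression at
spatial capture locations ("spots") that each contain several cells, so a
spot's profile is a mixture of cell-type profiles. Deconvolution estimates,
for every spot, the fraction of each cell type contributing to it, using a
cell-type-labelled scRNA-seq reference from the same tissue.

## Model

Training data are *pseudo-spots*: simulated spots built by sampling cells
from the reference and summing their count profiles, so the mixing
proportions are known exactly. The real ST matrix has no labels; the model
transfers supervision from the pseudo (source) domain to the real (target)
domain with three coupled mechanisms.

**Masked autoencoder.** Each iteration, a Bernoulli(ρ) mask `M` (1 =
masked) zeroes a fraction ρ of the real matrix entries. A two-layer
encoder `E` (linear → batch norm → LeakyReLU → linear) maps the masked
matrix to a latent representation `H_R`; a three-layer decoder mirrors it
and reconstructs the input. The reconstruction loss is the squared error
over masked entries only,

    L_MSE = ‖(X̂_r − X_r) ⊙ M‖² / |M|,

normalized by the masked-entry count so its scale does not drift with ρ.
(The raw squared norm is the textbook form; the count normalization is a
deliberate choice that keeps the loss weight λ meaningful across masking
rates and batch sizes.)

**Adversarial alignment.** The latent matrix is split column-wise 1:1. The
first half feeds a classifier trained with correct domain labels (real = 1,
pseudo = 0); the second half feeds a discriminator trained with flipped
labels. Both heads are small LeakyReLU MLPs with sigmoid outputs scored by
mean binary cross entropy:

    L_C = BCE(C(H_R1), 1) + BCE(C(H_S1), 0)
    L_D = BCE(D(H_R2), 0) + BCE(D(H_S2), 1)

The encoder minimizes both, which pushes real and pseudo latent
distributions toward each other. The split ratio is configurable (1:3,
1:1, 3:1); 1:1 is the default.

**Supervised predictor.** A two-layer softmax-headed MLP maps the full
latent vector of a pseudo-spot to proportions; its loss is the per-spot
mean squared Euclidean distance to the known label (again a per-spot mean
rather than a raw sum, for batch-size invariance).

**Three-sub-step training.** Each iteration: (1) encoder+decoder minimize
`λ·L_MSE + (1−λ)·(L_C + L_D)`; (2) classifier+discriminator minimize
`λ·L_C + (1−λ)·L_D` on a fresh forward pass with the encoder frozen in
inference mode (so encoder batch-norm buffers stay untouched — the
frozen-parameter contract is bitwise); (3) encoder+predictor minimize
`L_P`. Each sub-step has its own Adam optimizer so moment estimates never
leak across parameter groups. Inference composes encoder and predictor on
the unmasked real data with batch norm in inference mode.

The networks are implemented on a small reverse-mode automatic
differentiation core written in numpy (`spadama.autograd`); every operation
and the composed components are verified against central finite differences
in the test suite.

## Defaults and their rationale

| parameter | default | notes |
|---|---|---|
| epochs | 200 | fixed-length training, no early stopping |
| batch size | 2048 | pseudo-spot mini-batches; the real matrix is used full-batch when smaller |
| learning rate | 0.01 | Adam, β = (0.9, 0.999) |
| masking rate ρ | 0.3 | per-entry Bernoulli, resampled every iteration |
| loss weight λ | 0.5 | λ = 1 disables the adversarial term in sub-step 1 |
| latent dim | 128 | even, so the 1:1 split is exact |
| encoder widths | G → 512 → 128 | decoder mirrors with 128 → 256 → 512 → G |
| heads | 64 hidden units | classifier/discriminator on 64 latent columns each |
| gradient clip | 5.0 (global norm) | guards the adversarial phase; disable via config |
| marker genes | top 200 per type | one-vs-rest Wilcoxon rank-sum on log-normalized counts, ties broken lexicographically |
| normalization | 10⁴ counts/row + log1p | applied identically to real and pseudo spots, after gene subsetting |

Hidden widths, the LeakyReLU slope (0.01), weight initialization (uniform
fan-in) and the optimizer family beyond its learning rate are this
package's own choices, exposed in configuration.

Pseudo-spot composition: cells per spot t ~ round N(μ_t=10, σ_t=5) clamped
to [2, 30]; distinct types c ~ round N(μ_c=4, σ_c=2) clamped to
[1, min(K, t)]; c types drawn uniformly; t partitioned uniformly at random
into c positive parts; cells sampled with replacement within each type
(so rare types can still fill spots); spot expression is the *sum* of cell
counts (spots physically aggregate transcripts), normalized afterwards.
These defaults describe Visium-like spot occupancy. Each spot draws from a
counter-derived substream of the seed, so enlarging a batch never reshuffles
earlier spots.

## Evaluation metrics

Per cell type, across spots: Pearson correlation; a global structural
similarity index on min-max-scaled vectors with stabilizers C1 = 0.01,
C2 = 0.03; RMSE; and Jensen-Shannon divergence (log base 2, hence in
[0, 1]) between the normalized spatial distributions. The Accuracy Score
ranks competing methods per metric (best = rank N), normalizes ranks by N
and averages the four; this keeps AS in (0, 1] with 1 for a method strictly
best everywhere, and ties share mean ranks. Region AUC scores the summed
proportions of a region's constituent types against in-region membership
via the Mann-Whitney formulation (ties count one half). Degenerate
(constant) vectors yield flagged NaN entries excluded from means.

## Synthetic fixtures

`make_reference` plants a disjoint block of `markers_per_type` marker genes
per type: baseline per-gene rates are log-normal(0, 0.5), a type's markers
are multiplied by `signal` (default 8), and counts are negative binomial
with dispersion 0.25 (variance μ + 0.25 μ²). `make_ground_truth_st` draws
spot proportions from a symmetric Dirichlet (default α = 1; a `blocks`
pattern tilts contiguous spot regions toward region-specific types),
realizes per-type cell counts by a multinomial over a clamped-normal total,
and sums sampled cells — exactly the pseudo-spot construction, but from a
held-out half of the reference cells so training never sees the cells that
built the evaluation spots.

What the fixture does **not** emulate: platform-specific capture-efficiency
differences between scRNA-seq and ST, spot bleed, segmentation error, or
real spatial geometry. In particular, because the synthetic ST spots are
generated by the same mixing process as the pseudo-spots, there is
essentially *no domain gap* between source and target in the fixture.
Passing the recovery tests therefore demonstrates that the supervised
transfer pipeline works end to end, not that the adversarial alignment is
beneficial — on this fixture it has nothing to align and acts as a
regularizer. Conclusions about adversarial benefit require data with a real
platform gap.

## Problem sizes used in tests

The integration tests and the acceptance script run a deliberately small
configuration: K = 5 types, G = 200 genes, 200 cells/type, 500 spots,
2000 pseudo-spots, 50 epochs, batch 256, with the default architecture.
At this scale a full run takes about a minute on one CPU and typically
recovers proportions with mean per-type PCC in the 0.90–0.97 range and
RMSE 0.07–0.16 depending on the seed; the adversarial term is the main
source of run-to-run spread (see the fixture caveat above). Ablation
comparisons use the same protocol over three seeds.

## Numerical notes

- BCE predictions are clipped to [1e-7, 1 − 1e-7]; all losses are finite
  for finite inputs.
- Softmax subtracts the (detached) row maximum before exponentiation.
- Batch-norm uses batch statistics in training and frozen running averages
  (momentum 0.1) at inference; a mini-batch of one observation is skipped.
- All randomness flows from explicit seeds through `numpy.random.Generator`;
  training, simulation and inference are bitwise reproducible
  single-threaded.
- Rounded proportion CSVs are re-projected onto the simplex on read.
- Run artifacts are stamped with a SHA-256 content hash of the
  configuration via `manifest.json`, `report.json` and the run log.

## Known limitations

- Dense in-memory matrices: intended scale is ≤ ~5k spots × ~3k genes.
- No GPU path; the numpy networks are adequate at the intended scale but
  not for atlas-size references.
- No quality-control filtering, batch correction or image registration;
  inputs are assumed pre-filtered.
- Fixed-length training (no early stopping), mirroring the method's
  fixed 200-epoch schedule.
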