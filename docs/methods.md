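# Methods

`semiprofile` implements single-cell *semi-profiling*: given bulk RNA-seq
for every sample of a cohort and real single-cell data for a small set of
*representative* samples, it infers a single-cell expression matrix for
every remaining sample, and decides — by clustering or active learning —
which samples are worth sequencing for real. This note records the models,
the parameter choices and their rationale, what the synthetic cohorts do
and do not emulate, and the numerical decisions a maintainer would want to
know about.

## Pipeline overview

1. **Bulk setup.** Bulk counts are library-normalized (target 10,000) and
   log1p-transformed; the top highly variable genes (Seurat-style
   mean-binned dispersion, 20 bins; default 6,000, plus any forced markers)
   define the gene panel; PCA to `min(100, n_samples − 1)` components gives
   the bulk embedding `D_b` operates in. K-means (10 restarts, seeded) into
   B clusters selects the sample nearest each centroid as that cluster's
   representative. A *global mode* scores candidate B by silhouette instead
   of iterating.
2. **Representative processing.** For each representative's cells:
   background removal (entries strictly below 0.1% of the cell's library
   are zeroed; at-threshold values kept), standard QC (cells expressing
   < 200 genes, genes in < 3 cells, mitochondrial fraction > 20%, doublet
   proxy > 6,000 genes; samples left with < 1,000 cells are flagged, not
   dropped), normalization to 10,000 counts/cell + log1p, alignment to the
   bulk gene panel, gene-set scores (mean of each set's normalized pre-log
   expression, then log1p), feature-importance weights, and self-inclusive
   K = 15 nearest-neighbour averaging of the log-scale feature matrix (the
   precomputed message-passing step of a graph-convolution layer).
3. **Generative model.** A VAE generator with a ZINB observation model and
   an adversarial discriminator (details below).
4. **Inference.** Per target sample, the pretrained generator is fine-tuned
   so the pseudobulk of its generated cells matches the target's pseudobulk
   estimate; decoding every representative cell through the fine-tuned
   model, then zeroing entries below the activation threshold (0.1% of the
   library, matching background removal), yields the inferred matrix. One
   generated cell per representative cell.
5. **Active learning.** After a round, each cluster's heterogeneity is the
   sum over members of `D_b + λ_sc·D_sc + λ_pb·D_pb` (λ's default 1): bulk
   embedding distance, directional K = 1 single-cell KNN distance (real
   cells for representatives, the latest inferred cells for targets, in a
   joint PCA space), and log1p-pseudobulk distance. The most heterogeneous
   clusters are split; within a cluster the new representative minimizes
   the total bulk distance of members to the nearer of (old, new)
   representative — the split score deliberately uses bulk distance only,
   mirroring how cluster choice and split choice are specified differently.
   Splitting is applied one cluster at a time so a single large cluster can
   absorb several picks when fewer than B clusters are splittable.
6. **Stop criteria.** Newly sequenced representatives are compared with
   their previous-round inferred versions; mean Pearson ≥ 0.85 on
   proportions (level 1), marker dot-plot summaries (level 2), or analysis
   matrices (level 3) stops the loop.

## The generative model

Each cell is the concatenation of gene expression and gene-set scores
`(x_i, s_i)`. The encoder (two linear branches — genes and set scores —
summed into a 256-unit ReLU hidden layer) maps the neighbour-aggregated
features to a diagonal Gaussian `q(z | x_i, s_i)` over a 32-dimensional
latent variable. The decoder (256-unit ReLU hidden layer) emits, for gene
features, softmax mean fractions ρ(z) on the gene simplex, dropout
probabilities π(z), and a free gene-wise inverse-dispersion vector θ — the
SCVI parameterization of a zero-inflated negative binomial with NB mean
`μ = library·ρ`; a separate linear head reconstructs the gene-set scores
with a weighted squared-error (Gaussian) likelihood. The reconstructed
cell exchanged with the discriminator and the bulk losses is the ZINB mean
`μ·(1 − π)`. Weights are Kaiming-initialized; Adam with weight decay 1e-6;
all randomness flows from explicit seeds, and per-target sub-seeds are
derived by hashing so results do not depend on the order targets are
fitted.

The discriminator is a 4-layer MLP (256, 128, 10 hidden units, leaky
rectifiers, sigmoid output) scoring the probability a cell is real. Its
input is the same concatenated feature layout the generator reconstructs,
with the expression part log1p-compressed so real and generated features
share a scale.

**Losses.** The VAE loss is the feature-weighted ZINB negative log
likelihood plus the closed-form Gaussian KL to the standard-normal prior.
The adversarial term adds `−λ_d · Σ −log(1 − D(G(·)))` (λ_d = 0.01 by
default; the λ's have no published values and are exposed in
`LossWeights`). The representative bulk loss is the L2 distance between
the pseudobulk (per-gene mean of normalized cells, gene features only) of
the reconstruction and of the input; the target bulk loss replaces the
input pseudobulk with the *target pseudobulk estimate*. Probabilities are
floored at 1e-8 inside logarithms.

**Squared-error training form.** The bulk losses are defined (and
reported) as L2 norms, but the training objective uses their squares. A
raw norm has a unit-magnitude gradient that never vanishes: at the large
late-stage bulk weights it perpetually reallocates softmax mass away from
genes excluded from the loss, collapsing their means. The squared form has
the vanishing-at-optimum gradient the mini-stage strategy (below) assumes
— its premise is precisely that larger residuals receive larger gradients.

**Feature-importance weights** are proportional to per-feature variance on
the *likelihood-target scale* (normalized counts for genes, scores for
gene sets), rescaled to mean 1 and floored at 0.01. The count scale
matters: an overdispersed NB is nearly flat in its mean for large values
(gradient ∼ 1/μ), and count-scale variance weights — which grow roughly
like μ²/θ — restore the anchoring of highly expressed genes that log-scale
weights cannot provide.

## Training schedule

- **Pretrain 1** (reconstruction): generator alone for 100 epochs
  (minibatch 128, lr 1e-3), then 100 alternating iterations of 3 generator
  epochs and 3 discriminator epochs.
- **Pretrain 2** (bulk-aware): same structure at 50/50/3 with lr 1e-4,
  full-batch (falling back to fixed-size accumulation batches above a cell
  budget), with `λ_BulkR · L²_BulkR` added (λ_BulkR = 1).
- **Inference** (per target): the discriminator is retired. Five
  mini-stages with thresholds (none, 1/2, 1/4, 1/8, 1/(8√2)) of the peak
  normalized expression `max_expr` of the representative matrix: in stage
  k, genes whose per-gene peak exceeds the threshold are excluded from the
  bulk loss (equivalently, their bulk-loss gradients are zeroed) and the
  bulk weight is quadrupled, shifting optimization from highly to lowly
  expressed genes. lr 2e-4, each stage capped at 150 epochs with patience
  10 — counted only after a 30-epoch minimum, because a freshly
  initialized optimizer transiently raises the loss and must not be
  mistaken for convergence.
- **Model selection.** Across all inference epochs the checkpoint
  minimizing the stage-wide objective — per-cell NLL plus
  `λ_BulkT · (full-gene bulk L2)²` at the base weight — is kept. "Until
  convergence" is otherwise ill-defined across mini-stages whose own
  losses are computed on different gene subsets; without this, late masked
  stages can return a model whose excluded genes have silently drifted.

**Target pseudobulk estimate.** With real bulk for both samples, the
conversion ratio `α = (B_T + ε) ⊘ (B_R + ε)` (ε = 0.1) converts the
representative's pseudobulk into the target estimate `pb_R ⊙ α`; the ratio
cancels gene-wise platform bias that is consistent across samples. When
pseudobulk is available directly, the estimate is the target pseudobulk
itself and the ratio path is bypassed.

## Evaluation

`Dif_sc` is the symmetric K = 1 (configurable) nearest-neighbour distance
between two cell matrices in a shared 100-component PCA space, normalized
by the total cell count. The cohort error
`E_N = (mean_i Dif_sc(m_i, m̃_i) − LB)/(UB − LB)` uses a random-pairing
upper bound (100 seeded pairings; representatives contribute LB by
definition) and a split-half lower bound of the pooled cells. Real
matrices entering the evaluation receive the same background removal and
normalization as profiled representative data, so real and generated
supports agree — comparing raw counts against thresholded reconstructions
systematically penalizes the generator for zeros the preprocessing would
have removed anyway. When E_N is compared across representative counts,
all rounds are evaluated in one PCA space (real cells plus every round's
generated cells); per-round spaces are not comparable. Inference
difficulty (for the active-vs-passive comparison) is the mean directional
D_sc of each sample to its representative, computed on real cells in a
real-only PCA space so runs with and without inference share coordinates.

Deconvolution-style accuracy uses per-sample Lin's CCC, Pearson r, and
RMSE between annotated (MLP classifier trained on representatives'
labelled cells, seeded) and true proportions. RRHO matrices report
`−log10 P(X ≥ k)` hypergeometric overlap tails between ranked marker
lists over the HVG universe (the ≥ convention is deliberate and tested).
Activation matrices are gene-set mean fold changes per cell type versus a
reference condition, blanked under a minimum cell count. Grid summary
correlation bins two 2-D embeddings into a 20×20 grid and correlates
co-occupied cell means. The cost model prices bulk sequencing (one run at
$7,000 plus $110 library preparation per sample) against single-cell
profiling at $0.30/cell and 5,000 cells/sample.

## Synthetic cohorts

`synthetic.generate_cohort` draws, per sample, Dirichlet cell-type
proportions, per-cell type labels, and ZINB counts around
`type_mean ⊙ condition_shift ⊙ sample_shift`:

- **Type profiles**: log-normal base rates with a boosted marker block per
  type (defaults: 5% of genes, 8-fold) — enough separation for marker
  structure and annotation without making types trivially separable.
- **Condition shifts**: per-condition multiplicative gene factors,
  optionally cell-type-specific. Type-specific responses matter: a purely
  gene-wise shift is exactly representable by bulk-guided scaling, which
  would make cross-condition inference unrealistically easy.
- **Sample shifts** (`sample_shift_scale`, default 0.2 log-sd): gene-wise
  log-normal per-sample factors. Without them, samples differ only in
  composition, and a K = 1 cell-level distance cannot see composition-only
  differences (supports overlap) — there would be nothing for bulk-guided
  inference or active learning to recover.
- **Real bulk**: `pseudobulk ⊙ exp(g) ⊙ exp(η)` with a gene-wise bias `g`
  shared across samples (scale `bulk_bias_scale`, default 0.5 — on log
  scale this yields a real-bulk/pseudobulk correlation around 0.85–0.9,
  emulating the systematic platform discrepancy seen between matched bulk
  and pseudobulk) and small per-sample noise `η` (default one tenth of the
  bias scale). Shared `g` makes conversion ratios stable across samples —
  the estimator's assumption — while `η` lets tests falsify it.

What the generator does **not** emulate: batch effects, continuous
differentiation trajectories within types, gene–gene correlation beyond
the mixture structure, spliced/unspliced counts, or spatial structure.
Within a type, cells are exchangeable ZINB draws, so cell-level variation
is pure count noise — a harder regime for mean-emitting generation than
real manifolds, and the reason evaluation fixtures use moderately deep
libraries. Passing tests therefore demonstrate recovery of composition,
sample-level expression shifts and cluster structure, not trajectory- or
batch-level fidelity.

## Benchmark experiment sizes

The packaged experiments (`semiprofile.experiments`, driven by
`scripts/acceptance.py`) use: a 300-cell × 200-gene representative for
identity recovery and for the doubled-proportion transformation (3 cell
types at proportions 0.5/0.3/0.2; the second type is doubled); a 12-sample
cohort for conversion-ratio inference; and a 16-sample, 120-gene,
120-cells-per-sample cohort with four planted cell-type-specific condition
clusters for the selection curves, grown 2 → 4 → 8 representatives with
fine-tuning capped at 60 epochs per mini-stage. The selection cohort's
clusters are deliberately unequal in size (6/4/3/3) and in shift magnitude:
balanced, equally spread clusters make plain bulk-distance selection
already optimal, leaving nothing for the heterogeneity objective to
allocate budget over, which is the regime the active algorithm exists for. Cohort generation uses
fixed internal seeds — the synthetic data play the role of a published
dataset — while the caller's seed drives model initialization, training,
clustering and pairing randomness.

## Known limitations

- The generator emits ZINB means (denoised cells); distances to noisy real
  cells therefore carry an irreducible noise floor, and on very shallow
  or tiny fixtures copying a representative's real cells can rival
  generation.
- θ moves slowly under gradient training from its init (1.0); the
  count-scale feature weights compensate for the resulting likelihood
  flatness rather than fixing θ's estimation.
- Active and passive selection converge to similar picks when bulk
  distance is an almost-perfect proxy for single-cell difficulty; the
  active advantage appears when bulk is noisy or distorted, as with real
  platform effects.
- The per-gene mini-stage masks use each gene's peak representative
  expression; with few genes and heavy-tailed expression the masks exclude
  only a handful of genes per stage.
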