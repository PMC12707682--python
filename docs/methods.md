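# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices, and the limits of what the test suite demonstrates.

## Problem and model

The package predicts, for each student in a cohort, an overall well-being
score y ∈ [0, 1] and its decomposition into the five PERMA dimensions of
positive psychology (Positive emotions, Engagement, Relationships, Meaning,
Achievement). The architecture has four stages.

**1. Relationship graphs.** Four symmetric, zero-diagonal adjacency matrices
are built over the same cohort: clipped-cosine similarity, a Gaussian kernel
of Euclidean distances, a binary shared-learning-style graph, and a
PERMA-weighted graph Σₚ wₚ·simₚ computed on prior-masked features. Edges
below the shared threshold (default 0.3, closed: entries equal to the
threshold are kept) are removed. Negative cosine similarities are clipped to
zero before thresholding so all four graphs share a [0, 1] weight scale and
the one threshold is meaningful for each. The Euclidean kernel uses the
median nonzero pairwise distance as bandwidth — a bounded, monotone map from
distance to similarity with no free parameter. simₚ is clipped cosine on the
prior-masked features; the per-dimension similarity is otherwise
unconstrained by the framework, and cosine keeps the PERMA graph on the same
scale as the others. Comparisons against the threshold allow a 1e-12 slack
so pairs analytically *at* the threshold survive floating-point round-off.

**2. PERMA feature embedding.** Two representations are derived from the
feature matrix X (min-max scaled to [0, 1]): an interpretable n×5 score map
X·W_PERMA + b, and a five-token sequence, token_p =
lift(GELU(X·U_p + e_p)) with token width 128 lifted to the model width 256.
Keeping both resolves the tension between a 5-column interpretable map and a
128-dimensional embedding: the score map serves reporting and the PERMA
graph prior; the tokens feed the encoder, one token per dimension.
Initialisation blends a psychological prior with Xavier-uniform noise:
score_map = s·prior + (1−s)·random, and the feature rows of U_p are rescaled
toward the (mean-one normalised) relevance of each feature to dimension p;
the blend strength s ∈ [0, 1] defaults to 0.5. The default prior puts 0.6 of
a feature's mass on its block's dominant dimension (learning→E, social→R,
physical→P, mental→M) and 0.1 elsewhere. This allocation is a configurable
convention — no canonical item-to-dimension mapping exists for generic
survey features — and can be replaced by a JSON prior file.

**3. Relational encoding.** Per topology: three GCN layers
ReLU(D̃^{-1/2}ÃD̃^{-1/2}HW) on the self-loop-normalised adjacency (raw
features in, hidden width 128), then one 8-head GAT layer (head width 32,
LeakyReLU slope 0.2, ELU output, neighbourhoods include self) on the raw
thresholded adjacency. GCN-then-GAT ordering puts the attention maps on the
most refined representations. Branch outputs are fused per student by
softmax weights over the four topologies, scored from embedded learning
style and stress level only; the scoring vectors are zero-initialised so
every student starts at exactly uniform (0.25 per topology) and the weights
stay interpretable per student. The fused vector enhances the PERMA tokens
through single-head residual cross-modal attention (one key/value per
student, so the softmax is a singleton and the learned content is the
value/output projection).

**4. Encoder and heads.** A pre-norm transformer encoder (6 layers, width
256, five heads of width 64 — concatenated 320, projected back to 256 — FFN
1024 with GELU, dropout 0.1) runs over the 5-token sequence. Pre-norm
blocks were chosen for stability at this depth without warmup sensitivity.
Global average pooling feeds two sigmoid affine heads (overall and 5-dim).
The loss is L = λ₁·MSE(ŷ, y) + λ₂·MSE(Ŷ, Y) + λ₃·MSE(ŷ, rowmean(Ŷ)) with
λ = (1.0, 0.8, 0.5); the consistency term enforces the framework's
assumption that overall well-being tracks the mean of its dimensions.
Culture never enters the architecture by default (there is an optional
learned per-culture token offset, off by default); it is used for
stratified evaluation.

## Training

Training is transductive: graphs are built once over the whole cohort from
features only — labels never influence edge construction, so no label
leakage — while losses and metrics use only the relevant split. The split is
stratified 7:2:1 (train/validation/test) over learning-style × stress-level
cells (culture is added automatically for multi-cultural cohorts); strata
smaller than 3 are merged into the largest stratum with a warning ("nearest"
is undefined for categorical composites). Students are ordered within a
stratum by a seeded hash of their content, which makes the partition
deterministic and equivariant under row permutations. AdamW
(β = 0.9/0.999, ε = 1e-8, weight decay 1e-5) with gradient clipping at
global norm 1.0; linear warmup over 500 steps then cosine annealing to
1e-6; batch size 32 (batches index students for the loss; message passing
always runs over the full graph); early stopping on validation total loss
with patience 15, returning the best-validation-epoch parameters. The
default learning rate is 1e-4 (the sensitivity analyses identify it as
optimal; 2e-4 also appears as a nominal setting, and the optimum is used
here). Everything is a pure function of config + seed.

All of this runs on `permawell.autodiff`, a compact numpy reverse-mode
automatic-differentiation core written for this package (broadcasted
arithmetic, batched matmul, the activations above, softmax, layer norm,
gather/concat, AdamW). Gradients are verified against central finite
differences in the test suite.

## Evaluation framework

* MAE and RMSE on the overall prediction (RMSE ≥ MAE always).
* PDA = mean over dimensions of (1 − MAE): per-dimension accuracy on [0, 1].
* PCI = 1 − mean |ŷ − rowmean(Ŷ)|: internal consistency, labels play no role.
* PCE = α·PDA + β·PCI + γ·(1 − RMSE_norm), weights (0.4, 0.3, 0.3).
  RMSE_norm is RMSE divided by the label range (1.0 for [0, 1] labels) and
  capped at 1, so PCE stays in [0, 1] on any dataset.
* Consistency-violation rate: the fraction of students with
  |ŷ − rowmean(Ŷ)| > ε. No canonical ε exists; the default is 0.1 and the
  value used is always reported alongside the rate.
* Model comparison: two-sided paired t-tests on per-student *absolute*
  errors (the error sign convention is otherwise ambiguous), s_d with the
  n−1 denominator; degenerate zero-variance pairs are flagged rather than
  producing NaN. Raw p-values by default, optional Holm adjustment.

## Synthetic cohorts

The generator emulates the structure the method assumes in real survey
cohorts. Each student draws latent PERMA factors π ∈ [0, 1]⁵ from a
truncated normal whose mean vector and sd depend on the student's cultural
group (defaults: two groups of equal proportion with shifted latent means,
sd 0.15 — culture enters *only* through the latent distribution). Features
are clip01(L·π + noise) with a nonnegative block-aligned loading matrix
(0.6 dominant / 0.1 off) and feature noise sd 0.05, then min-max rescaled
per column; PERMA labels equal the latents; the overall label is
clip01(mean(π) + noise) with label noise sd 0.05; learning styles are
uniform over 4 categories; stress level is the rank tertile of 1 − π_P
(stress is treated as an observed attribute and needs a deterministic,
testable definition; the complement of positive emotions is the natural
latent proxy). Size presets mirror the two survey scales: `small` (268×23)
and `large` (12757×23); the default test-bed cohort is 512×23.

What the generator does **not** emulate: item-level discreteness (Likert
grids), missing responses, culture-dependent response styles beyond mean
shifts, dependence between stress and features other than through the
latents, and any temporal structure. Passing tests therefore demonstrate
that the implementation is faithful and that the method behaves as designed
under its own assumptions — not that it attains any particular accuracy on
real survey data.

## Reduced-scale harness

The ablation, sweep, learnability and consistency studies run a desk-scale
configuration: width 64 (token 32, FFN 128), 2 encoder layers (5 heads × 16),
2 GCN layers × 64, 4 GAT heads × 16, batch 128, 30 epochs, warmup 20 steps,
learning rate 1e-3 (schedules this short need a faster rate; 3e-3
destabilised optimisation in bring-up experiments, collapsing the predictor
to a constant). Problem sizes: cohorts of 512 students for the studies,
64–128 for smoke tests. The ablation harness trains stepwise variants —
tokens-only MLP, + prior initialisation, + multi-topology GNN with
cross-modal attention, + dimension-aligned encoder, + consistency loss —
over several seeds and reports mean ± sd of MAE/PDA/PCI/PCE.

## Known limitations

* Dense n×n adjacency representation: memory is quadratic in cohort size;
  fine up to tens of thousands of students, no approximate-neighbour path.
* The numpy core is single-threaded per op and CPU-only; the full-scale
  configuration (6×256) trains slowly compared to a GPU framework.
* On [0, 1]-bounded features with nonnegative loadings, cosine similarities
  concentrate near 1, so the cosine graph is near-complete at threshold 0.3;
  the euclidean and style graphs carry most of the discriminative structure.
* Consistency regularisation improves PCI on average (verified over seeds);
  on an individual seed the gain can be marginal or slightly negative.
* The prior map is a convention, not a validated psychometric instrument;
  conclusions about individual PERMA dimensions inherit its arbitrariness.
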