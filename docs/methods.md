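# Methods

## Model

Let the alignment have S sequences and p positions. One-hot encoding maps
position i to as many binary bit-columns as the number of distinct
unambiguous states observed there (≤ 4 for nucleotides, ≤ 20 for amino
acids, +1 if gaps are encoded as a state). Monomorphic bit-columns are
removed: a constant column cannot discriminate classes and, for the
all-ones case, is collinear with the intercept. Each sequence j carries a
response y_j ∈ {+1, −1} (focal clade / trait vs. the rest) and a sample
weight w_j.

The fitted object minimizes

    L(β0, β) = (1/Σw) Σ_j w_j log(1 + exp(−y_j(β0 + x_jᵀβ)))
             + λ1 ‖β‖1 + λ2 Σ_g w_g ‖β_g‖2

with the intercept unpenalized. The group norm is the Euclidean norm; with
any other choice (e.g. an l1 sum) the group term would collapse into a
rescaled lasso and no group-level zeroing would occur. The loss is
normalized by the total weight so that λ values are comparable across data
sets of different size.

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ1 | 0.05·λ_max (workflow) | position-level sparsity; λ_max is the smallest λ1 that zeroes all β |
| λ2 | 0.05·λ_max (workflow) | gene-level sparsity |
| w_g | √(gene length) | group weight; keeps long genes from being penalized out purely by size |
| balance | class weights w_c = S/(2·S_c) | equalizes per-class weight mass; up/down-sampling available |
| tolerance | 1e-6 relative objective change | solver stop rule |
| max_iterations | 10,000 | solver cap |
| refit | group lasso at 0.01·λ_max of the reduced problem | robust re-estimation on selected genes; plain ridge available |
| ambiguity | `missing` (no bits) | `constituent_bits` sets the bit of each constituent state instead |
| gaps | no bits | `gap_as_state` gives '-' its own bit-column |

The workflow defaults λ1 = λ2 = 0.05·λ_max were chosen as a "small"
regularization level on the λ_max scale: strong enough that most genes are
zeroed, weak enough that genes carrying genuine concordant variation
survive. They are a starting point, not a recommendation — λ should be
chosen per data set via the CV (`cross_validate`) or stability-selection
(`stability_select`) helpers, both exposed with explicit grids because
each data set's useful range depends on its signal density.

Class weights use the standard inverse-frequency form S/(2·S_c); any
formula with equal per-class mass would serve, and this one reduces to
unit weights for balanced data.

## Solver

FISTA on the smooth weighted logistic loss with the composite nonsmooth
penalty entering through its exact proximal map: componentwise
soft-thresholding at t·λ1 followed by per-group Euclidean shrinkage at
t·λ2·w_g (the two operations compose exactly for this penalty pair). The
step size starts from a power-iteration bound on the gradient's Lipschitz
constant and backtracks when the majorization test fails. Momentum uses
the standard t_k schedule with a function-value restart: whenever the
accelerated step would increase the objective, momentum resets and a plain
proximal-gradient step is taken from the previous iterate, so the recorded
objective sequence is non-increasing. Initialization is β = 0 with β0 at
the weighted log-odds (the intercept-only optimum), which makes the null
model (λ1 ≥ λ_max) an immediate fixed point. Convergence is declared at a
relative objective change below the tolerance; the fit itself contains no
randomness.

λ_max is computed in closed form as the sup-norm of the loss gradient at
the intercept-only optimum; it is exact for the lasso and remains an
upper bound for the composite penalty (the group subgradient can absorb
zero).

## Resampling

Sequence bootstrap resamples rows with replacement *within each class*,
preserving class sizes so no replicate degenerates. Site bootstrap
resamples alignment positions with replacement; a sampled position brings
its bit-columns and gene membership along, and replicate scores are
aggregated back onto original coordinates (a position drawn twice
contributes twice, as in any site-bootstrap). Both re-run the full
selection + refit pipeline per replicate. Replicates whose solver fails
to converge are excluded and counted; more than 10% failures aborts the
run. The 95% support threshold is strict (support must exceed it) and
configurable. Sequence resampling is the default mode because it
resamples the statistical units of the regression; site mode is provided
as an alternative view of positional robustness, and the two are not
interchangeable, so the CLI requires the mode to be stated.

The permutation null redraws ±1 labels by fair coin (rejecting one-class
draws), balances with class weights, and fits the selection stage; it
reports per-gene inclusion frequencies with min/median/max. Under the
null, genes still enter individual models at moderate frequencies — a
consequence of fitting to noise — but none should be stable across
replicates at the 95% level.

## Synthetic data

The generator plants signal directly: non-diagnostic positions are i.i.d.
uniform (optionally skewed) over the alphabet; each diagnostic position
has a clade state carried by members with probability `fidelity` and by
non-members with probability `leakage`, otherwise a distinct background
state. Defaults — S = 100, p = 2,000 nucleotides, 20 contiguous
equal-length genes, a 30-taxon clade, 2 diagnostic genes × 10 diagnostic
positions, fidelity 0.95, leakage 0.05 — represent a modest phylogenomic
screen with strong but imperfect signal. Direct injection gives exact
ground truth for recovery tests; what it does *not* emulate is
phylogenetic autocorrelation (sites evolved along a tree are not i.i.d.
given the clade, and background positions carry residual tree structure),
rate variation, or indel patterns. Passing recovery tests therefore
demonstrates that the estimator finds concordant-state structure at
realistic sparsity and noise levels, not that real alignments are this
clean; on real data, tree-induced correlation makes the permutation and
bootstrap controls more important, not less.

Type-I control checks use alignments simulated with no diagnostic genes
and a strong regularization level (0.3·λ_max): at signal-detection λ
values a null model happily absorbs noise genes with high replicate
support, which is precisely why support must be calibrated against a
strong-λ or permutation baseline rather than read off the analysis fit.

## Numerical choices and degenerate inputs

- Bit-columns are ordered by position, then fixed alphabet order, so
  encodings and models are byte-reproducible.
- Bit-columns are never centered or standardized; the coefficients'
  interpretation (and the scores built from |β|) depends on the raw 0/1
  coding.
- Ties at SPP = 0.5 classify as +1.
- Empty selection in the workflow returns an explicit empty-model result
  rather than raising; degenerate responses (one class), empty designs,
  overlapping groups, and out-of-range partition indices raise typed
  errors at the boundary where they are detectable.
- Singleton bit-columns (minor count 1) are retained; regularization,
  not pre-filtering, decides their fate.
- All stochastic steps (balancing resamples, CV folds, subsampling,
  bootstrap, permutation, simulation) take explicit seeds; CV caches
  per-(λ1, λ2) fits within a fold so duplicated grid points are exactly
  identical, and warm-starts along the λ path only affect speed.

## Problem sizes

Tests and the acceptance script run the full pipeline at S = 100,
p = 2,000 (≈ 5,900 retained bit-columns), 100 bootstrap replicates and 20
independent recovery simulations; module tests use smaller instances
(≤ 60 × 300). These sizes give stable estimates of the recovery and
support proportions being checked while keeping a complete run in the
low minutes on one CPU.

## Known limitations

- Multiclass/multilabel responses, overlapping or hierarchical group
  penalties, ElasticNet, and parametric (covariance-test) significance
  are out of scope.
- The l1-path is computed by proximal gradient per λ, not by a path
  algorithm; very fine grids cost proportionally.
- `predict` scores sequences against the training bit-column map; states
  unseen in training contribute nothing, which is conservative for
  divergent query sequences.
- FSS requires an explicit category map; no default "all genes" category
  is invented.
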