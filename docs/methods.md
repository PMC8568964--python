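# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator, and the numerical and design choices behind
`scnormlm`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model and normalization

Sequencing of cell *j* is modeled as binomial sampling of each gene's mRNA
proportion from the cell's pool: g_ij | n_j, p_ij ~ Binomial(n_j, p_ij)
with n_j the cell's total UMI count. With a uniform prior, the posterior
of p_ij is Beta(1 + g_ij, 1 + n_j − g_ij), and the posterior mean of
ln p_ij,

    y_ij = psi(1 + g_ij) − psi(2 + n_j),

is the minimum-MSE log-expression estimate ("Bayesian log expression").
It is defined for every count including zero, strictly negative, and uses
no pooling across cells or genes — deliberately, so that no imputation-like
smoothing can manufacture correlations. The suite verifies this estimator
against direct numerical quadrature of the Beta posterior at 1e-8.

Depth confounds y at the mean and variance levels, and nonlinearly so. The
mean-level correction regresses Y on *cellular summary covariates*:
monomials in b1 = ln n_j and b2 = (number of zero-count genes in cell j).
The shipped default set {1, b1, b1², b2} is what restricted forward
stepwise selection recovers on synthetic null data (see below). User
covariates (batches etc.) are concatenated, one-hot encoded when
categorical (all levels kept; redundancy is removed by the rank-revealing
orthonormalization with tolerance 1e-10), centered, and orthonormalized,
leaving the intercept as literal ones.

The variance model pools squared mean-model residuals per cell,
v_k = Σ_i ε²_ik, and fits ln v = α_v · C + ε. One shared model for all
genes keeps nuisance parameters few; zero v_k (possible only in degenerate
fixtures) are clamped to the smallest positive value. Normalization
rescales residuals per cell,

    y~_ij = y^_ij + (y_ij − y^_ij) / v^_j^(γ_i / 2),

with γ_i the gene's zero-count number divided by the maximum over genes
(γ = 0 everywhere when the matrix has no zeros), so that zero-inflated
genes — whose measurement noise varies most across cells — are rescaled in
full while accurately measured genes are untouched. Continuous covariate
values are divided cell-wise by v^_j for testing; categorical indicators
are restored to raw one-hot form; the intercept is untouched.

**Scale convention.** The fitted v^ is defined up to an overall constant as
far as P values are concerned (a per-gene constant factor on residuals
changes no correlation), but it does change logFC estimates: dividing by a
v^ whose scale grows with the number of genes would shrink zero-inflated
genes' logFC by an arbitrary dimension-dependent factor. `normalize`
therefore rescales v^ to unit geometric mean before applying it. The
acceptance suite's logFC-recovery test (bias coefficients ≈ 1 across all
expression bins) is the direct check of this convention.

**Outlier cells.** The inverse fitted variance is modeled as normal; cells
between the r and 1−r percentiles (r = 0.02) initialize the non-outlier
set, maximum-likelihood mean/sd give every cell a two-sided P, and cells at
Bonferroni-adjusted P ≤ 1e-10 become outliers for the next round, to
convergence (max 100 rounds). A zero-sd fit or a non-positive threshold
declares no outliers. The fraction is checked against the prior bound r
with a warning.

## Exact association tests

With normalized expression and covariates, DE fits y~ = αs + βC̃ + ε and
co-expression fits y~_i = α y~_j + βC̃ + ε. Both reduce to the correlation
of the two covariate-residualized vectors; under the null and normal
errors, its square follows Beta(1/2, (n_c − 1 − rank C̃)/2) exactly, which
equals the classical two-sided Pearson/t test when C̃ is the intercept
alone (verified at 1e-10). logFC is the least-squares α̂; co-expression
reports conditional Pearson R, symmetric in the pair by construction.
Genes with zero residual variance are flagged and reported as R = 0,
P = 1 rather than raising, so batch runs survive degenerate rows. The
design rank is computed numerically (SVD, tolerance 1e-10 relative).

Multiple testing: Benjamini–Hochberg Q values within user-specified groups
(per gRNA for screens, except the pooled TSS-target group; per gene for
networks); Storey's π̂₁ with the λ = 0.5 plug-in as an empirical
false-positive-rate estimate; Fisher's method for gRNA-to-gene-level
combination (a zero input P yields 0 with a warning).

## Covariate selection

Candidate covariates are monomials in (b1, b2) restricted to those whose
every lower-order term is already selected (downward closure), capped at
total order 4. Each candidate is scored by running the full
normalization + co-expression pipeline on a fixed subsample of gene pairs
(default 1e5) of a synthetic null dataset and computing the uniformity
score: the **mean** over expression-bin-pair groups (10 gene bins by
expressed-cell count → 55 pair groups) of the one-sample KS statistic
against Uniform(0, 1). The mean, not the worst group, is used because with
strong depth confounding many strata sit at KS ≈ 1 simultaneously and a
max-aggregated score cannot rank candidates at all — forward selection
would stall at the intercept. A step is accepted when it lowers the score
by more than `stop_tolerance` = 0.001, roughly five times the score's
sampling sd at the default subsample, so accepted steps reflect systematic
improvement; the observed fourth-step improvements on null data are an
order of magnitude below this threshold while the third covariate's
improvement is five times above it. Selection applies the standard QC
first and skips outlier removal (speed; it removes nothing on healthy null
data). Selection is deterministic given the dataset, subsample seed, and
tolerance.

## Synthetic null data

The generator states a world with *no co-expression whatsoever*: cell
depths n_j are drawn from a pool D_c (rescaled by the simulated/source
gene-count ratio, rounded, floored at 1), gene base proportions p_i from a
pool D_g, biological variation b_ij ~ N(0, σ²) i.i.d., and counts are
multinomial per cell with weights p_i e^{b_ij}. Ground-truth logFC between
any two cell groups is the difference of group means of
ln(p~_ij / Σ_k p~_kj). Defaults: σ = 0.5 (≈ 65% biological CV on the
natural scale — a typical homogeneous cell line).

When no real dataset supplies the pools, a parametric stand-in is used:
depths log-normal with median 2000 and sdlog 0.5; proportions Zipf-like
(∝ 1/rank over the simulated genes), mimicking a few-hundred-gene slice of
a droplet dataset. The logFC-recovery evaluation instead uses a
deep-sequencing variant (median depth 20,000): with ~2000-read cells,
upper-bin genes receive only ~1–3 reads each, and measurement noise
(~1/reads) then exceeds the biological variance σ² = 0.25, making
high-fidelity logFC recovery information-theoretically impossible for any
estimator; at 20,000 reads the criterion tests the method rather than
Poisson noise.

What a green calibration test does and does not establish: the simulator
reproduces depth confounding, zero inflation, and the multinomial
read-competition constraint of real UMI data, with i.i.d. log-normal
biological noise; it does not contain cell subpopulations, batch structure,
trajectories, or transcriptional bursting, so calibration here demonstrates
correct removal of depth-driven technical confounding, not robustness to
every biological violation of model assumptions.

The synthetic CRISPR screen assigns each cell 2 distinct gRNAs of 10 (1 for
a random 20% of cells). The capacity constraint makes indicators pairwise
anti-correlated, as in real high-MOI screens; a strictly fixed MOI is
deliberately avoided because it makes the tested indicator an exact linear
function of the untested ones, a degenerate design no real screen has. One
active gRNA multiplies 100 of 500 genes' proportions by e^{−0.5} in its
carrier cells; all other gRNAs are inert, so their associations with the
affected genes measure the false-positive rate.

## CRISPR screen logic

Cross-association between gRNAs is the per-pair odds ratio with the
one-sided (depletion) hypergeometric P. Competition-aware testing appends
untested-gRNA indicators as mean-only covariates at test time (they do not
enter variance normalization); above 10,000 total covariates the indicator
block is compressed once per screen to its top 500 principal axes, and the
tested gRNA's centered indicator is projected out of the PC rows at test
time so its own signal cannot leak into the covariates. Pair types follow
the six-way classification (TSS target/other, NTC-vs-targeted/other per
mode, enhancer); weaker/stronger gRNAs per target are ranked by the P of
the association with the targeted gene (ties by |logFC|, then id).
Off-target rate: significant (Q ≤ 0.05) trans-genes (different chromosome
or TSS distance > 1 Mbp) of the weaker gRNA that are clearly untouched
(P ≥ 0.1) by the stronger one, as a fraction of the weaker's significant
trans-targets, extrapolated by 1/(1 − 0.1) and clipped at 1; the screen
rate averages over weaker gRNAs with ≥ 1 significant trans-target.
Regulation edges require, for both gRNAs in both screens: target
repression (Q ≤ 0.05, logFC ≤ −0.2); trans response (Q ≤ 0.2,
|logFC| ≥ 0.05 absolute and relative to the target's); and no repressed
bystander (P ≤ 0.001, logFC ≤ −0.1) within ±1 Mbp of the targeted TSS
(TSS-to-TSS distance).

## Co-expression networks

Q values are computed per gene (each gene against all others as one BH
group, reflecting asymmetric gene roles); an edge exists when either
direction passes the cutoff (default Q ≤ 1e-15), signed by the conditional
R. Principal genes are the top-degree genes (ties lexicographic).
Program removal residualizes expression against current covariates,
extracts the top principal component of the gene-set rows (deterministic
sign: largest-magnitude loading positive), and appends it as one covariate;
iteration — choosing the next set and when to stop — is the caller's
judgment, by design. Annotation over-abundance uses a permutation null
(same number of annotated nodes re-drawn uniformly among network nodes)
with the add-one estimator P = (1 + #{null ≥ obs})/(n_perm + 1); sets with
fewer than two internal edges or more than half of all edges internal are
excluded, and a parent set is dropped when it annotates exactly the same
network nodes as its child.

## Numerical choices and limitations

- Orthonormalization: modified Gram–Schmidt with re-orthogonalization,
  drop tolerance 1e-10; deterministic row order.
- Pair-test memory is bounded by chunking (2^25 elements per block).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs.
- QC iterates gene and cell filters simultaneously on the current matrix
  to a fixed point; the gene cell-fraction threshold uses the current cell
  count. Defaults follow droplet conventions (500 reads / 100 genes per
  cell; 50 cells and 2% per gene) and are configurable for plate-based
  protocols with deeper per-cell sequencing.
- Known limitations: linear, cross-sectional associations only (no
  causal direction from co-expression; no mixed effects); the exact beta
  null assumes normal residuals — calibration at extreme sparsity relies
  on the variance normalization and is checked empirically, not proven;
  the asymmetric covariate scaling (values by 1/v^, residuals by
  v^{γ/2}) is applied as specified rather than harmonized, and its effect
  is absorbed by the numerical-rank-based degrees of freedom.
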