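# scnormlm

Normalization and exact linear-model association testing for UMI-based
single-cell RNA-seq, unifying differential expression, gene co-expression,
and high-MOI single-cell CRISPR screen analysis in one statistical
framework, together with a synthetic-null simulator for calibration and
method evaluation.

## The problem

Raw UMI counts confound biology with sequencing depth: cells differ by
orders of magnitude in total captured transcripts, and that shared technical
factor induces spurious gene–gene correlations and miscalibrated P values
in any test applied to naively normalized values (see the worked example
below — ~70% of null gene pairs reach P ≤ 0.05 under log-CPM). This package
removes that confounding and then tests associations with an *exact* null
distribution, so P values need neither permutation nor asymptotics.

## The model

Sequencing is treated as binomial sampling from each cell's mRNA pool. For
gene *i* in cell *j* with count *g<sub>ij</sub>* and cell depth
*n<sub>j</sub>* = Σ<sub>k</sub> *g<sub>kj</sub>*, a uniform prior on the
mRNA proportion gives the posterior Beta(1 + *g<sub>ij</sub>*,
1 + *n<sub>j</sub>* − *g<sub>ij</sub>*), and the minimum-MSE estimate of
the log proportion is its posterior mean

> *y<sub>ij</sub>* = ψ(1 + *g<sub>ij</sub>*) − ψ(2 + *n<sub>j</sub>*)

with ψ the digamma function (natural log throughout). Cellular summary
covariates — log depth, its square, and the number of zero-count genes,
recovered by restricted forward stepwise selection on synthetic null data —
absorb the remaining nonlinear depth confounding at the mean level; a
shared log-linear model of each cell's pooled residual variance rescales
residuals per cell, scaled per gene by γ<sub>i</sub> ∈ [0, 1] (the gene's
zero-count fraction relative to the most zero-inflated gene) so that
accurately measured genes are left untouched.

Associations are then tested with ordinary linear models on the normalized
values: DE as ỹ = αs + βC̃ + ε against a binary membership s (α̂ is the
natural-log fold change), co-expression as ỹ<sub>i</sub> = αỹ<sub>j</sub> +
βC̃ + ε (reported as a conditional Pearson R, symmetric in the pair).
Under the null, the fraction of residual variance explained by the
predictor follows Beta(1/2, (n<sub>c</sub> − 1 − rank C̃)/2) *exactly* for
normal errors, giving closed-form two-sided P values. For high-MOI CRISPR
screens, every untested gRNA's indicator enters as a mean-level covariate
("competition-aware" testing, compressed to 500 principal components for
libraries beyond 10,000 covariates), which removes the false positives that
anti-correlated gRNA assignment otherwise creates. Benjamini–Hochberg Q
values (grouped per gRNA / per gene), Storey's π̂₁, Fisher's method,
Q-value co-expression networks with gene-program removal, CRISPRi
off-target rates, and a four-condition regulation filter complete the
toolkit.

## Worked example

```python
import numpy as np
import scnormlm as sc

# simulate a depth-confounded null dataset (no true co-expression)
pools = sc.parametric_distributions(n_genes=500)
data = sc.simulate_null(pools, sc.SimulationConfig(n_cells=2000, n_genes=500, sigma=0.5, seed=0))
counts, _ = sc.qc_filter(data.counts)

# normalize: posterior-mean log expression + covariate and variance model
expr = sc.normalize_counts(counts)
print(f"normalized {len(expr.gene_ids)} genes x {expr.n_cells} cells; "
      f"covariates: {[t.label for t in expr.covariates_tilde.terms]}")

# exact co-expression tests on 10,000 random null pairs
rng = np.random.default_rng(0)
ii, jj = np.triu_indices(counts.n_genes, k=1)
sel = rng.choice(ii.size, 10_000, replace=False)
res = sc.test_coexpression(expr, np.column_stack([ii[sel], jj[sel]]))
print(f"null co-expression: fraction P<=0.05 = {(res['p'] <= 0.05).mean():.4f}")

# compare with the conventional log(CPM+1) pipeline, no summary covariates
logcpm = np.log(counts.counts / counts.cell_totals * 1e6 + 1)
naive = sc.test_coexpression((logcpm, np.ones((1, counts.n_cells))),
                             np.column_stack([ii[sel], jj[sel]]))
print(f"logCPM baseline:    fraction P<=0.05 = {(naive['p'] <= 0.05).mean():.4f}")
```

Output:

```
normalized 500 genes x 1995 cells; covariates: ['intercept', 'log_reads', 'log_reads_sq', 'n_zero_genes']
null co-expression: fraction P<=0.05 = 0.0524
logCPM baseline:    fraction P<=0.05 = 0.7011
```

The data contain no co-expression at all, so the fraction of P ≤ 0.05
should be 0.05: the normalized pipeline is calibrated (0.0524), while the
log-CPM baseline declares 70% of null pairs significant — the library-size
confounding this package exists to remove.

A command-line interface mirrors the library (`scnormlm normalize / de /
coexpr / crispr / simulate / select-covariates`; `scnormlm --print-config`
lists every default).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main pipeline from scratch: it simulates null data, normalizes,
measures co-expression and null-DE calibration (stratified KS and type-I
error), evaluates logFC recovery against the simulator's ground truth in a
deeply sequenced regime, and compares naive vs competition-aware
false-positive rates on a synthetic CRISPR screen, logging each summary to
stderr and writing the results JSON to `--out`.
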