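"""Synthetic null scRNA-seq data with known ground truth.

The generator mimics a real UMI dataset's per-cell sequencing depths and
per-gene expression proportions while containing no co-expression at all:
each cell draws its depth n_j and each gene a base proportion p_i from the
(empirical or parametric) pools, per-gene-per-cell biological variation
b_ij ~ N(0, sigma^2) perturbs proportions multiplicatively, and reads are
multinomial within each cell. Because genes are independent given depth,
any co-expression detected on such data is a false positive, which makes
the datasets suitable for calibration checks and covariate selection. The
true log fold change between any two cell groups is known exactly from the
underlying proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix


@dataclass
class EmpiricalDistributions:
    """Sampling pools for the simulator.

    ``d_c``: multiset of per-cell total read counts; ``d_g``: per-gene total
    read proportions (sum to 1 over the source matrix's genes);
    ``source_n_genes``: gene count of the source, used to rescale depths
    when simulating a different number of genes.
    """

    d_c: np.ndarray
    d_g: np.ndarray
    source_n_genes: int

    def __post_init__(self):
        self.d_c = np.asarray(self.d_c)
        self.d_g = np.asarray(self.d_g, dtype=float)
        if (self.d_c <= 0).any():
            raise ValueError("per-cell totals must be positive")
        if not np.isclose(self.d_g.sum(), 1.0):
            raise ValueError("gene read proportions must sum to 1")


@dataclass
class SimulationConfig:
    """Simulator hyperparameters: output size, biological variation
    strength sigma (sd of ln-proportion perturbations), and RNG seed."""

    n_cells: int
    n_genes: int
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SyntheticDataset:
    """Simulated counts plus the ground truth that produced them."""

    counts: CountMatrix
    true_proportions: np.ndarray  # p~_ij = p_i * exp(b_ij), genes x cells
    base_proportions: np.ndarray  # p_i
    sampled_totals: np.ndarray  # n_j
    config: SimulationConfig


def fit_empirical(m: CountMatrix) -> EmpiricalDistributions:
    """Empirical depth and gene-proportion pools from a real count matrix."""
    totals = m.cell_totals
    grand = m.counts.sum()
    if grand == 0:
        raise ValueError("empty count matrix")
    return EmpiricalDistributions(
        d_c=totals[totals > 0], d_g=m.counts.sum(axis=1) / grand, source_n_genes=m.n_genes
    )


#: Parametric stand-in pool defaults: depths log-normal with median 2000
#: reads and sdlog 0.5; gene-proportion pool Zipf-like, p_r proportional to
#: 1/rank. Chosen to mimic a few-hundred-gene slice of a droplet dataset.
DEPTH_MEDIAN = 2000.0
DEPTH_SDLOG = 0.5
ZIPF_EXPONENT = 1.0


def parametric_distributions(
    n_genes: int = 500,
    depth_median: float = DEPTH_MEDIAN,
    depth_sdlog: float = DEPTH_SDLOG,
    zipf_exponent: float = ZIPF_EXPONENT,
    n_depth_draws: int = 10_000,
    seed: int = 0,
) -> EmpiricalDistributions:
    """Synthetic stand-in for the empirical pools when no real dataset is at
    hand: log-normal depths and a power-law gene-proportion pool."""
    rng = np.random.default_rng(seed)
    d_c = np.maximum(
        np.round(rng.lognormal(np.log(depth_median), depth_sdlog, size=n_depth_draws)), 1
    ).astype(np.int64)
    ranks = np.arange(1, n_genes + 1, dtype=float)
    d_g = ranks**-zipf_exponent
    d_g /= d_g.sum()
    return EmpiricalDistributions(d_c=d_c, d_g=d_g, source_n_genes=n_genes)


def simulate_null(d: EmpiricalDistributions, cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate a co-expression-free count matrix mimicking the pools in d.

    Steps: sample each cell's depth from d_c (rescaled by
    n_genes/source_n_genes, rounded, floored at 1); sample each gene's base
    proportion from d_g; draw biological variation b ~ N(0, sigma^2);
    multinomially distribute each cell's reads with weights p_i e^{b_ij}.
    """
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.n_genes / d.source_n_genes
    n_j = np.maximum(np.round(rng.choice(d.d_c, size=cfg.n_cells) * scale), 1).astype(np.int64)
    p_i = rng.choice(d.d_g, size=cfg.n_genes)
    b = rng.normal(0.0, cfg.sigma, size=(cfg.n_genes, cfg.n_cells))
    p_tilde = p_i[:, None] * np.exp(b)
    w = p_tilde / p_tilde.sum(axis=0)
    counts = np.empty((cfg.n_genes, cfg.n_cells), dtype=np.int64)
    for j in range(cfg.n_cells):
        counts[:, j] = rng.multinomial(n_j[j], w[:, j])
    width = len(str(max(cfg.n_genes, cfg.n_cells)))
    m = CountMatrix(
        counts,
        [f"g{i:0{width}d}" for i in range(cfg.n_genes)],
        [f"c{j:0{width}d}" for j in range(cfg.n_cells)],
    )
    return SyntheticDataset(
        counts=m,
        true_proportions=p_tilde,
        base_proportions=p_i,
        sampled_totals=n_j,
        config=cfg,
    )


def true_logfc(
    d: SyntheticDataset, membership: np.ndarray, cell_mask: np.ndarray | None = None
) -> np.ndarray:
    """Ground-truth natural-log fold change per gene between the two groups:
    difference of the group means of ln(p~_ij / sum_k p~_kj).

    ``cell_mask`` restricts to a cell subset (e.g. post-QC), with
    ``membership`` given over the retained cells.
    """
    p = d.true_proportions
    if cell_mask is not None:
        p = p[:, np.asarray(cell_mask, dtype=bool)]
    m = np.asarray(membership).astype(bool)
    if m.size != p.shape[1]:
        raise ValueError("membership length does not match cell count")
    if m.all() or not m.any():
        raise ValueError("both membership groups must be non-empty")
    lp = np.log(p / p.sum(axis=0))
    return lp[:, m].mean(axis=1) - lp[:, ~m].mean(axis=1)


def random_partitions(
    n_cells: int,
    n_rep: int = 100,
    rate_low: float = 0.05,
    rate_high: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Random binary cell partitions for null DE, one row per repetition.

    Each repetition draws a partition rate uniformly in [rate_low,
    rate_high] and assigns round(rate * n_cells) cells (at least 1) to the
    minor group without replacement.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_rep, n_cells), dtype=bool)
    for r in range(n_rep):
        rate = rng.uniform(rate_low, rate_high)
        k = max(1, int(round(rate * n_cells)))
        out[r, rng.choice(n_cells, size=k, replace=False)] = True
    return out


def expression_bins(m: CountMatrix, n_bins: int = 10) -> np.ndarray:
    """Split genes into equal-size bins by number of expressed cells
    (0 = lowest expression). Ties are broken by stable gene order."""
    n_expr = (m.counts > 0).sum(axis=1)
    order = np.argsort(n_expr, kind="stable")
    bins = np.empty(m.n_genes, dtype=np.int64)
    bins[order] = np.minimum(np.arange(m.n_genes) * n_bins // m.n_genes, n_bins - 1)
    return bins


def pair_bin_groups(bins: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Unordered bin-pair group id for gene pairs (10 bins -> 55 groups)."""
    n_bins = int(bins.max()) + 1
    lo = np.minimum(bins[ii], bins[jj])
    hi = np.maximum(bins[ii], bins[jj])
    return lo * n_bins + hi


def evaluate_logfc(
    estimates: np.ndarray, truth: np.ndarray, bins: np.ndarray
) -> pd.DataFrame:
    """Per-bin bias and variance of logFC estimation.

    Fits the intercept-free regression estimate = c * truth within each bin:
    ``coefficient`` (sum(est*truth)/sum(truth^2)) is the scale bias and
    ``r2`` the squared Pearson correlation (estimation variance).
    """
    est = np.asarray(estimates, float)
    tr = np.asarray(truth, float)
    bins = np.asarray(bins)
    if not est.shape == tr.shape == bins.shape:
        raise ValueError("estimates, truth and bins must have equal length")
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        t, e = tr[mask], est[mask]
        denom = (t**2).sum()
        if denom == 0:
            rows.append({"bin": int(b), "coefficient": np.nan, "r2": np.nan, "n": int(mask.sum())})
            continue
        coef = float((e * t).sum() / denom)
        r2 = float(np.corrcoef(e, t)[0, 1] ** 2) if mask.sum() > 1 else np.nan
        rows.append({"bin": int(b), "coefficient": coef, "r2": r2, "n": int(mask.sum())})
    return pd.DataFrame(rows).set_index("bin")


def evaluate_uniformity(p: np.ndarray, groups: np.ndarray, min_size: int = 5) -> pd.DataFrame:
    """Two-sided KS test against Uniform(0,1) within each group of P values.

    Groups are expression bins for DE or bin pairs for co-expression;
    groups smaller than ``min_size`` are skipped with a warning.
    """
    p = np.asarray(p, float)
    groups = np.asarray(groups)
    rows = []
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < min_size:
            warnings.warn(f"group {g} has fewer than {min_size} P values; skipped")
            continue
        res = stats.kstest(p[mask], "uniform")
        rows.append(
            {"group": g, "ks_statistic": float(res.statistic), "ks_p": float(res.pvalue), "n": int(mask.sum())}
        )
    cols = ["group", "ks_statistic", "ks_p", "n"]
    return pd.DataFrame(rows, columns=cols).set_index("group")


def simulate_crispr_screen(
    n_genes: int = 500,
    n_cells: int = 3000,
    n_grnas: int = 10,
    moi: int = 2,
    moi_low_fraction: float = 0.2,
    active_grna: int = 0,
    n_affected_genes: int = 100,
    effect_logfc: float = -0.5,
    sigma: float = 0.5,
    seed: int = 0,
    distributions: EmpiricalDistributions | None = None,
):
    """Synthetic screen with anti-correlated gRNA assignment (for method
    evaluation; not part of the core data model).

    Each cell receives ``moi`` distinct gRNAs drawn uniformly (``moi - 1``
    for a ``moi_low_fraction`` of cells), an underdispersed infection whose
    capacity constraint makes gRNA indicators mutually anti-correlated while
    avoiding the exact collinearity of a strictly fixed MOI, where the
    tested indicator would be fully determined by the untested ones. A
    single active gRNA multiplies the true proportions of the
    first ``n_affected_genes`` genes by exp(effect_logfc) in the cells
    carrying it; all other gRNAs are inert, so any association they show
    with the affected genes is a false positive.

    Returns (SyntheticDataset, assignment matrix bool (n_grnas, n_cells),
    affected gene index array).
    """
    from .crispr import GRNAAssignment  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    d = distributions or parametric_distributions(n_genes=n_genes)
    cfg = SimulationConfig(n_cells=n_cells, n_genes=n_genes, sigma=sigma, seed=int(rng.integers(2**31)))
    base = simulate_null(d, cfg)
    assign = np.zeros((n_grnas, n_cells), dtype=bool)
    low = rng.random(n_cells) < moi_low_fraction
    for j in range(n_cells):
        k = max(1, moi - 1) if low[j] else moi
        assign[rng.choice(n_grnas, size=k, replace=False), j] = True
    affected = np.arange(n_affected_genes)
    p_tilde = base.true_proportions.copy()
    carriers = assign[active_grna]
    p_tilde[np.ix_(affected, carriers)] *= np.exp(effect_logfc)
    w = p_tilde / p_tilde.sum(axis=0)
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for j in range(n_cells):
        counts[:, j] = rng.multinomial(base.sampled_totals[j], w[:, j])
    m = CountMatrix(counts, base.counts.gene_ids, base.counts.cell_ids)
    ds = SyntheticDataset(
        counts=m,
        true_proportions=p_tilde,
        base_proportions=base.base_proportions,
        sampled_totals=base.sampled_totals,
        config=cfg,
    )
    grna_ids = [f"grna{k}" for k in range(n_grnas)]
    meta = pd.DataFrame(
        {
            "class": ["TSS-targeting" if k == active_grna else "NTC" for k in range(n_grnas)],
            "target_gene": [m.gene_ids[0] if k == active_grna else None for k in range(n_grnas)],
            "target_chrom": [None] * n_grnas,
            "target_position": [None] * n_grnas,
        },
        index=pd.Index(grna_ids, name="grna_id"),
    )
    return ds, GRNAAssignment(assign, grna_ids, meta), affected
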