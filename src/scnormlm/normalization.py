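"""Bayesian log expression and variance normalization.

The measurement model treats sequencing as binomial sampling of each gene's
mRNA proportion within a cell's transcript pool. With a uniform prior on the
proportion p, observing g UMIs of a gene in a cell with n total UMIs gives
the posterior p | g ~ Beta(1 + g, 1 + n - g), and the minimum-MSE point
estimate of ln p is its posterior mean

    y = E[ln p | g, n] = psi(1 + g) - psi(2 + n),

with psi the digamma function (natural log throughout). Downstream, per-cell
technical confounding is removed by regressing on cellular summary
covariates (log depth, its square, number of zero-count genes) at the mean
level, and a shared per-cell error-variance model rescales residuals so that
hypothesis tests on the normalized values are calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import digamma

from .io import CountMatrix, CovariateTable

#: Tolerance below which a candidate covariate row is considered collinear
#: with the rows already orthonormalized and is dropped.
COLLINEARITY_TOL = 1e-10


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate row: a monomial in the summary bases, a categorical
    indicator, or the intercept.

    ``order`` is the exponent vector over the base covariates
    (b1 = log total reads, b2 = number of zero-count genes); the intercept
    has an all-zero order vector and categorical indicators have none.
    """

    label: str
    order: tuple[int, ...] | None = None
    is_categorical: bool = False
    is_intercept: bool = False

    def __post_init__(self):
        if self.is_intercept and self.order is not None and any(self.order):
            raise ValueError("intercept term must have an all-zero order vector")
        if self.is_categorical and self.order is not None:
            raise ValueError("categorical terms carry no order vector")


def intercept_term() -> CovariateTerm:
    return CovariateTerm("intercept", order=(0, 0), is_intercept=True)


def default_summary_terms() -> list[CovariateTerm]:
    """The shipped covariate set: intercept, log depth, its square, and the
    zero-gene count (the set recovered by forward selection on null data)."""
    return [
        intercept_term(),
        CovariateTerm("log_reads", order=(1, 0)),
        CovariateTerm("log_reads_sq", order=(2, 0)),
        CovariateTerm("n_zero_genes", order=(0, 1)),
    ]


@dataclass
class CovariateSet:
    """A covariates x cells design with per-row term metadata.

    After :func:`aggregate_covariates` the non-intercept rows are centered,
    mutually orthogonal with unit norm; the intercept row stays all-ones.
    One-hot categorical rows take part in the orthonormalization like any
    continuous row but their original 0/1 copies are retained
    (``raw_categorical``) so the variance-scaling step can exempt them.
    """

    values: np.ndarray  # (n_terms, n_cells)
    terms: list[CovariateTerm]
    orthonormalized: bool = False
    raw_categorical: np.ndarray | None = None
    raw_categorical_terms: list[CovariateTerm] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.terms):
            raise ValueError("row count does not match term count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def with_rows(self, rows: np.ndarray, terms: list[CovariateTerm]) -> "CovariateSet":
        """Return a copy with extra rows appended (used at test time)."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return replace(
            self,
            values=np.vstack([self.values, rows]),
            terms=self.terms + list(terms),
            orthonormalized=False,
        )


def bayesian_log_expression(m: CountMatrix) -> np.ndarray:
    """Posterior-mean log expression proportion, psi(1+g) - psi(2+n).

    Defined for every non-negative count; every entry is strictly negative
    because it estimates the log of a proportion.
    """
    g = m.counts
    n = m.cell_totals
    return digamma(1.0 + g) - digamma(2.0 + n)[None, :]


def summary_base_covariates(m: CountMatrix) -> np.ndarray:
    """The two cellular summary bases, one row each: b1 = ln(total reads),
    b2 = number of zero-count genes per cell."""
    totals = m.cell_totals
    if (totals == 0).any():
        raise ValueError("cell with zero total reads; apply QC first")
    b1 = np.log(totals.astype(float))
    b2 = (m.counts == 0).sum(axis=0).astype(float)
    return np.vstack([b1, b2])


def summary_covariates(m: CountMatrix, terms: list[CovariateTerm] | None = None) -> CovariateSet:
    """Evaluate monomial summary-covariate terms cell-wise.

    Each non-intercept row is prod_k b_k^{p_k} for that term's exponent
    vector p over the bases (b1, b2).
    """
    terms = list(terms) if terms is not None else default_summary_terms()
    bases = summary_base_covariates(m)
    rows = []
    for t in terms:
        if t.is_intercept:
            rows.append(np.ones(m.n_cells))
            continue
        if t.order is None:
            raise ValueError(f"term {t.label!r} has no order vector")
        p = np.asarray(t.order)
        if len(p) != bases.shape[0]:
            raise ValueError(f"term {t.label!r}: order vector length {len(p)} != {bases.shape[0]} bases")
        rows.append(np.prod(bases ** p[:, None], axis=0))
    return CovariateSet(np.vstack(rows), terms)


def _one_hot(col, label: str) -> tuple[np.ndarray, list[CovariateTerm]]:
    levels = sorted(map(str, set(col)))
    arr = np.asarray([str(v) for v in col])
    rows = np.stack([(arr == lv).astype(float) for lv in levels])
    terms = [CovariateTerm(f"{label}={lv}", is_categorical=True) for lv in levels]
    return rows, terms


def orthonormalize_rows(cov: CovariateSet, tol: float = COLLINEARITY_TOL) -> CovariateSet:
    """Center non-intercept rows, then stable Gram-Schmidt with collinearity
    dropping; the intercept stays as literal all-ones and is excluded."""
    n = cov.n_cells
    out_rows: list[np.ndarray] = []
    out_terms: list[CovariateTerm] = []
    basis: list[np.ndarray] = []
    seen_intercept = False
    for row, term in zip(cov.values, cov.terms):
        if term.is_intercept:
            if seen_intercept:
                warnings.warn("duplicate intercept dropped")
                continue
            seen_intercept = True
            out_rows.append(np.ones(n))
            out_terms.append(term)
            continue
        v = row - row.mean()
        scale = np.linalg.norm(v)
        if scale <= tol * max(1.0, np.linalg.norm(row)):
            warnings.warn(f"covariate {term.label!r} is constant; dropped")
            continue
        v = v / scale
        for b in basis:  # twice for numerical stability
            v -= (v @ b) * b
        for b in basis:
            v -= (v @ b) * b
        nrm = np.linalg.norm(v)
        if nrm <= tol:
            warnings.warn(f"covariate {term.label!r} is collinear with earlier rows; dropped")
            continue
        v /= nrm
        basis.append(v)
        out_rows.append(v)
        out_terms.append(term)
    return replace(cov, values=np.vstack(out_rows), terms=out_terms, orthonormalized=True)


def aggregate_covariates(
    existing: CovariateTable | None, summary: CovariateSet
) -> CovariateSet:
    """Concatenate user covariates with the summary covariates and
    orthonormalize (excluding the single intercept).

    Categorical columns are one-hot encoded with all levels kept; exact
    collinearity (e.g. the redundant level against the intercept) is removed
    by the rank-revealing orthonormalization. Original one-hot copies are
    stored for the variance-scaling exemption at normalization time.
    """
    rows: list[np.ndarray] = [np.ones(summary.n_cells)]
    terms: list[CovariateTerm] = [intercept_term()]
    raw_cat_rows: list[np.ndarray] = []
    raw_cat_terms: list[CovariateTerm] = []
    if existing is not None:
        if existing.values.shape[0] != summary.n_cells:
            raise ValueError("covariate table and count matrix disagree on cell count")
        for col in existing.values.columns:
            if existing.kinds.get(col) == "categorical":
                r, t = _one_hot(existing.values[col].to_numpy(), col)
                rows.extend(r)
                terms.extend(t)
                raw_cat_rows.extend(r)
                raw_cat_terms.extend(t)
            else:
                rows.append(existing.values[col].to_numpy(dtype=float))
                terms.append(CovariateTerm(col))
    for row, t in zip(summary.values, summary.terms):
        if t.is_intercept:
            continue
        rows.append(row)
        terms.append(t)
    if len(rows) >= summary.n_cells:
        raise ValueError("more covariates than cells")
    cov = CovariateSet(np.vstack(rows), terms)
    cov = orthonormalize_rows(cov)
    if raw_cat_rows:
        cov.raw_categorical = np.vstack(raw_cat_rows)
        cov.raw_categorical_terms = raw_cat_terms
    return cov


@dataclass
class CellVarianceModel:
    """Mean-level covariate effects and the shared per-cell variance model.

    ``v`` is each cell's combined error variance (squared mean-model
    residuals summed over genes); ``v_hat`` its log-linear fit
    exp(alpha_v . C) which is strictly positive.
    """

    alpha_y: np.ndarray  # (n_genes, n_cov)
    v: np.ndarray  # (n_cells,)
    alpha_v: np.ndarray  # (n_cov,)
    v_hat: np.ndarray  # (n_cells,)


def _lstsq_coef(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of Y (targets x cells) on rows of C."""
    coef, *_ = np.linalg.lstsq(C.T, np.atleast_2d(Y).T, rcond=None)
    return coef.T


def estimate_cell_variance(Y: np.ndarray, C: CovariateSet) -> CellVarianceModel:
    """Fit mean effects gene-wise, pool squared residuals per cell, and model
    their log by the same covariates.

    A single variance model shared by all genes (rather than one per gene)
    keeps the number of nuisance parameters small; zero pooled variances are
    clamped to the smallest positive value before taking logs.
    """
    Cv = C.values
    alpha_y = _lstsq_coef(Y, Cv)
    resid = Y - alpha_y @ Cv
    v = (resid**2).sum(axis=0)
    if (v <= 0).all():
        raise ValueError("degenerate variance: expression perfectly explained by covariates")
    if (v <= 0).any():
        clamp = v[v > 0].min()
        warnings.warn(f"{int((v <= 0).sum())} cell(s) with zero error variance clamped to {clamp:.3g}")
        v = np.where(v > 0, v, clamp)
    alpha_v = _lstsq_coef(np.log(v), Cv)[0]
    v_hat = np.exp(alpha_v @ Cv)
    return CellVarianceModel(alpha_y=alpha_y, v=v, alpha_v=alpha_v, v_hat=v_hat)


@dataclass
class NormalizedExpression:
    """Variance-normalized expression with the test-ready covariate design.

    ``gamma`` in [0, 1] scales the variance-normalization exponent per gene
    from 0 (no zero-count cells; measured accurately, left untouched) to 1
    (the most zero-inflated gene, fully rescaled).
    """

    y_tilde: np.ndarray  # (n_genes, n_cells)
    gamma: np.ndarray  # (n_genes,)
    covariates_tilde: CovariateSet
    gene_ids: list[str]
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.y_tilde.shape[1]


def normalize(
    Y: np.ndarray, C: CovariateSet, model: CellVarianceModel, m: CountMatrix
) -> NormalizedExpression:
    """Rescale per-cell residual variance and build test covariates.

    y~_ij = y^_ij + (y_ij - y^_ij) / v^_j^{gamma_i/2}, with the fitted cell
    variances first rescaled to unit geometric mean so that the per-gene
    overall scale (hence logFC estimates) is preserved; P values are
    invariant to that per-gene constant. Continuous covariate rows are
    divided cell-wise by the fitted variance; one-hot categorical rows are
    restored to their raw 0/1 encoding, the intercept is untouched.
    """
    fitted = model.alpha_y @ C.values
    v_rel = model.v_hat / np.exp(np.mean(np.log(model.v_hat)))
    gtil = m.zeros_per_gene.astype(float)
    gmax = gtil.max()
    gamma = gtil / gmax if gmax > 0 else np.zeros_like(gtil)
    scale = v_rel[None, :] ** (-gamma[:, None] / 2.0)
    y_tilde = fitted + (Y - fitted) * scale

    rows = []
    terms = []
    for row, t in zip(C.values, C.terms):
        if t.is_intercept:
            rows.append(row)
        elif t.is_categorical:
            continue  # re-inserted from the raw one-hot copy below
        else:
            rows.append(row / v_rel)
        terms.append(t)
    terms = [t for t in terms if not t.is_categorical]
    if C.raw_categorical is not None:
        rows.extend(C.raw_categorical)
        terms.extend(C.raw_categorical_terms)
    cov_tilde = CovariateSet(np.vstack(rows), terms)
    return NormalizedExpression(
        y_tilde=y_tilde,
        gamma=gamma,
        covariates_tilde=cov_tilde,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
    )


@dataclass
class OutlierConfig:
    """Iterative low/high-variance outlier-cell detection parameters."""

    prior_outlier_bound: float = 0.02
    bonferroni_p_threshold: float = 1e-10
    max_iterations: int = 100

    def __post_init__(self):
        if not 0 < self.prior_outlier_bound < 0.5:
            raise ValueError("prior_outlier_bound must be in (0, 0.5)")


def remove_outliers(model: CellVarianceModel, cfg: OutlierConfig | None = None) -> np.ndarray:
    """Flag outlier cells from the inverse fitted variance; returns a keep mask.

    A normal distribution is fit by maximum likelihood on the inverse
    variances of current non-outliers (initially the cells between the r and
    1-r percentiles), all cells get two-sided P values, and cells whose
    Bonferroni-adjusted P falls at or below the threshold become outliers for
    the next round, until the set stabilizes.
    """
    from scipy import stats

    cfg = cfg or OutlierConfig()
    x = 1.0 / model.v_hat
    n = x.size
    if cfg.bonferroni_p_threshold <= 0:
        return np.ones(n, bool)  # nothing can fall below an impossible cutoff
    lo, hi = np.percentile(x, [100 * cfg.prior_outlier_bound, 100 * (1 - cfg.prior_outlier_bound)])
    keep = (x >= lo) & (x <= hi)
    for _ in range(cfg.max_iterations):
        if keep.sum() < 3:
            raise ValueError("fewer than 3 non-outlier cells")
        mu, sd = x[keep].mean(), x[keep].std()
        if sd == 0:
            keep = np.ones(n, bool)  # all identical: nothing can be an outlier
            break
        p = 2 * stats.norm.sf(np.abs(x - mu) / sd)
        new_keep = np.minimum(p * n, 1.0) > cfg.bonferroni_p_threshold
        if (new_keep == keep).all():
            keep = new_keep
            break
        keep = new_keep
    frac = 1 - keep.mean()
    if frac > cfg.prior_outlier_bound:
        warnings.warn(
            f"outlier fraction {frac:.3f} exceeds prior bound {cfg.prior_outlier_bound}"
        )
    return keep


def normalize_counts(
    m: CountMatrix,
    existing: CovariateTable | None = None,
    terms: list[CovariateTerm] | None = None,
    outlier_cfg: OutlierConfig | None = None,
    remove_outlier_cells: bool = False,
) -> NormalizedExpression:
    """Full normalization pipeline on a QC'd count matrix.

    Computes Bayesian log expression, builds/aggregates covariates, fits the
    cell-variance model, optionally drops outlier cells (refitting on the
    kept cells), and returns variance-normalized expression with the scaled
    covariate design ready for association testing.
    """
    Y = bayesian_log_expression(m)
    C = aggregate_covariates(existing, summary_covariates(m, terms))
    model = estimate_cell_variance(Y, C)
    if remove_outlier_cells:
        keep = remove_outliers(model, outlier_cfg)
        if not keep.all():
            m = m.subset(cell_mask=keep)
            if existing is not None:
                existing = CovariateTable(existing.values.loc[np.asarray(m.cell_ids)], existing.kinds)
            return normalize_counts(m, existing, terms, outlier_cfg, remove_outlier_cells=False)
    return normalize(Y, C, model, m)
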