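"""Exact linear-model association tests and multiple-testing utilities.

Differential expression fits y~ = alpha*s + beta*C~ + eps for a binary cell
membership s; co-expression fits the same model with another gene's
normalized expression as predictor. Under the null the proportion of
residual variance explained by the predictor follows
Beta(1/2, (n_c - 1 - rank(C~))/2) exactly for normal errors, which yields
permutation-free two-sided P values. The reported coefficient is the logFC
(natural log) for DE and the conditional Pearson correlation for
co-expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizedExpression, CovariateSet

RANK_TOL = 1e-10


def beta_pvalue(r_squared, n_cells: int, cov_rank: int):
    """Upper tail of Beta(1/2, (n_cells - 1 - cov_rank)/2) at r_squared."""
    df = n_cells - 1 - cov_rank
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom: n={n_cells}, rank={cov_rank}")
    r2 = np.clip(np.asarray(r_squared, dtype=float), 0.0, 1.0)
    return stats.beta.sf(r2, 0.5, df / 2.0)


def _design_rank(C: np.ndarray) -> int:
    s = np.linalg.svd(C, compute_uv=False)
    return int((s > RANK_TOL * s[0]).sum()) if s.size else 0


def residualize(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the rows of X after least-squares fit on the rows of C."""
    X2 = np.atleast_2d(X)
    coef, *_ = np.linalg.lstsq(C.T, X2.T, rcond=None)
    return X2 - coef.T @ C


def _cov_arrays(expr: NormalizedExpression | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(expr, NormalizedExpression):
        return expr.y_tilde, expr.covariates_tilde.values
    Y, C = expr
    if isinstance(C, CovariateSet):
        C = C.values
    return np.asarray(Y, float), np.atleast_2d(np.asarray(C, float))


def test_de(
    expr: NormalizedExpression | tuple,
    membership: np.ndarray,
    gene_subset: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Differential expression of every gene against a binary membership.

    Returns a frame indexed by gene with columns ``logfc`` (alpha-hat), ``r``
    (signed conditional correlation), ``r2``, and ``p``.
    """
    Y, C = _cov_arrays(expr)
    gene_ids = expr.gene_ids if isinstance(expr, NormalizedExpression) else list(range(Y.shape[0]))
    if gene_subset is not None:
        idx = [gene_ids.index(g) if isinstance(g, str) else int(g) for g in gene_subset]
        Y = Y[idx]
        gene_ids = [gene_ids[i] for i in idx]
    s = np.asarray(membership, float)
    if s.ndim != 1 or s.size != Y.shape[1]:
        raise ValueError("membership must be one value per cell")
    if len(np.unique(s)) < 2:
        raise ValueError("both membership groups must be non-empty")
    n = Y.shape[1]
    rank = _design_rank(C)
    rs = residualize(s, C)[0]
    s_norm2 = rs @ rs
    if s_norm2 <= RANK_TOL * n:
        raise ValueError("membership is collinear with the covariates")
    ry = residualize(Y, C)
    alpha = (ry @ rs) / s_norm2
    y_norm2 = (ry**2).sum(axis=1)
    zero_var = y_norm2 <= (RANK_TOL * np.abs(Y).max(axis=1).clip(min=1.0)) ** 2 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ry @ rs) / np.sqrt(y_norm2 * s_norm2)
    r = np.where(zero_var, 0.0, r)
    r2 = r**2
    p = beta_pvalue(r2, n, rank)
    p = np.where(zero_var, 1.0, p)
    return pd.DataFrame(
        {"logfc": alpha, "r": r, "r2": r2, "p": p, "zero_variance": zero_var},
        index=pd.Index(gene_ids, name="gene"),
    )


def coexpression_matrices(expr: NormalizedExpression | tuple) -> tuple[np.ndarray, np.ndarray]:
    """All-vs-all conditional correlation and P matrices.

    R[i, j] is the Pearson correlation of genes i and j after removing the
    covariates from both; P from the exact beta null. Symmetric by
    construction; the diagonal is (1, 0).
    """
    Y, C = _cov_arrays(expr)
    n = Y.shape[1]
    rank = _design_rank(C)
    ry = residualize(Y, C)
    norms = np.sqrt((ry**2).sum(axis=1))
    zero = norms <= RANK_TOL * np.abs(Y).max(axis=1).clip(min=1.0) * np.sqrt(n)
    safe = np.where(zero, 1.0, norms)
    Z = ry / safe[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    P = beta_pvalue(R**2, n, rank)
    P[zero, :] = 1.0
    P[:, zero] = 1.0
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    return R, P


def test_coexpression(
    expr: NormalizedExpression | tuple, pairs: np.ndarray | list | None = None
) -> pd.DataFrame:
    """Conditional co-expression tests for gene pairs (all pairs if None).

    The statistic is symmetric in the pair; zero-residual-variance genes are
    flagged and reported with R = 0, P = 1.
    """
    Y, C = _cov_arrays(expr)
    gene_ids = expr.gene_ids if isinstance(expr, NormalizedExpression) else list(range(Y.shape[0]))
    name_to_idx = {g: i for i, g in enumerate(gene_ids)}
    n = Y.shape[1]
    rank = _design_rank(C)
    ry = residualize(Y, C)
    norms = np.sqrt((ry**2).sum(axis=1))
    zero = norms <= RANK_TOL * np.abs(Y).max(axis=1).clip(min=1.0) * np.sqrt(n)
    Z = ry / np.where(zero, 1.0, norms)[:, None]
    if pairs is None:
        ii, jj = np.triu_indices(Y.shape[0], k=1)
    else:
        pr = [
            (name_to_idx[a] if isinstance(a, str) else int(a), name_to_idx[b] if isinstance(b, str) else int(b))
            for a, b in pairs
        ]
        ii = np.asarray([p[0] for p in pr])
        jj = np.asarray([p[1] for p in pr])
    # chunked to bound memory at large pair counts
    r = np.empty(ii.size)
    step = max(1, int(2**25 // max(n, 1)))
    for k in range(0, ii.size, step):
        sl = slice(k, k + step)
        r[sl] = np.einsum("ij,ij->i", Z[ii[sl]], Z[jj[sl]])
    r = np.clip(r, -1.0, 1.0)
    flagged = zero[ii] | zero[jj]
    same = ii == jj
    r = np.where(flagged, 0.0, r)
    r = np.where(same & ~flagged, 1.0, r)
    p = beta_pvalue(r**2, n, rank)
    p = np.where(flagged, 1.0, p)
    p = np.where(same & ~flagged, 0.0, p)
    return pd.DataFrame(
        {
            "gene_i": [gene_ids[i] for i in ii],
            "gene_j": [gene_ids[j] for j in jj],
            "r": r,
            "r2": r**2,
            "p": p,
            "zero_variance": flagged,
        }
    )


def bh_qvalues(p: np.ndarray, groups: np.ndarray | list | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values, computed within each group."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    q = np.empty_like(p)
    if groups is None:
        groups = np.zeros(p.size)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        mask = groups == g
        q[mask] = _bh(p[mask])
    return q


def _bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def storey_pi1(p: np.ndarray, lam: float = 0.5) -> float:
    """Estimated non-null fraction: 1 - #{p > lam} / ((1 - lam) n), in [0, 1].

    Used as an empirical false-positive-rate estimate on pair types where
    the null is expected to hold.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty P value vector")
    pi0 = (p > lam).sum() / ((1.0 - lam) * p.size)
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


def fisher_combine(p: np.ndarray) -> float:
    """Fisher's combined probability: chi2 upper tail of -2 sum ln p, 2k df."""
    p = np.asarray(p, dtype=float)
    if (p == 0).any():
        warnings.warn("zero P value in Fisher combination; returning 0")
        return 0.0
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * p.size))
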