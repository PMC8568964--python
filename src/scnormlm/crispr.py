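"""High-MOI single-cell CRISPR screen analysis.

Cells in high-MOI screens carry many gRNAs drawn from a fixed infection
pool, so gRNA presence indicators are mutually anti-correlated; testing one
gRNA without accounting for the others converts true effects of one guide
into false associations of its competitors. The competition-aware design
counters this by including every untested gRNA's indicator as a mean-level
covariate (compressed to principal components for very large libraries).
Downstream logic classifies gRNA-gene pair types, estimates CRISPRi
off-target rates by comparing the weaker against the stronger guide per
target, and distils trans-associations into regulator->target edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import test_de, bh_qvalues
from .normalization import CovariateSet, CovariateTerm, NormalizedExpression

#: Covariate count above which the gRNA indicator block is compressed.
PC_REDUCTION_THRESHOLD = 10_000
#: Number of principal components kept when compressing.
N_GRNA_PCS = 500


@dataclass
class GRNAAssignment:
    """Binary gRNA x cell assignment plus per-gRNA metadata.

    ``meta`` is indexed by gRNA id with columns ``class`` (one of
    ``TSS-targeting``, ``NTC``, ``enhancer-candidate``), ``target_gene``,
    ``target_chrom``, ``target_position``.
    """

    matrix: np.ndarray
    grna_ids: list[str]
    meta: pd.DataFrame

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix).astype(bool)
        if self.matrix.shape[0] != len(self.grna_ids):
            raise ValueError("assignment rows must match gRNA ids")
        self.meta = self.meta.loc[list(self.grna_ids)]
        tss = self.meta["class"] == "TSS-targeting"
        if tss.any() and self.meta.loc[tss, "target_gene"].isna().any():
            raise ValueError("TSS-targeting gRNAs must declare a target gene")
        ntc = self.meta["class"] == "NTC"
        if ntc.any() and self.meta.loc[ntc, "target_gene"].notna().any():
            raise ValueError("NTC gRNAs must not declare a target gene")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


def read_grna_assignment(matrix_path, meta_path) -> GRNAAssignment:
    """Read assignment (MTX/TSV via io.read_counts conventions, entries 0/1)
    and gRNA metadata TSV (grna_id, class, target_gene, chrom, position)."""
    from .io import read_counts

    m = read_counts(matrix_path)
    if not np.isin(m.counts, (0, 1)).all():
        raise ValueError("gRNA assignment entries must be 0/1")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.columns = ["class", "target_gene", "target_chrom", "target_position"] + list(meta.columns[4:])
    return GRNAAssignment(m.counts.astype(bool), m.gene_ids, meta)


def grna_cross_association(a: GRNAAssignment) -> pd.DataFrame:
    """Pairwise gRNA co-occurrence: odds ratio and one-sided (depletion)
    hypergeometric P for each unordered gRNA pair.

    The P value is the lower tail P(X <= n11) for the number of shared cells
    under random assignment with fixed margins; pairs with a zero table
    margin get a missing odds ratio.
    """
    X = a.matrix.astype(np.int64)
    n = a.n_cells
    inter = X @ X.T
    tot = X.sum(axis=1)
    rows = []
    for i in range(len(a.grna_ids)):
        for j in range(i + 1, len(a.grna_ids)):
            n11 = int(inter[i, j])
            n10 = int(tot[i] - n11)
            n01 = int(tot[j] - n11)
            n00 = n - n11 - n10 - n01
            if min(tot[i], tot[j], n - tot[i], n - tot[j]) == 0:
                oratio = np.nan
            elif n10 == 0 or n01 == 0:
                oratio = np.inf
            else:
                oratio = n11 * n00 / (n10 * n01)
            p = float(stats.hypergeom.cdf(n11, n, int(tot[i]), int(tot[j])))
            rows.append(
                {"grna_i": a.grna_ids[i], "grna_j": a.grna_ids[j], "odds_ratio": oratio, "p": p}
            )
    return pd.DataFrame(rows)


def grna_pc_block(a: GRNAAssignment, n_pcs: int = N_GRNA_PCS) -> np.ndarray:
    """Top principal axes (rows over cells) of the centered gRNA indicator
    block, computed once per screen. Sign fixed deterministically."""
    X = a.matrix.astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, int((s > 1e-12 * s[0]).sum()))
    pcs = vt[:k]
    signs = np.sign(pcs[np.arange(k), np.abs(pcs).argmax(axis=1)])
    return pcs * signs[:, None]


def competition_aware_design(
    a: GRNAAssignment,
    tested: str,
    base_cov: CovariateSet,
    pc_block: np.ndarray | None = None,
    max_covariates: int = PC_REDUCTION_THRESHOLD,
    n_pcs: int = N_GRNA_PCS,
) -> CovariateSet:
    """Covariate design for testing one gRNA with all others as covariates.

    The untested gRNAs' indicators are appended to the base covariates as
    mean-only rows. If the total covariate count would exceed
    ``max_covariates`` the indicator block is replaced by its top ``n_pcs``
    principal components (pass ``pc_block`` to reuse the once-per-screen
    SVD); the tested gRNA's own indicator is projected out of the PC rows so
    its signal cannot leak into the covariates.
    """
    if tested not in a.grna_ids:
        raise KeyError(f"unknown gRNA {tested!r}")
    t = a.grna_ids.index(tested)
    others = [k for k in range(len(a.grna_ids)) if k != t]
    if base_cov.n_terms + len(others) > max_covariates:
        pcs = pc_block if pc_block is not None else grna_pc_block(a, n_pcs)
        s = a.matrix[t].astype(float)
        sc = s - s.mean()
        denom = sc @ sc
        rows = pcs - np.outer((pcs @ sc) / denom, sc) if denom > 0 else pcs
        terms = [CovariateTerm(f"grna_pc{i}") for i in range(rows.shape[0])]
    else:
        rows = a.matrix[others].astype(float)
        terms = [CovariateTerm(f"grna:{a.grna_ids[k]}") for k in others]
    return base_cov.with_rows(rows, terms)


def test_grna(
    expr: NormalizedExpression,
    a: GRNAAssignment,
    tested: str,
    competition_aware: bool = True,
    pc_block: np.ndarray | None = None,
    gene_subset=None,
) -> pd.DataFrame:
    """DE of every gene against one gRNA's presence, naive or aware."""
    cov = expr.covariates_tilde
    if competition_aware:
        cov = competition_aware_design(a, tested, cov, pc_block=pc_block)
    s = a.matrix[a.grna_ids.index(tested)].astype(float)
    res = test_de((expr.y_tilde, cov), s)
    res.index = pd.Index(expr.gene_ids, name="gene")
    res.insert(0, "grna", tested)
    return res


PAIR_LABELS = (
    "naive_target",
    "naive_other",
    "aware_target",
    "aware_other",
    "tss_target",
    "tss_other",
    "ntc",
    "enhancer",
)


def classify_pairs(
    a: GRNAAssignment,
    genes: pd.DataFrame | list,
    mode: str = "aware",
    collapse_ntc: bool = False,
) -> pd.DataFrame:
    """Label every (gRNA, gene) pair by its role in screen evaluation.

    TSS-targeting gRNAs give ``tss_target`` against their own target and
    ``tss_other`` elsewhere; enhancer-candidate gRNAs give ``enhancer``; NTC
    gRNAs give ``{mode}_target`` against genes TSS-targeted by any library
    gRNA and ``{mode}_other`` otherwise (``ntc`` for all NTC pairs when
    ``collapse_ntc``). Every pair receives exactly one label.
    """
    if mode not in ("naive", "aware"):
        raise ValueError("mode must be 'naive' or 'aware'")
    gene_ids = list(genes.index) if isinstance(genes, pd.DataFrame) else list(genes)
    targeted = set(a.meta.loc[a.meta["class"] == "TSS-targeting", "target_gene"].dropna())
    missing = targeted - set(gene_ids)
    if missing:
        warnings.warn(f"target gene(s) missing from annotation: {sorted(missing)[:3]}")
    rows = []
    for gid in a.grna_ids:
        cls = a.meta.loc[gid, "class"]
        tgt = a.meta.loc[gid, "target_gene"]
        for gene in gene_ids:
            if cls == "TSS-targeting":
                label = "tss_target" if gene == tgt else "tss_other"
            elif cls == "enhancer-candidate":
                label = "enhancer"
            elif collapse_ntc:
                label = "ntc"
            else:
                label = f"{mode}_target" if gene in targeted else f"{mode}_other"
            rows.append((gid, gene, label))
    return pd.DataFrame(rows, columns=["grna", "gene", "pair_type"])


def grouped_qvalues(results: pd.DataFrame, pair_types: pd.DataFrame) -> pd.DataFrame:
    """Attach BH Q values with screen-specific grouping: all ``tss_target``
    pairs form one group; every other pair type is grouped per gRNA."""
    df = results.reset_index().merge(pair_types, on=["grna", "gene"], how="left")
    group = np.where(
        df["pair_type"] == "tss_target", "tss_target", df["grna"] + "|" + df["pair_type"].fillna("?")
    )
    df["q"] = bh_qvalues(df["p"].to_numpy(), group)
    df["q_group"] = group
    return df


def _is_trans(ann: pd.DataFrame, gene: str, chrom, pos, max_cis_bp: float = 1e6) -> bool:
    if gene not in ann.index:
        return False
    row = ann.loc[gene]
    if chrom is None or row["chromosome"] != chrom:
        return True
    return abs(int(row["tss"]) - int(pos)) > max_cis_bp


def rank_grnas_per_target(results: pd.DataFrame, a: GRNAAssignment) -> pd.DataFrame:
    """Per targeted gene, identify the weaker and stronger gRNA by the P of
    their association with the gene they target (ties by |logFC|, then id)."""
    rows = []
    tssmeta = a.meta[a.meta["class"] == "TSS-targeting"]
    for tgt, sub in tssmeta.groupby("target_gene"):
        if len(sub) < 2:
            continue
        recs = []
        for gid in sub.index:
            hit = results[(results["grna"] == gid) & (results["gene"] == tgt)]
            if hit.empty:
                continue
            recs.append((float(hit["p"].iloc[0]), -abs(float(hit["logfc"].iloc[0])), gid))
        if len(recs) < 2:
            continue
        recs.sort()  # strongest (smallest P) first
        rows.append({"target_gene": tgt, "stronger": recs[0][2], "weaker": recs[-1][2]})
    return pd.DataFrame(rows)


def offtarget_rate(
    results: pd.DataFrame,
    grna_pairs: pd.DataFrame,
    genes: pd.DataFrame,
    a: GRNAAssignment,
    q_thresh: float = 0.05,
    insignif_p: float = 0.1,
    max_cis_bp: float = 1e6,
) -> tuple[pd.DataFrame, float]:
    """CRISPRi off-target rate from weaker/stronger gRNA agreement.

    For each weaker gRNA, its significant (Q <= q_thresh) trans-genes that
    the stronger gRNA leaves clearly untouched (P >= insignif_p) count as
    off-targets. The raw rate is off-targets over significant trans-targets,
    the estimated rate min(raw/(1 - insignif_p), 1), and the overall rate
    the mean estimate over weaker gRNAs with at least one significant
    trans-target.

    ``results`` needs columns grna, gene, p, q, logfc; ``grna_pairs`` the
    frame from :func:`rank_grnas_per_target`.
    """
    per = []
    for _, pr in grna_pairs.iterrows():
        weak, strong, tgt = pr["weaker"], pr["stronger"], pr["target_gene"]
        chrom = a.meta.loc[weak, "target_chrom"]
        pos = a.meta.loc[weak, "target_position"]
        if pd.isna(chrom) and tgt in genes.index:
            chrom, pos = genes.loc[tgt, "chromosome"], genes.loc[tgt, "tss"]
        wk = results[results["grna"] == weak].set_index("gene")
        st = results[results["grna"] == strong].set_index("gene")
        trans = [g for g in wk.index if _is_trans(genes, g, chrom, pos, max_cis_bp)]
        sig = [g for g in trans if wk.loc[g, "q"] <= q_thresh]
        off = [g for g in sig if g in st.index and st.loc[g, "p"] >= insignif_p]
        if not sig:
            per.append(
                {"target_gene": tgt, "weaker": weak, "n_significant_trans": 0, "n_offtarget": 0,
                 "raw_rate": np.nan, "estimated_rate": np.nan}
            )
            continue
        raw = len(off) / len(sig)
        per.append(
            {
                "target_gene": tgt,
                "weaker": weak,
                "n_significant_trans": len(sig),
                "n_offtarget": len(off),
                "raw_rate": raw,
                "estimated_rate": min(raw / (1.0 - insignif_p), 1.0),
            }
        )
    cols = ["target_gene", "weaker", "n_significant_trans", "n_offtarget", "raw_rate", "estimated_rate"]
    per_df = pd.DataFrame(per, columns=cols)
    valid = per_df["estimated_rate"].dropna()
    overall = float(valid.mean()) if len(valid) else np.nan
    return per_df, overall


@dataclass
class RegulationConfig:
    """Thresholds for distilling trans-associations into regulation edges."""

    cis_q: float = 0.05
    cis_logfc: float = -0.2
    trans_q: float = 0.2
    trans_abs_logfc: float = 0.05
    trans_rel_logfc: float = 0.05
    neighbor_window_bp: float = 1e6
    neighbor_p: float = 1e-3
    neighbor_logfc: float = -0.1


def infer_regulations(
    results: pd.DataFrame,
    a: GRNAAssignment,
    genes: pd.DataFrame,
    cfg: RegulationConfig | None = None,
) -> pd.DataFrame:
    """Regulator -> target edges supported by every gRNA in every screen.

    ``results`` holds one row per (screen, grna, gene) with columns screen,
    grna, gene, p, q, logfc. An edge regulator->trans-gene survives only if,
    for both gRNAs targeting the regulator's TSS in both screens: (1) the
    regulator itself is significantly repressed (Q <= cis_q and
    logFC <= cis_logfc); (2) the trans-gene responds (Q <= trans_q,
    |logFC| >= trans_abs_logfc, and |logFC| relative to the regulator's
    >= trans_rel_logfc); and (3) no other gene within the cis window of the
    targeted TSS looks repressed (P <= neighbor_p and
    logFC <= neighbor_logfc), which would leave a cis bystander as the
    plausible driver.
    """
    cfg = cfg or RegulationConfig()
    results = results.sort_values(["screen", "grna", "gene"], kind="stable")
    screens = sorted(results["screen"].unique())
    tssmeta = a.meta[a.meta["class"] == "TSS-targeting"]
    edges = []
    for tgt, sub in tssmeta.groupby("target_gene"):
        grnas = sorted(sub.index)
        if tgt not in genes.index:
            warnings.warn(f"regulator {tgt!r} lacks annotation; skipped")
            continue
        tchrom, tpos = genes.loc[tgt, "chromosome"], genes.loc[tgt, "tss"]
        replicate_tables = {}
        complete = True
        for sc in screens:
            for gid in grnas:
                tab = results[(results["screen"] == sc) & (results["grna"] == gid)].set_index("gene")
                if tab.empty or tgt not in tab.index:
                    complete = False
                replicate_tables[(sc, gid)] = tab
        if not complete:
            warnings.warn(f"regulator {tgt!r} missing a gRNA/screen replicate; excluded")
            continue
        # condition 1 + 3 are per-replicate, gene-independent
        ok = True
        for tab in replicate_tables.values():
            cis = tab.loc[tgt]
            if not (cis["q"] <= cfg.cis_q and cis["logfc"] <= cfg.cis_logfc):
                ok = False
                break
            for g in tab.index:
                if g == tgt or g not in genes.index:
                    continue
                if genes.loc[g, "chromosome"] != tchrom:
                    continue
                if abs(int(genes.loc[g, "tss"]) - int(tpos)) > cfg.neighbor_window_bp:
                    continue
                if tab.loc[g, "p"] <= cfg.neighbor_p and tab.loc[g, "logfc"] <= cfg.neighbor_logfc:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        candidate_genes = sorted(
            g
            for g in replicate_tables[(screens[0], grnas[0])].index
            if g != tgt and _is_trans(genes, g, tchrom, tpos, cfg.neighbor_window_bp)
        )
        for g in candidate_genes:
            support = []
            passed = True
            for (sc, gid), tab in replicate_tables.items():
                if g not in tab.index:
                    passed = False
                    break
                row = tab.loc[g]
                cis_lfc = tab.loc[tgt, "logfc"]
                rel = abs(row["logfc"]) / abs(cis_lfc) if cis_lfc != 0 else np.inf
                if not (
                    row["q"] <= cfg.trans_q
                    and abs(row["logfc"]) >= cfg.trans_abs_logfc
                    and rel >= cfg.trans_rel_logfc
                ):
                    passed = False
                    break
                support.append((sc, gid, float(row["logfc"]), float(row["q"])))
            if passed:
                edges.append(
                    {
                        "regulator": tgt,
                        "target": g,
                        "support": tuple(support),
                        "mean_logfc": float(np.mean([s[2] for s in support])),
                    }
                )
    return pd.DataFrame(edges, columns=["regulator", "target", "support", "mean_logfc"])
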