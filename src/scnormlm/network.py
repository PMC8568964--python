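"""Q-value co-expression networks and gene-program removal.

Q values are computed per gene (each gene's tests against all others form
one BH group) to respect differing gene roles; an edge is kept when either
direction passes the cutoff. Dominant transcriptional programs (e.g.
house-keeping gene sets) can be absorbed by appending the top principal
component of the set genes' residual expression as an extra covariate, one
program per call, with the looping left to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import bh_qvalues, residualize
from .normalization import CovariateSet, CovariateTerm, NormalizedExpression


@dataclass
class CoexpressionNetwork:
    """Symmetric, self-edge-free signed adjacency over a gene list."""

    genes: list[str]
    adjacency: np.ndarray  # bool
    sign: np.ndarray  # int8, sign of conditional R on edges
    q_threshold: float

    def __post_init__(self):
        A = np.asarray(self.adjacency, bool)
        if not (A == A.T).all():
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("self-edges are not allowed")
        self.adjacency = A

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_edge_list(self) -> pd.DataFrame:
        ii, jj = np.where(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            {
                "gene_i": [self.genes[i] for i in ii],
                "gene_j": [self.genes[j] for j in jj],
                "sign": self.sign[ii, jj],
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for _, row in self.to_edge_list().iterrows():
            g.add_edge(row["gene_i"], row["gene_j"], sign=int(row["sign"]))
        return g


def pergene_qvalue_matrix(pairs: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """Directed Q matrix: Q[i, j] is gene i's BH Q for its test against j,
    adjusted within gene i's group of tests versus all other genes."""
    idx = {g: k for k, g in enumerate(genes)}
    n = len(genes)
    P = np.ones((n, n))
    ii = pairs["gene_i"].map(idx).to_numpy()
    jj = pairs["gene_j"].map(idx).to_numpy()
    P[ii, jj] = pairs["p"].to_numpy()
    P[jj, ii] = pairs["p"].to_numpy()
    Q = np.ones((n, n))
    for i in range(n):
        others = np.arange(n) != i
        Q[i, others] = bh_qvalues(P[i, others])
    return Q


def build_network(
    pairs: pd.DataFrame, genes: list[str], q_threshold: float = 1e-15
) -> CoexpressionNetwork:
    """Threshold per-gene Q values into a co-expression network.

    ``pairs`` is a co-expression result frame (gene_i, gene_j, r, p); the
    edge (i, j) exists when either direction's per-gene Q passes the cutoff
    and carries the sign of the conditional correlation.
    """
    idx = {g: k for k, g in enumerate(genes)}
    n = len(genes)
    Q = pergene_qvalue_matrix(pairs, genes)
    A = (Q <= q_threshold) | (Q.T <= q_threshold)
    np.fill_diagonal(A, False)
    sign = np.zeros((n, n), dtype=np.int8)
    ii = pairs["gene_i"].map(idx).to_numpy()
    jj = pairs["gene_j"].map(idx).to_numpy()
    sg = np.sign(pairs["r"].to_numpy()).astype(np.int8)
    sign[ii, jj] = sg
    sign[jj, ii] = sg
    sign[~A] = 0
    return CoexpressionNetwork(list(genes), A, sign, q_threshold)


def principal_genes(net: CoexpressionNetwork, k: int = 100) -> list[str]:
    """The k most-connected genes (ties broken lexicographically)."""
    deg = net.degrees()
    connected = [(int(-deg[i]), g) for i, g in enumerate(net.genes) if deg[i] > 0]
    connected.sort()
    if len(connected) < k:
        warnings.warn(f"only {len(connected)} genes have edges (asked for {k})")
    return [g for _, g in connected[:k]]


def remove_geneset_pc(
    expr: NormalizedExpression, gene_set: list[str], covariates: CovariateSet, label: str | None = None
) -> CovariateSet:
    """Append the top PC of a gene set's residual expression as a covariate.

    Existing covariates are removed from the normalized expression at the
    mean level; the leading right singular vector (a per-cell score) of the
    residualized rows restricted to the set is appended as one continuous
    covariate. Applying this covariate in subsequent tests absorbs the
    program that dominates the set's co-expression. The caller drives any
    iteration (choosing the next set and when to stop).
    """
    present = [g for g in gene_set if g in expr.gene_ids]
    if len(present) < 2:
        raise ValueError("need at least 2 gene-set genes present in the expression matrix")
    idx = [expr.gene_ids.index(g) for g in present]
    resid = residualize(expr.y_tilde[idx], covariates.values)
    _, s, vt = np.linalg.svd(resid, full_matrices=False)
    pc = vt[0]
    pc = pc * np.sign(pc[np.abs(pc).argmax()])  # deterministic sign
    term = CovariateTerm(label or f"geneset_pc({len(present)} genes)")
    return covariates.with_rows(pc[None, :], [term])


def edge_overabundance(
    net: CoexpressionNetwork,
    annotations: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    parent_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation P for over-abundance of edges within annotated gene sets.

    Only sets with at least two internal edges and at most half of all
    network edges internal are tested; the null re-assigns the same number
    of annotated nodes uniformly among network nodes, and
    P = (1 + #{null >= observed}) / (n_perm + 1). With a parent map, a
    set's parent is dropped when it annotates the same network nodes.
    """
    rng = np.random.default_rng(seed)
    nodes = net.genes
    node_idx = {g: i for i, g in enumerate(nodes)}
    A = net.adjacency
    total_edges = net.n_edges
    sets = dict(annotations)
    if parent_map:
        member_on_net = {
            name: frozenset(g for g in members if g in node_idx) for name, members in sets.items()
        }
        drop = {
            parent_map[name]
            for name in sets
            if parent_map.get(name) in sets and member_on_net[name] == member_on_net[parent_map[name]]
        }
        sets = {k: v for k, v in sets.items() if k not in drop}
    rows = []
    for name in sorted(sets):
        members = sorted({g for g in sets[name] if g in node_idx})
        mi = np.asarray([node_idx[g] for g in members], dtype=int)
        observed = int(A[np.ix_(mi, mi)].sum() // 2) if mi.size else 0
        if observed < 2 or observed > total_edges / 2:
            rows.append(
                {"set": name, "n_members": len(members), "observed_edges": observed,
                 "p": np.nan, "excluded": True}
            )
            continue
        null_ge = 0
        for _ in range(n_perm):
            perm = rng.choice(len(nodes), size=mi.size, replace=False)
            if A[np.ix_(perm, perm)].sum() // 2 >= observed:
                null_ge += 1
        rows.append(
            {
                "set": name,
                "n_members": len(members),
                "observed_edges": observed,
                "p": (1 + null_ge) / (n_perm + 1),
                "excluded": False,
            }
        )
    return pd.DataFrame(rows).set_index("set")
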