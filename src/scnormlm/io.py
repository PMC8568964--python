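"""Readers, writers and quality control for UMI count data and side tables.

Counts are stored genes x cells. Matrix Market files follow the same
convention (genes are rows, 1-based indices) and are accompanied by plain
text gene/cell id files. Dense TSV has one gene per row, first column the
gene id, and a header row of cell ids.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Integer gene x cell UMI count matrix with id lists.

    Attributes
    ----------
    counts : ndarray of int, shape (n_genes, n_cells)
    gene_ids, cell_ids : list of str
        Unique identifiers matching the matrix dimensions.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != self.counts.shape[1]:
            raise ValueError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_totals(self) -> np.ndarray:
        """Per-cell total UMI counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def zeros_per_gene(self) -> np.ndarray:
        """Number of zero-count cells per gene."""
        return (self.counts == 0).sum(axis=1)

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            self.counts[np.ix_(gm, cm)],
            [g for g, k in zip(self.gene_ids, gm) if k],
            [c for c, k in zip(self.cell_ids, cm) if k],
        )


@dataclass
class QCConfig:
    """Iterative QC thresholds (defaults follow droplet/10x conventions)."""

    min_reads_per_cell: int = 500
    min_genes_per_cell: int = 100
    min_cells_per_gene: int = 50
    min_cell_fraction_per_gene: float = 0.02

    def __post_init__(self) -> None:
        if min(self.min_reads_per_cell, self.min_genes_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.min_cell_fraction_per_gene <= 1:
            raise ValueError("min_cell_fraction_per_gene must be in [0, 1]")


@dataclass
class QCReport:
    """Removed gene/cell ids per QC iteration."""

    iterations: list[dict] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def removed_genes(self) -> list[str]:
        return [g for it in self.iterations for g in it["genes"]]

    @property
    def removed_cells(self) -> list[str]:
        return [c for it in self.iterations for c in it["cells"]]


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".mtx") else path
    return stem + ".genes.txt", stem + ".cells.txt"


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        return [ln.strip().split("\t")[0] for ln in fh if ln.strip()]


def read_counts(path, fmt: str | None = None, genes_path=None, cells_path=None) -> CountMatrix:
    """Read a gene x cell count matrix from Matrix Market or dense TSV.

    For ``mtx`` the gene and cell id files default to ``<stem>.genes.txt`` /
    ``<stem>.cells.txt`` next to the matrix.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = "mtx" if path.endswith(".mtx") else "tsv"
    if fmt == "mtx":
        try:
            mat = spio.mmread(path)
        except Exception as exc:  # scipy raises assorted types on bad headers
            raise ParseError(f"{path}: malformed Matrix Market file: {exc}") from exc
        mat = sparse.coo_matrix(mat)
        if not np.issubdtype(mat.dtype, np.integer):
            if not np.allclose(mat.data, np.round(mat.data)):
                raise ParseError(f"{path}: non-integer entries in count matrix")
            mat = mat.astype(np.int64)
        if mat.data.size and mat.data.min() < 0:
            raise ParseError(f"{path}: negative count entries")
        gp, cp = _sidecar_paths(path)
        genes = _read_ids(genes_path or gp)
        cells = _read_ids(cells_path or cp)
        if (len(genes), len(cells)) != mat.shape:
            raise ParseError(
                f"{path}: id files ({len(genes)} genes, {len(cells)} cells) do not "
                f"match declared shape {mat.shape}"
            )
        return CountMatrix(np.asarray(mat.todense()), genes, cells)
    if fmt == "tsv":
        return _read_counts_tsv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_counts_tsv(path: str) -> CountMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    toks = first.split("\t")
    # Header detection: a header row has non-numeric tokens beyond column 1.
    has_header = any(not _is_int(t) for t in toks[1:]) if len(toks) > 1 else False
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None, index_col=0)
    cells = [str(c) for c in df.columns] if has_header else [f"cell{i}" for i in range(df.shape[1])]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.where(~np.vectorize(_is_number)(arr.astype(str)))
        row = int(bad[0][0]) + 1 + int(has_header)
        raise ParseError(f"{path}: non-numeric count entry on line {row + 1}")
    if not np.allclose(arr, np.round(arr)):
        raise ParseError(f"{path}: non-integer count entries")
    return CountMatrix(arr.astype(np.int64), [str(g) for g in df.index], cells)


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_counts(m: CountMatrix, path, fmt: str | None = None) -> None:
    """Write counts as Matrix Market (+ id sidecars) or dense TSV."""
    path = os.fspath(path)
    if fmt is None:
        fmt = "mtx" if path.endswith(".mtx") else "tsv"
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(m.counts), field="integer")
        gp, cp = _sidecar_paths(path)
        for p, ids in ((gp, m.gene_ids), (cp, m.cell_ids)):
            with open(p, "w") as fh:
                fh.write("\n".join(ids) + "\n")
    elif fmt == "tsv":
        pd.DataFrame(m.counts, index=m.gene_ids, columns=m.cell_ids).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def qc_filter(m: CountMatrix, cfg: QCConfig | None = None) -> tuple[CountMatrix, QCReport]:
    """Iterative joint gene/cell filtering to a fixed point.

    Each iteration evaluates all four thresholds on the current matrix and
    removes offending genes and cells simultaneously, then repeats until
    nothing is removed. The gene cell-fraction threshold always refers to the
    current number of cells.
    """
    cfg = cfg or QCConfig()
    cur = m
    report = QCReport()
    while True:
        totals = cur.cell_totals
        genes_per_cell = (cur.counts > 0).sum(axis=0)
        cells_per_gene = (cur.counts > 0).sum(axis=1)
        cell_ok = (totals >= cfg.min_reads_per_cell) & (genes_per_cell >= cfg.min_genes_per_cell)
        gene_ok = (cells_per_gene >= cfg.min_cells_per_gene) & (
            cells_per_gene >= cfg.min_cell_fraction_per_gene * cur.n_cells
        )
        if cell_ok.all() and gene_ok.all():
            break
        report.iterations.append(
            {
                "genes": [g for g, k in zip(cur.gene_ids, gene_ok) if not k],
                "cells": [c for c, k in zip(cur.cell_ids, cell_ok) if not k],
            }
        )
        cur = cur.subset(gene_ok, cell_ok)
        if cur.n_genes == 0 or cur.n_cells == 0:
            raise ValueError("QC removed all genes or all cells")
    return cur, report


@dataclass
class CovariateTable:
    """Raw per-cell covariates: a cells x columns frame plus per-column kind."""

    values: pd.DataFrame  # indexed by cell id
    kinds: dict[str, str]  # column -> "continuous" | "categorical"


def read_cell_covariates(path, cell_ids: list[str] | None = None) -> CovariateTable:
    """Read a covariate TSV: header row, first column cell id.

    Column types come from an optional second row whose first field is
    ``#type`` (values ``continuous``/``categorical``); otherwise non-numeric
    columns are treated as categorical.
    """
    path = os.fspath(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        second = fh.readline().rstrip("\n").split("\t")
    kinds: dict[str, str] | None = None
    skip = []
    if second and second[0] == "#type":
        declared = second[1:]
        if len(declared) != len(header) - 1:
            raise ParseError(f"{path}: #type row has {len(declared)} entries, expected {len(header) - 1}")
        bad = [t for t in declared if t not in ("continuous", "categorical")]
        if bad:
            raise ParseError(f"{path}: unknown covariate type {bad[0]!r} in #type row")
        kinds = dict(zip(header[1:], declared))
        skip = [1]
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ParseError(f"{path}: missing values in column {col!r}")
    if kinds is None:
        kinds = {
            c: "continuous" if np.issubdtype(df[c].dtype, np.number) else "categorical"
            for c in df.columns
        }
    for c, k in kinds.items():
        if k == "continuous":
            df[c] = pd.to_numeric(df[c])
    if cell_ids is not None:
        missing = set(cell_ids) - set(df.index)
        unknown = set(df.index) - set(cell_ids)
        if missing:
            raise ParseError(f"{path}: no covariates for cell(s) {sorted(missing)[:3]}")
        if unknown:
            raise ParseError(f"{path}: unknown cell id(s) {sorted(unknown)[:3]}")
        df = df.loc[list(cell_ids)]
    return CovariateTable(df, kinds)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene annotation TSV (gene_id, chromosome, tss) indexed by gene id.

    TSS coordinates are 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["gene_id", "chromosome", "tss"] + list(df.columns[3:])
    df["tss"] = df["tss"].astype(np.int64)
    if (df["tss"] < 1).any():
        raise ParseError(f"{path}: TSS coordinates must be >= 1 (1-based)")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicated gene ids")
    return df.set_index("gene_id")


def tss_distance(ann: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """TSS-to-TSS distance in bp; infinite across chromosomes."""
    a, b = ann.loc[gene_a], ann.loc[gene_b]
    if a["chromosome"] != b["chromosome"]:
        return np.inf
    return float(abs(int(a["tss"]) - int(b["tss"])))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, members (tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: GMT rows need name, description, >=1 gene")
            if parts[0] in sets:
                warnings.warn(f"duplicate gene set {parts[0]!r}; keeping first")
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
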