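"""Jam3-positive/negative single-cell marker comparison.

Multiciliated cells are split on the expression of a single gene (Jam3 by
default: a cell is positive with at least one read), and per-cell scores for
marker panels — deuterosomal-stage genes and mature-MCC genes — are compared
between the two groups with a two-sided Mann-Whitney test.  Scores are means
of library-size-normalised (CPM) expression over the panel's genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy import stats

from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of non-negative integer counts."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise InputError("counts must be a 2-D genes x cells array")
        if not np.all(np.isfinite(counts)):
            raise InputError("counts must be finite")
        if np.any(counts < 0):
            raise InputError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise InputError("counts must be integral")
            counts = rounded.astype(np.int64)
        self.counts = counts
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise InputError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise InputError("cell ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise InputError(f"gene {gene!r} not present in matrix") from None


@dataclass
class MarkerPanel:
    """Marker gene lists plus the split and reference genes."""

    deuterosomal: list[str]
    mature: list[str]
    reference_gene: str = "Foxj1"
    split_gene: str = "Jam3"

    def __post_init__(self) -> None:
        self.deuterosomal = list(self.deuterosomal)
        self.mature = list(self.mature)
        if not self.deuterosomal or not self.mature:
            raise InputError("marker lists must be non-empty")
        overlap = set(self.deuterosomal) & set(self.mature)
        if overlap:
            raise InputError(f"marker lists overlap: {sorted(overlap)}")
        if self.split_gene in set(self.deuterosomal) | set(self.mature):
            raise InputError(f"marker lists must not contain {self.split_gene!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> ExpressionMatrix:
    """Read a genes x cells TSV: first column gene ids, header cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.to_numpy(), list(df.index), list(df.columns))


def read_counts_mtx(mtx_path, genes_path, cells_path) -> ExpressionMatrix:
    """Read a MatrixMarket genes x cells matrix with row/column label files."""
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    cells = [line.strip() for line in open(cells_path) if line.strip()]
    return ExpressionMatrix(np.asarray(mat), genes, cells)


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one gene per line; blank lines ignored."""
    genes = [line.strip() for line in open(path) if line.strip()]
    if not genes:
        raise InputError(f"gene list {path} is empty")
    return genes


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def split_by_gene(m: ExpressionMatrix, split_gene: str = "Jam3") -> tuple[list[str], list[str]]:
    """Partition cells on the split gene: positive means >= 1 read.

    Returns (positive cell ids, negative cell ids); the partition is
    exhaustive and disjoint.
    """
    row = m.counts[m.gene_index(split_gene)]
    pos_mask = row >= 1
    if not pos_mask.any():
        log.warning("no cell has a %s read; all cells negative", split_gene)
    positive = [c for c, keep in zip(m.cell_ids, pos_mask) if keep]
    negative = [c for c, keep in zip(m.cell_ids, pos_mask) if not keep]
    return positive, negative


def marker_score(
    m: ExpressionMatrix, genes: list[str], normalize: str = "cpm"
) -> pd.Series:
    """Per-cell marker-panel score: mean normalised expression over the panel.

    Normalisation is per-cell library size: ``cpm`` scales to counts per
    million, ``fraction`` to counts per total.  Listed genes absent from the
    matrix are dropped with a warning; a cell with zero total counts gets NaN.
    """
    if normalize not in ("cpm", "fraction"):
        raise InputError(f"unknown normalization {normalize!r}")
    present = [g for g in genes if g in set(m.gene_ids)]
    missing = [g for g in genes if g not in set(m.gene_ids)]
    if missing:
        log.warning("dropping %d absent marker genes: %s", len(missing), missing)
    if not present:
        raise InputError("none of the listed marker genes is present")
    depth = m.counts.sum(axis=0).astype(float)
    scale = 1e6 if normalize == "cpm" else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = m.counts * scale / depth[None, :]
    norm[:, depth == 0] = np.nan
    idx = [m.gene_index(g) for g in present]
    score = norm[idx].mean(axis=0)
    return pd.Series(score, index=m.cell_ids, name="score")


def compare_marker_sets(m: ExpressionMatrix, panel: MarkerPanel) -> dict:
    """Compare marker scores between split-gene-positive and -negative cells.

    For each panel (deuterosomal, mature) and for the reference gene's CPM, a
    two-sided Mann-Whitney U test between the two groups.  Returns a dict
    keyed by panel name with group means, the U statistic, p-value and n.
    """
    positive, negative = split_by_gene(m, panel.split_gene)
    if not positive or not negative:
        raise InputError(
            f"both {panel.split_gene}-positive and -negative groups must be "
            f"non-empty (got {len(positive)} / {len(negative)})"
        )
    panels = {
        "deuterosomal": panel.deuterosomal,
        "mature": panel.mature,
        "reference_gene": [panel.reference_gene],
    }
    out: dict[str, dict] = {}
    for name, genes in panels.items():
        score = marker_score(m, genes)
        a = score[positive].dropna().to_numpy()
        b = score[negative].dropna().to_numpy()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[name] = {
            "mean_positive": float(np.mean(a)),
            "mean_negative": float(np.mean(b)),
            "statistic": float(stat),
            "p_value": float(p),
            "n_positive": int(a.size),
            "n_negative": int(b.size),
        }
    return out
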