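"""Sentinel-gene Spearman co-expression discovery and multi-gene cluster masks.

Starting from a well-understood "sentinel" gene (PRG4, ACAN, COL2A1, IBSP ...)
and a cell subset, every sufficiently expressed candidate gene is ranked by
the magnitude of its Spearman correlation with the sentinel over that subset.
Correlations are computed on normalized values; because per-gene z-scoring is
a monotone transform, ranks (hence rho) are identical on the z scale.
P-values use the two-sided t approximation and are BH-adjusted across the
tested candidates. Clusters are refined by intersecting strong-expression
masks (z > threshold for every listed gene) and re-running the test on the
masked cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import ConsistencyError, ParameterError
from .preprocess import NormalizedMatrix, ZScoreMatrix
from .zzplot import CellSelection

MIN_SUBSET = 10

__all__ = [
    "CoexpressionRanking",
    "spearman_discovery",
    "multi_gene_mask",
    "sentinel_high_cells",
    "refine_cluster",
]


@dataclass
class CoexpressionRanking:
    """Ranked Spearman co-expression table for one sentinel gene.

    ``table`` columns: gene, rho, p, q, n_cells_used, co_positive_frac
    (fraction of subset cells where sentinel and candidate are both nonzero,
    offered as a secondary "how often co-expressed" sort key). Rows are
    ordered by |rho| descending; the sentinel itself is excluded.
    """

    sentinel: str
    subset_barcodes: list[str]
    table: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)

    def to_frame(self) -> pd.DataFrame:
        return self.table.set_index("gene")


def _resolve_subset(norm: NormalizedMatrix, subset) -> np.ndarray:
    if subset is None:
        return np.arange(norm.n_cells)
    barcodes = subset.barcodes if isinstance(subset, CellSelection) else list(subset)
    index = {b: i for i, b in enumerate(norm.barcodes)}
    missing = [b for b in barcodes if b not in index]
    if missing:
        raise ConsistencyError(f"subset barcodes not in matrix: {missing[:5]}")
    return np.array([index[b] for b in barcodes], dtype=int)


def spearman_discovery(
    norm: NormalizedMatrix,
    sentinel: str,
    subset: CellSelection | Sequence[str] | None = None,
    min_expressing_frac: float = 0.1,
    provenance: list[dict] | None = None,
) -> CoexpressionRanking:
    """Rank all candidate genes by |Spearman rho| with the sentinel.

    Candidates must be expressed (nonzero) in at least ``min_expressing_frac``
    of the subset, which filters dropout-dominated genes; candidates constant
    within the subset are untestable and skipped. Ties get average ranks.
    """
    if not 0.0 <= min_expressing_frac <= 1.0:
        raise ParameterError(f"min_expressing_frac must be in [0, 1], got {min_expressing_frac}")
    cols = _resolve_subset(norm, subset)
    n = len(cols)
    if n < MIN_SUBSET:
        raise ParameterError(f"subset has {n} cells; at least {MIN_SUBSET} required")

    si = norm.gene_index(sentinel)
    sub = np.asarray(norm.values[:, cols].todense(), dtype=np.float64)
    svals = sub[si]
    if not np.any(svals > 0):
        raise ParameterError(f"sentinel {norm.genes[si]!r} is not expressed in the subset")
    if np.all(svals == svals[0]):
        raise ParameterError(f"sentinel {norm.genes[si]!r} is constant in the subset")

    expressed_frac = (sub > 0).mean(axis=1)
    candidates = np.flatnonzero(expressed_frac >= min_expressing_frac)
    candidates = candidates[candidates != si]
    # constant candidates have no rank variance to correlate
    variable = np.array([not np.all(sub[g] == sub[g, 0]) for g in candidates])
    candidates = candidates[variable]

    if candidates.size == 0:
        table = pd.DataFrame(
            columns=["gene", "rho", "p", "q", "n_cells_used", "co_positive_frac"]
        )
        return CoexpressionRanking(
            sentinel=norm.genes[si],
            subset_barcodes=[norm.barcodes[c] for c in cols],
            table=table,
            provenance=list(provenance or []),
        )

    # Spearman = Pearson on average-tie ranks, vectorized over candidates
    srank = scipy.stats.rankdata(svals)
    cranks = scipy.stats.rankdata(sub[candidates], axis=1)
    s_centered = srank - srank.mean()
    c_centered = cranks - cranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((s_centered**2).sum() * (c_centered**2).sum(axis=1))
    rho = (c_centered @ s_centered) / denom
    rho = np.clip(rho, -1.0, 1.0)

    # two-sided p via the t approximation with n - 2 degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2))
    q = multipletests(p, method="fdr_bh")[1] if len(p) > 1 else p.copy()

    co_pos = ((sub[candidates] > 0) & (svals > 0)).mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": [norm.genes[g] for g in candidates],
            "rho": rho,
            "p": p,
            "q": q,
            "n_cells_used": n,
            "co_positive_frac": co_pos,
        }
    )
    table = table.sort_values(
        by=["rho", "gene"], key=lambda s: -s.abs() if s.name == "rho" else s, kind="stable"
    ).reset_index(drop=True)
    return CoexpressionRanking(
        sentinel=norm.genes[si],
        subset_barcodes=[norm.barcodes[c] for c in cols],
        table=table,
        provenance=list(provenance or []),
    )


def multi_gene_mask(
    z: ZScoreMatrix, genes: Sequence[str], threshold: float = 1.0
) -> np.ndarray:
    """Boolean per-cell mask: z > threshold for EVERY listed gene.

    The conventional "strong expression" cut is z > 1; conjunction over genes
    makes the mask monotone shrinking as genes are added.
    """
    if len(genes) == 0:
        raise ParameterError("multi_gene_mask needs at least one gene")
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    mask = np.ones(z.n_cells, dtype=bool)
    for gene in genes:
        mask &= z.gene_z(gene) > threshold
    return mask


def sentinel_high_cells(z: ZScoreMatrix, sentinel: str, threshold: float = 1.0) -> CellSelection:
    """Cells strongly expressing the sentinel (z > threshold), as a selection."""
    mask = multi_gene_mask(z, [sentinel], threshold=threshold)
    return CellSelection(
        barcodes=[b for b, m in zip(z.barcodes, mask) if m],
        criteria={"gene_thresholds": {sentinel.upper(): threshold}},
    )


def refine_cluster(
    norm: NormalizedMatrix,
    mask: np.ndarray | Sequence[str],
    sentinel: str,
    min_expressing_frac: float = 0.1,
    provenance: list[dict] | None = None,
) -> CoexpressionRanking:
    """Re-run Spearman discovery on a masked cell subset, keeping provenance.

    ``mask`` is either a boolean per-cell array (aligned with the matrix) or
    an explicit barcode list from an earlier selection. Each refinement round
    appends its mask description to the ranking's provenance list.
    """
    if isinstance(mask, np.ndarray) and mask.dtype == bool:
        if mask.shape != (norm.n_cells,):
            raise ConsistencyError("mask length does not match cell count")
        barcodes = [b for b, m in zip(norm.barcodes, mask) if m]
    else:
        barcodes = list(mask)
    step = {"type": "mask", "sentinel": sentinel.upper(), "n_cells": len(barcodes)}
    return spearman_discovery(
        norm,
        sentinel,
        subset=barcodes,
        min_expressing_frac=min_expressing_frac,
        provenance=list(provenance or []) + [step],
    )
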