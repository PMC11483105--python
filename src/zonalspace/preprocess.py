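"""Normalization and per-gene z-scoring of UMI counts.

The pipeline is: raw counts -> trimmed-quantile normalization (per-cell scale
factors; zeros stay zeros) -> per-gene z-scores over ALL cells with population
standard deviation. Under that convention a gene's z of 0 is exactly its
population mean, which is what anchors the left vertical guide line of the
zonal scatter at x = 0.

Dropouts (raw count 0) are tracked in an explicit boolean mask and excluded
from expressing-cell summaries but NOT from the z-score moments.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from ._exceptions import GeneLookupError, InputFormatError, NormalizationError, ParameterError
from .io_formats import CountMatrix

CACHE_VERSION = 1

__all__ = [
    "NormalizedMatrix",
    "ZScoreMatrix",
    "trimmed_quantile_normalize",
    "zscore",
    "expression_summaries",
    "save_cache",
    "load_cache",
]


@dataclass
class NormalizedMatrix:
    """Per-cell scaled expression values (genes x cells), sparse.

    ``values[g, c] = counts[g, c] * scale[c]`` with strictly positive scale
    factors, so the zero pattern of the raw counts is preserved exactly.
    """

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix
    scale: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene: str) -> int:
        return _gene_index(self.genes, gene)

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense normalized values of one gene across all cells."""
        return np.asarray(self.values[self.gene_index(gene)].todense()).ravel()


@dataclass
class ZScoreMatrix:
    """Per-gene z-scored expression plus the dropout mask and gene summaries.

    ``z[g, c] = (values[g, c] - mean_g) / sd_g`` with mean and population sd
    taken over all cells (dropouts included). Genes with zero variance carry
    z = 0 everywhere and are flagged non-informative.
    """

    genes: list[str]
    barcodes: list[str]
    z: np.ndarray
    dropout: np.ndarray  # bool, True where raw count == 0
    mean_with_dropouts: np.ndarray  # per-gene mean of normalized values, all cells
    sd: np.ndarray  # per-gene population sd of normalized values
    mean_without_dropouts: np.ndarray  # per-gene mean over expressing cells (0 if none)
    noninformative: np.ndarray  # bool, True where sd == 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene: str) -> int:
        return _gene_index(self.genes, gene)

    def gene_z(self, gene: str) -> np.ndarray:
        return self.z[self.gene_index(gene)]

    def gene_dropout(self, gene: str) -> np.ndarray:
        return self.dropout[self.gene_index(gene)]


def _gene_index(genes: list[str], gene: str) -> int:
    target = gene.upper()
    try:
        return genes.index(target)
    except ValueError:
        near = difflib.get_close_matches(target, genes, n=3)
        hint = f"; close matches: {near}" if near else ""
        raise GeneLookupError(f"gene {target!r} not in matrix{hint}") from None


def trimmed_quantile_normalize(
    counts: CountMatrix,
    quantile: float = 0.75,
    trim_frac: float = 0.05,
) -> NormalizedMatrix:
    """Scale each cell so its upper quantile of nonzero counts is constant.

    The top ``trim_frac`` fraction of genes by dataset-wide total count is
    excluded before taking each cell's quantile, so a handful of very abundant
    transcripts cannot dominate the scale factors. Per cell ``c`` with quantile
    ``q_c``, ``scale[c] = median(q) / q_c`` and all counts of the cell
    (trimmed genes included) are multiplied by ``scale[c]``.
    """
    if not 0.0 < quantile < 1.0:
        raise ParameterError(f"quantile must be in (0, 1), got {quantile}")
    if not 0.0 <= trim_frac < 0.25:
        raise ParameterError(f"trim_frac must be in [0, 0.25), got {trim_frac}")

    mat = counts.counts.tocsc()
    n_genes, n_cells = mat.shape
    totals = np.asarray(mat.sum(axis=1)).ravel()
    n_trim = int(trim_frac * n_genes)
    keep = np.ones(n_genes, dtype=bool)
    if n_trim > 0:
        # stable sort -> deterministic trimming under ties
        trimmed = np.argsort(totals, kind="stable")[n_genes - n_trim:]
        keep[trimmed] = False

    kept = mat[keep, :].tocsc()
    q = np.empty(n_cells)
    for c in range(n_cells):
        col = kept.data[kept.indptr[c]:kept.indptr[c + 1]]
        col = col[col > 0]
        if col.size == 0:
            raise NormalizationError(
                f"cell {counts.barcodes[c]!r} has no nonzero counts among "
                "untrimmed genes; cannot compute its quantile"
            )
        q[c] = np.quantile(col, quantile)
    scale = np.median(q) / q
    values = mat.astype(np.float64).multiply(sp.csr_matrix(scale)).tocsr()
    return NormalizedMatrix(
        genes=list(counts.genes),
        barcodes=list(counts.barcodes),
        values=sp.csr_matrix(values),
        scale=scale,
    )


def zscore(norm: NormalizedMatrix) -> ZScoreMatrix:
    """Per-gene z-scores over all cells with population (ddof=0) sd."""
    values = np.asarray(norm.values.todense(), dtype=np.float64)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    noninformative = sd == 0
    safe_sd = np.where(noninformative, 1.0, sd)
    z = (values - mean[:, None]) / safe_sd[:, None]
    z[noninformative, :] = 0.0

    dropout = values == 0
    n_expressing = (~dropout).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_without = np.where(
            n_expressing > 0, values.sum(axis=1) / np.maximum(n_expressing, 1), 0.0
        )
    return ZScoreMatrix(
        genes=list(norm.genes),
        barcodes=list(norm.barcodes),
        z=z,
        dropout=dropout,
        mean_with_dropouts=mean,
        sd=sd,
        mean_without_dropouts=mean_without,
        noninformative=noninformative,
    )


def expression_summaries(z: ZScoreMatrix, gene: str) -> dict:
    """Summaries of one gene on the normalized scale.

    Returns mean over all cells (dropouts counted as 0), mean over expressing
    cells only, percent and number of expressing cells, and the total summed
    expression. A never-expressed gene reports mean_without_dropouts = 0 with
    ``never_expressed`` flagged.
    """
    gi = z.gene_index(gene)
    n = z.n_cells
    n_expressing = int((~z.dropout[gi]).sum())
    return {
        "gene": z.genes[gi],
        "mean_with_dropouts": float(z.mean_with_dropouts[gi]),
        "mean_without_dropouts": float(z.mean_without_dropouts[gi]),
        "pct_expressing": 100.0 * n_expressing / n,
        "n_expressing": n_expressing,
        "total_expression": float(z.mean_with_dropouts[gi] * n),
        "never_expressed": n_expressing == 0,
    }


def save_cache(path: str | Path, norm: NormalizedMatrix, z: ZScoreMatrix) -> None:
    """Serialize the preprocessed pair to one compressed columnar file."""
    vals = norm.values.tocsr()
    np.savez_compressed(
        path,
        version=np.array([CACHE_VERSION]),
        genes=np.array(norm.genes),
        barcodes=np.array(norm.barcodes),
        values_data=vals.data,
        values_indices=vals.indices,
        values_indptr=vals.indptr,
        scale=norm.scale,
        z=z.z,
        mean_with=z.mean_with_dropouts,
        sd=z.sd,
        mean_without=z.mean_without_dropouts,
    )


def load_cache(path: str | Path) -> tuple[NormalizedMatrix, ZScoreMatrix]:
    """Inverse of :func:`save_cache`; a version mismatch is an explicit error."""
    with np.load(path, allow_pickle=False) as data:
        version = int(data["version"][0])
        if version != CACHE_VERSION:
            raise InputFormatError(
                f"cache {path} has version {version}, expected {CACHE_VERSION}; re-run preprocessing"
            )
        genes = [str(g) for g in data["genes"]]
        barcodes = [str(b) for b in data["barcodes"]]
        shape = (len(genes), len(barcodes))
        values = sp.csr_matrix(
            (data["values_data"], data["values_indices"], data["values_indptr"]), shape=shape
        )
        norm = NormalizedMatrix(genes=genes, barcodes=barcodes, values=values, scale=data["scale"])
        zmat = data["z"]
        sd = data["sd"]
        zs = ZScoreMatrix(
            genes=genes,
            barcodes=barcodes,
            z=zmat,
            dropout=np.asarray(values.todense()) == 0,
            mean_with_dropouts=data["mean_with"],
            sd=sd,
            mean_without_dropouts=data["mean_without"],
            noninformative=sd == 0,
        )
    return norm, zs
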