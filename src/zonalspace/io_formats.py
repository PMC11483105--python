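"""Reading count matrices and marker configuration; writing tables and selections.

Count matrices are UMI counts, genes x cells. Two on-disk layouts are supported:
the 10x-style MatrixMarket triplet directory (``matrix.mtx[.gz]`` +
``barcodes.tsv[.gz]`` + ``features.tsv[.gz]`` / ``genes.tsv[.gz]``) and a dense
delimited file with a header row. Gene symbols are case-folded to uppercase at
ingestion so marker matching is case-insensitive.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from ._exceptions import ConfigError, InputFormatError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ZMGSet",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_counts_dense",
    "read_zmg_config",
    "default_zmg",
    "write_table",
    "read_table",
]


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells.

    Parameters
    ----------
    genes
        Gene symbols, unique after uppercasing; one per row.
    barcodes
        Cell identifiers, unique; one per column.
    counts
        Non-negative integer matrix of shape ``(len(genes), len(barcodes))``,
        stored sparse (CSR).
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise InputFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise InputFormatError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        self.genes = [g.upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise InputFormatError(
                f"duplicate gene symbols after case-folding: {dupes}; "
                "pass collapse_duplicates=True to sum them"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InputFormatError("cell barcodes are not unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class ZMGSet:
    """Superficial and deep zone-marker-gene lists with optional weights.

    The two lists must be disjoint and non-empty. Weights default to 1.0,
    under which the zonal score reduces to the plain mean-difference form.
    """

    superficial: list[str]
    deep: list[str]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.superficial = [g.upper() for g in self.superficial]
        self.deep = [g.upper() for g in self.deep]
        if not self.superficial or not self.deep:
            raise ConfigError("superficial and deep marker lists must be non-empty")
        overlap = set(self.superficial) & set(self.deep)
        if overlap:
            raise ConfigError(
                f"genes listed in both superficial and deep: {sorted(overlap)}"
            )
        weights = {g.upper(): float(w) for g, w in self.weights.items()}
        for g, w in weights.items():
            if not w > 0:
                raise ConfigError(f"weight for {g} must be positive, got {w}")
        self.weights = {
            g: weights.get(g, 1.0) for g in self.superficial + self.deep
        }

    def weight(self, gene: str) -> float:
        return self.weights.get(gene.upper(), 1.0)


def _find_member(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise InputFormatError(
        f"none of {list(stems)} (or .gz variants) found in {directory}"
    )


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: Path) -> Iterator[list[str]]:
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                yield line.split("\t")


def _collapse_duplicate_genes(
    genes: list[str], counts: sp.spmatrix
) -> tuple[list[str], sp.csr_matrix]:
    """Sum rows sharing a case-folded symbol, keeping first-occurrence order."""
    upper = [g.upper() for g in genes]
    order: dict[str, int] = {}
    for g in upper:
        order.setdefault(g, len(order))
    rows = np.array([order[g] for g in upper])
    agg = sp.csr_matrix(
        (np.ones(len(rows)), (rows, np.arange(len(rows)))),
        shape=(len(order), len(rows)),
    )
    return list(order), sp.csr_matrix(agg @ counts)


def read_counts_mtx(directory: str | Path, collapse_duplicates: bool = False) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet directory into a :class:`CountMatrix`.

    ``matrix.mtx`` stores genes as rows with 1-based coordinate indices;
    ``features.tsv`` may carry one column (symbols) or the 10x two-plus-column
    layout (id, symbol, ...), in which case the symbol column is used.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputFormatError(f"not a directory: {directory}")
    mtx_path = _find_member(directory, ["matrix.mtx"])
    barcodes_path = _find_member(directory, ["barcodes.tsv"])
    features_path = _find_member(directory, ["features.tsv", "genes.tsv"])

    with (gzip.open(mtx_path, "rb") if mtx_path.suffix == ".gz" else open(mtx_path, "rb")) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:
            raise InputFormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    barcodes = [fields[0] for fields in _read_lines(barcodes_path)]
    feature_rows = list(_read_lines(features_path))
    genes = [f[1] if len(f) >= 2 else f[0] for f in feature_rows]

    if mat.shape[0] != len(genes):
        raise InputFormatError(
            f"{mtx_path} declares {mat.shape[0]} genes but "
            f"{features_path} lists {len(genes)}"
        )
    if mat.shape[1] != len(barcodes):
        raise InputFormatError(
            f"{mtx_path} declares {mat.shape[1]} cells but "
            f"{barcodes_path} lists {len(barcodes)}"
        )
    if collapse_duplicates:
        genes, mat = _collapse_duplicate_genes(genes, mat)
    return CountMatrix(genes=genes, barcodes=barcodes, counts=mat)


def write_counts_mtx(matrix: CountMatrix, directory: str | Path) -> None:
    """Write a :class:`CountMatrix` as a plain (uncompressed) 10x triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), matrix.counts.tocoo())
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes)
    )


def read_counts_dense(
    path: str | Path,
    genes_in: str = "rows",
    collapse_duplicates: bool = False,
) -> CountMatrix:
    """Read a dense TSV/CSV expression matrix with header row and label column.

    ``genes_in`` declares the on-disk orientation (``"rows"`` or ``"columns"``);
    the returned matrix is always genes x cells.
    """
    path = Path(path)
    if genes_in not in ("rows", "columns"):
        raise ParameterError(f"genes_in must be 'rows' or 'columns', got {genes_in!r}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except FileNotFoundError:
        raise InputFormatError(f"no such file: {path}") from None
    if genes_in == "columns":
        df = df.T
    values = df.to_numpy()
    bad = np.argwhere(~np.isfinite(values) | (values < 0) | (values != np.round(values)))
    if bad.size:
        coords = [
            f"(gene={df.index[i]}, cell={df.columns[j]}, value={values[i, j]})"
            for i, j in bad[:10]
        ]
        raise InputFormatError(
            f"non-integer or negative entries in {path}: {', '.join(coords)}"
        )
    genes = [str(g) for g in df.index]
    counts = sp.csr_matrix(values.astype(np.int64))
    if collapse_duplicates:
        genes, counts = _collapse_duplicate_genes(genes, counts)
    return CountMatrix(genes=genes, barcodes=[str(c) for c in df.columns], counts=counts)


def read_zmg_config(path: str | Path) -> ZMGSet:
    """Read a zone-marker configuration (JSON or YAML).

    Expected keys: ``superficial`` and ``deep`` (lists of gene symbols) and an
    optional ``weights`` mapping gene -> positive weight (default 1.0).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path} must contain a mapping with keys superficial/deep")
    for key in ("superficial", "deep"):
        if key not in data:
            raise ConfigError(f"{path} is missing required key {key!r}")
    return ZMGSet(
        superficial=list(data["superficial"]),
        deep=list(data["deep"]),
        weights=dict(data.get("weights") or {}),
    )


def default_zmg() -> ZMGSet:
    """The packaged default marker set for human articular cartilage.

    Superficial: PRG4, IGFBP5, CHI3L1, OGN. Deep: COL10A1, IBSP, CLEC3A, F13A1.
    """
    with resources.files("zonalspace.data").joinpath("zmg_default.json").open() as fh:
        data = json.load(fh)
    return ZMGSet(superficial=data["superficial"], deep=data["deep"])


def write_table(table, path: str | Path, format: str = "csv") -> None:
    """Write a tabular result (anything with ``to_frame`` or a DataFrame) to disk.

    CSV is RFC-4180; JSON uses the pandas ``split`` orientation so a round trip
    preserves the cell values.
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    path = Path(path)
    if format == "csv":
        df.to_csv(path)
    elif format == "json":
        df.to_json(path, orient="split", double_precision=10)
    else:
        raise ParameterError(f"unsupported table format: {format!r}")


def read_table(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Inverse of :func:`write_table` (used for round-trip verification)."""
    if format == "csv":
        return pd.read_csv(path, index_col=0)
    if format == "json":
        return pd.read_json(path, orient="split")
    raise ParameterError(f"unsupported table format: {format!r}")
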