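"""Zonal dot count and percentage tables, and selection enrichment.

For a chosen gene every cell falls into exactly one of nine compartments:
zone (superficial / middle / deep) crossed with expression category
(non-expressing, expressing below the population mean z < 0, expressing above
it z > 0; expressing cells at exactly z = 0 count as above). The percentage
table derives per-zone percent-expressing and dataset-wide expression means
from the count table and the normalized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConsistencyError, ParameterError
from .preprocess import NormalizedMatrix, ZScoreMatrix
from .zonal import ZONES, ZonalScores
from .zzplot import CellSelection

CATEGORIES = ("non_expressing", "z_below_mean", "z_above_mean")

__all__ = [
    "ZonalDotCountTable",
    "ZonalDotPercentageTable",
    "zonal_dot_count",
    "zonal_dot_percentage",
    "cluster_enrichment",
]


@dataclass
class ZonalDotCountTable:
    """3x3 integer grid: zones (rows) x expression categories (columns)."""

    gene: str
    grid: np.ndarray  # shape (3, 3), int
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.grid, index=pd.Index(ZONES, name="zone"), columns=list(CATEGORIES)
        )


@dataclass
class ZonalDotPercentageTable:
    """Per-zone percent expressing plus dataset-wide expression summaries."""

    gene: str
    pct_expressing: dict[str, float]  # per zone
    total_expression: float
    mean_per_total_cell: float
    mean_per_expressing_cell: float
    empty_zones: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pct_expressing": [self.pct_expressing[zname] for zname in ZONES]},
            index=pd.Index(ZONES, name="zone"),
        )
        df["total_expression"] = self.total_expression
        df["mean_per_total_cell"] = self.mean_per_total_cell
        df["mean_per_expressing_cell"] = self.mean_per_expressing_cell
        return df


def zonal_dot_count(z: ZScoreMatrix, zones: ZonalScores, gene: str) -> ZonalDotCountTable:
    """Tally every cell into its (zone, expression-category) compartment."""
    if list(z.barcodes) != list(zones.barcodes):
        raise ConsistencyError("z-score matrix and zonal scores have different barcodes")
    gi = z.gene_index(gene)
    dropout = z.dropout[gi]
    gz = z.z[gi]
    # expressing cells at exactly the mean (z == 0) tally as above-mean
    category = np.where(dropout, 0, np.where(gz < 0, 1, 2))
    grid = np.zeros((3, 3), dtype=int)
    for zi, zname in enumerate(ZONES):
        in_zone = zones.zone == zname
        for ci in range(3):
            grid[zi, ci] = int(np.sum(in_zone & (category == ci)))
    return ZonalDotCountTable(gene=z.genes[gi], grid=grid, n_cells=z.n_cells)


def zonal_dot_percentage(
    count_table: ZonalDotCountTable, norm: NormalizedMatrix
) -> ZonalDotPercentageTable:
    """Derive the percentage table from a count table and the normalized matrix."""
    if count_table.n_cells != norm.n_cells:
        raise ConsistencyError("count table and matrix disagree on cell count")
    values = norm.gene_values(count_table.gene)
    zone_sizes = count_table.grid.sum(axis=1)
    expressing = count_table.grid[:, 1] + count_table.grid[:, 2]
    pct: dict[str, float] = {}
    empty: list[str] = []
    for zi, zname in enumerate(ZONES):
        if zone_sizes[zi] == 0:
            pct[zname] = 0.0
            empty.append(zname)
        else:
            pct[zname] = 100.0 * expressing[zi] / zone_sizes[zi]
    total = float(values.sum())
    n_expressing = int(expressing.sum())
    return ZonalDotPercentageTable(
        gene=count_table.gene,
        pct_expressing=pct,
        total_expression=total,
        mean_per_total_cell=total / count_table.n_cells,
        mean_per_expressing_cell=total / n_expressing if n_expressing else 0.0,
        empty_zones=empty,
    )


def cluster_enrichment(selection: CellSelection, zones: ZonalScores) -> pd.DataFrame:
    """Zonal composition of a selection relative to the whole population.

    Per zone: fraction of the selection in the zone, fraction of all cells in
    the zone, and their ratio (> 1 means the selection is enriched there). The
    ratio is NaN for a zone containing no cells at all.
    """
    if len(selection) == 0:
        raise ParameterError("selection is empty")
    index = {b: i for i, b in enumerate(zones.barcodes)}
    missing = [b for b in selection.barcodes if b not in index]
    if missing:
        raise ConsistencyError(f"selection barcodes not in dataset: {missing[:5]}")
    sel_zone = np.array([zones.zone[index[b]] for b in selection.barcodes])
    n, k = zones.n_cells, len(selection)
    rows = []
    for zname in ZONES:
        sel_frac = float(np.sum(sel_zone == zname)) / k
        pop_frac = float(np.sum(zones.zone == zname)) / n
        rows.append(
            {
                "selection_fraction": sel_frac,
                "population_fraction": pop_frac,
                "enrichment_ratio": sel_frac / pop_frac if pop_frac > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(ZONES, name="zone"))
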