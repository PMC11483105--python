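"""The zonal scatter ("Z-Z plot"): per-cell coordinates, guide lines, overlays.

Each cell is one point: X is the chosen gene's z-score (dropouts sit on the
Y-axis at x = 0), Y is the cell's zonal score. Two horizontal lines at +/- tau
separate the three zones; two vertical lines mark the gene's mean normalized
intensity with dropouts (at x = 0 under the all-cells z convention) and
without dropouts (at the z-position of the expressing-cell mean). Superficial
cells are drawn red, middle gray, deep blue; an overlay replaces the zone
colors of expressing cells with a diverging heat scale of a second gene's
z-score.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConsistencyError, ParameterError
from .preprocess import ZScoreMatrix, expression_summaries
from .zonal import ZONES, ZonalScores

ZONE_COLORS = {"superficial": "#d62728", "middle": "#7f7f7f", "deep": "#1f77b4"}

__all__ = ["ZZPlotData", "CellSelection", "build_zzplot", "overlay_coexpression", "select_cells", "render"]


@dataclass
class ZZPlotData:
    """Serializable specification of one zonal scatter."""

    gene: str
    records: pd.DataFrame  # barcode, x, y, dropout, zone, color_value
    hlines: tuple[float, float]  # (+tau, -tau)
    vlines: list[dict]  # {"x": position, "annotation": mean intensity}
    mode: str = "single"
    overlay_genes: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.records)


@dataclass
class CellSelection:
    """Barcodes picked from a plot plus the criteria that produced them."""

    barcodes: list[str]
    criteria: dict

    def __len__(self) -> int:
        return len(self.barcodes)

    def save(self, path: str | Path) -> None:
        """Write a single-column barcode TSV plus a JSON criteria sidecar."""
        path = Path(path)
        path.write_text("".join(b + "\n" for b in self.barcodes))
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.criteria, indent=2, sort_keys=True, default=str) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CellSelection":
        path = Path(path)
        barcodes = [b for b in path.read_text().splitlines() if b]
        sidecar = path.with_suffix(path.suffix + ".json")
        criteria = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(barcodes=barcodes, criteria=criteria)


def build_zzplot(z: ZScoreMatrix, zones: ZonalScores, gene: str) -> ZZPlotData:
    """Assemble the plot data for one gene.

    Expressing cells sit at (gene z-score, zonal score); dropouts are flagged
    and placed at x = 0. The vertical guide lines are annotated with the mean
    normalized intensities from :func:`expression_summaries`.
    """
    if list(z.barcodes) != list(zones.barcodes):
        raise ConsistencyError("z-score matrix and zonal scores have different barcodes")
    gi = z.gene_index(gene)
    summ = expression_summaries(z, gene)
    dropout = z.dropout[gi]
    x = np.where(dropout, 0.0, z.z[gi])
    records = pd.DataFrame(
        {
            "barcode": z.barcodes,
            "x": x,
            "y": zones.zc,
            "dropout": dropout,
            "zone": zones.zone,
            "color_value": np.nan,
        }
    )
    sd = z.sd[gi]
    x_right = (summ["mean_without_dropouts"] - summ["mean_with_dropouts"]) / sd if sd > 0 else 0.0
    vlines = [
        {"x": 0.0, "annotation": summ["mean_with_dropouts"]},
        {"x": float(x_right), "annotation": summ["mean_without_dropouts"]},
    ]
    return ZZPlotData(
        gene=z.genes[gi],
        records=records,
        hlines=(zones.tau, -zones.tau),
        vlines=vlines,
    )


def overlay_coexpression(plot: ZZPlotData, z: ZScoreMatrix, second_gene: str) -> ZZPlotData:
    """Color the primary gene's expressing cells by a second gene's z-score."""
    if plot.mode != "single":
        raise ParameterError("overlay requires a plot in single mode")
    gi = z.gene_index(second_gene)
    records = plot.records.copy()
    expressing = ~records["dropout"].to_numpy()
    color = np.full(len(records), np.nan)
    color[expressing] = z.z[gi][expressing]
    records["color_value"] = color
    return ZZPlotData(
        gene=plot.gene,
        records=records,
        hlines=plot.hlines,
        vlines=plot.vlines,
        mode="overlay",
        overlay_genes=[z.genes[gi]],
    )


def select_cells(
    plot: ZZPlotData,
    *,
    zones: set[str] | list[str] | None = None,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    exclude_dropouts: bool = False,
    gene_thresholds: dict[str, float] | None = None,
    z: ZScoreMatrix | None = None,
) -> CellSelection:
    """Select barcodes satisfying ALL given criteria (conjunction).

    ``gene_thresholds`` maps gene symbols to minimum z-scores (strict >) and
    requires the z-score matrix; the conventional "strong expression" cut is
    z > 1. At least one criterion must be supplied.
    """
    criteria_given = any(
        c is not None and c is not False
        for c in (zones, x_range, y_range, gene_thresholds)
    ) or exclude_dropouts
    if not criteria_given:
        raise ParameterError("select_cells needs at least one criterion")

    rec = plot.records
    mask = np.ones(len(rec), dtype=bool)
    if zones is not None:
        bad = set(zones) - set(ZONES)
        if bad:
            raise ParameterError(f"unknown zone labels: {sorted(bad)}")
        mask &= rec["zone"].isin(set(zones)).to_numpy()
    if x_range is not None:
        lo, hi = x_range
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ParameterError("x_range bounds must be finite")
        mask &= (rec["x"].to_numpy() >= lo) & (rec["x"].to_numpy() <= hi)
    if y_range is not None:
        lo, hi = y_range
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ParameterError("y_range bounds must be finite")
        mask &= (rec["y"].to_numpy() >= lo) & (rec["y"].to_numpy() <= hi)
    if exclude_dropouts:
        mask &= ~rec["dropout"].to_numpy()
    if gene_thresholds:
        if z is None:
            raise ParameterError("gene_thresholds requires the z-score matrix")
        if list(rec["barcode"]) != list(z.barcodes):
            raise ConsistencyError("plot and z-score matrix have different barcodes")
        for gene, thr in gene_thresholds.items():
            if not np.isfinite(thr):
                raise ParameterError(f"threshold for {gene} must be finite")
            mask &= z.gene_z(gene) > thr

    criteria = {
        "plot_gene": plot.gene,
        "zones": sorted(zones) if zones is not None else None,
        "x_range": list(x_range) if x_range is not None else None,
        "y_range": list(y_range) if y_range is not None else None,
        "exclude_dropouts": exclude_dropouts,
        "gene_thresholds": {g.upper(): t for g, t in (gene_thresholds or {}).items()} or None,
    }
    return CellSelection(barcodes=list(rec["barcode"][mask]), criteria=criteria)


def _draw(plot: ZZPlotData):
    """Build the matplotlib figure for a plot specification."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    rec = plot.records
    expressing = ~rec["dropout"].to_numpy()
    # dropout lane on the Y-axis; jitter is cosmetic and render-only
    jitter = np.random.default_rng(0).uniform(-0.02, 0.02, int((~expressing).sum()))
    ax.scatter(
        rec["x"][~expressing] + jitter,
        rec["y"][~expressing],
        s=6,
        c="#bbbbbb",
        linewidths=0,
    )
    if plot.mode == "overlay":
        color = np.clip(rec["color_value"][expressing], -3, 3)
        sc = ax.scatter(
            rec["x"][expressing],
            rec["y"][expressing],
            s=8,
            c=color,
            cmap="RdBu_r",
            vmin=-3,
            vmax=3,
            linewidths=0,
        )
        fig.colorbar(sc, ax=ax, label=f"{plot.overlay_genes[0]} z-score")
    else:
        colors = rec["zone"][expressing].map(ZONE_COLORS)
        ax.scatter(rec["x"][expressing], rec["y"][expressing], s=8, c=colors, linewidths=0)
    for yline in plot.hlines:
        ax.axhline(yline, color="black", linestyle="--", linewidth=0.8)
    for vline in plot.vlines:
        ax.axvline(vline["x"], color="green", linestyle=":", linewidth=0.8)
        ax.annotate(
            f"{vline['annotation']:.4g}",
            (vline["x"], ax.get_ylim()[1]),
            fontsize=8,
            ha="left",
            va="top",
        )
    ax.set_xlabel(plot.gene)
    ax.set_ylabel("zonal score")
    # text legend keeps every SVG marker a cell (no proxy marker artists)
    for i, zname in enumerate(ZONES):
        fig.text(0.13 + 0.18 * i, 0.955, zname, color=ZONE_COLORS[zname], fontsize=9)
    return fig


def _fig_svg(plot: ZZPlotData) -> str:
    """Render to an SVG string; byte-deterministic for identical plot data."""
    import io as _io

    import matplotlib
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "zonalspace"}):
        fig = _draw(plot)
        buf = _io.StringIO()
        fig.savefig(buf, format="svg", metadata={"Date": None})
        plt.close(fig)
    return buf.getvalue()


def render(plot: ZZPlotData, path: str | Path, format: str = "svg") -> None:
    """Write the plot to ``path`` as svg, png or a standalone html page.

    SVG output is byte-deterministic for identical plot data. The HTML format
    embeds the SVG in a minimal static page titled with the gene symbol.
    """
    path = Path(path)
    if format == "svg":
        path.write_text(_fig_svg(plot))
    elif format == "png":
        import matplotlib.pyplot as plt

        fig = _draw(plot)
        fig.savefig(path, format="png", dpi=150)
        plt.close(fig)
    elif format == "html":
        body = _fig_svg(plot)
        page = (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            f"<title>{html.escape(plot.gene)} zonal scatter</title></head>\n"
            f"<body>\n{body}\n</body></html>\n"
        )
        path.write_text(page)
    else:
        raise ParameterError(f"unsupported render format: {format!r}")
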