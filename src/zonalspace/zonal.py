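"""Per-cell zonal score and superficial/middle/deep zone assignment.

The zonal score of a cell is the weighted mean z-score of the superficial
markers minus the weighted mean z-score of the deep markers:

    Z_c = sum_{g in S} w_g E_{g,c} / sum_{g in S} w_g
        - sum_{g in D} w_g E_{g,c} / sum_{g in D} w_g

With unit weights (the default) this is the plain difference of marker-list
means. Positive scores indicate superficial-like cells, negative deep-like.
Zone labels come from a symmetric threshold tau around zero: superficial if
Z_c > tau, deep if Z_c < -tau, middle otherwise (boundary ties go to middle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, ParameterError
from .io_formats import ZMGSet
from .preprocess import ZScoreMatrix

logger = logging.getLogger(__name__)

ZONES = ("superficial", "middle", "deep")

__all__ = ["ZonalScores", "ZONES", "match_zmg", "zonal_score", "assign_zones", "zone_composition"]


@dataclass
class ZonalScores:
    """Per-cell zonal scores, zone labels and the boundary threshold tau."""

    barcodes: list[str]
    zc: np.ndarray
    zone: np.ndarray  # str labels from ZONES
    tau: float
    zmg_used: ZMGSet

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zonal_score": self.zc, "zone": self.zone},
            index=pd.Index(self.barcodes, name="barcode"),
        )


def match_zmg(zmg: ZMGSet, genes: list[str]) -> ZMGSet:
    """Drop marker genes absent from the matrix, warning per dropped symbol.

    The divisors in the zonal score are the *effective* list sizes, so an
    absent marker shrinks its list rather than entering as a silent zero.
    An emptied list is an error.
    """
    present = set(genes)
    sup = [g for g in zmg.superficial if g in present]
    deep = [g for g in zmg.deep if g in present]
    for g in set(zmg.superficial) - set(sup) | set(zmg.deep) - set(deep):
        logger.warning("marker gene %s absent from matrix; dropped from its list", g)
    if not sup:
        raise ConfigError("no superficial marker gene is present in the matrix")
    if not deep:
        raise ConfigError("no deep marker gene is present in the matrix")
    return ZMGSet(superficial=sup, deep=deep, weights=dict(zmg.weights))


def zonal_score(z: ZScoreMatrix, zmg: ZMGSet) -> np.ndarray:
    """Weighted mean-difference zonal score per cell.

    Markers absent from the matrix are dropped (with a warning) before the
    means are taken; NaN z-scores in a marker row are rejected.
    """
    eff = match_zmg(zmg, z.genes)

    def side(genes: list[str]) -> np.ndarray:
        idx = [z.gene_index(g) for g in genes]
        w = np.array([eff.weight(g) for g in genes])
        sub = z.z[idx, :]
        if np.isnan(sub).any():
            raise ParameterError("NaN z-score in a marker gene row")
        return (w[:, None] * sub).sum(axis=0) / w.sum()

    return side(eff.superficial) - side(eff.deep)


def assign_zones(
    zc: np.ndarray,
    tau: float | None = None,
    *,
    barcodes: list[str] | None = None,
    zmg_used: ZMGSet | None = None,
) -> ZonalScores:
    """Label each cell by thresholding its zonal score at +/- tau.

    When ``tau`` is None it defaults to half the population standard deviation
    of the scores, keeping the middle band symmetric about zero and scaled to
    the signature's spread. An explicit tau must be positive.
    """
    zc = np.asarray(zc, dtype=float)
    if tau is None:
        tau = 0.5 * float(zc.std(ddof=0))
        if tau == 0.0:
            raise ParameterError(
                "zonal scores are constant; relative tau is undefined - pass an absolute tau"
            )
    if not tau > 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    zone = np.full(zc.shape, "middle", dtype=object)
    zone[zc > tau] = "superficial"
    zone[zc < -tau] = "deep"
    if barcodes is None:
        barcodes = [f"cell{i}" for i in range(len(zc))]
    return ZonalScores(
        barcodes=list(barcodes),
        zc=zc,
        zone=zone.astype(str),
        tau=float(tau),
        zmg_used=zmg_used,
    )


def zone_composition(zones: ZonalScores) -> pd.DataFrame:
    """Cell counts and fractions per zone (rows ordered superficial, middle, deep)."""
    n = zones.n_cells
    counts = {zname: int((zones.zone == zname).sum()) for zname in ZONES}
    return pd.DataFrame(
        {
            "n_cells": [counts[zname] for zname in ZONES],
            "fraction": [counts[zname] / n if n else 0.0 for zname in ZONES],
        },
        index=pd.Index(ZONES, name="zone"),
    )
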