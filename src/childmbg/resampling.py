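"""Polygon-to-point resampling of bin-table rows.

Survey data located only to an administrative polygon are converted into
population-weighted point pseudo-observations on the pixel grid: up to ``k``
pixels are chosen inside the polygon by systematic population-proportional
sampling, the polygon's exposures and deaths are split across them in
proportion to pixel population, and totals are conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from childmbg.birth_histories import BINTABLE_COLUMNS, validate_bintable

logger = logging.getLogger(__name__)


@dataclass
class IntegrationPoints:
    """Per-polygon pixel locations and weights (weights sum to 1 per polygon)."""

    points: dict[int, pd.DataFrame]  # polygon id -> frame(row, col, weight)

    def __contains__(self, pid: int) -> bool:
        return pid in self.points

    def __getitem__(self, pid: int) -> pd.DataFrame:
        return self.points[pid]


def build_integration_points(
    labels: np.ndarray,
    population: np.ndarray,
    polygon_ids=None,
    k: int = 100,
    seed: int = 0,
) -> IntegrationPoints:
    """Select up to ``k`` population-weighted integration pixels per polygon.

    ``labels`` is a raster of polygon ids; pixels of each polygon are sampled
    without replacement by systematic probability-proportional-to-size
    sampling on pixel population (deterministic given ``seed``), and the
    selected pixels are weighted proportionally to their population. If a
    polygon has zero total population, uniform area weights over its pixels
    are used instead (logged).
    """
    if labels.shape != population.shape:
        raise ValueError("labels and population rasters must share a grid")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[int, pd.DataFrame] = {}
    ids = np.unique(labels) if polygon_ids is None else polygon_ids
    for pid in ids:
        rr, cc = np.where(labels == pid)
        if rr.size == 0:
            raise ValueError(f"polygon {pid} covers no pixels")
        pop = population[rr, cc].astype(float)
        if pop.sum() <= 0:
            logger.warning("polygon %s has zero population; falling back to area weights", pid)
            pop = np.ones_like(pop)
        if rr.size <= k:
            sel = np.arange(rr.size)
        else:
            # systematic PPS: equally spaced points on the cumulative population
            cum = np.cumsum(pop)
            step = cum[-1] / k
            targets = (rng.random() + np.arange(k)) * step
            sel = np.unique(np.searchsorted(cum, targets, side="left"))
        w = pop[sel] / pop[sel].sum()
        out[int(pid)] = pd.DataFrame({"row": rr[sel], "col": cc[sel], "weight": w})
    return IntegrationPoints(points=out)


def resample_bintable(bt: pd.DataFrame, ip: IntegrationPoints) -> pd.DataFrame:
    """Split polygon-referenced bin-table rows over their integration points.

    Point rows pass through unchanged. Each polygon row is replaced by one
    row per integration point with exposures and deaths multiplied by the
    point weight; totals are conserved to floating-point exactness.
    """
    validate_bintable(bt)
    is_poly = bt["loc_type"] == "polygon"
    missing = sorted(set(bt.loc[is_poly, "loc_id"].astype(int)) - set(ip.points))
    if missing:
        raise KeyError(f"no integration points for polygon ids: {missing}")
    keep = bt[~is_poly]
    parts = [keep] if len(keep) else []
    for pid, rows in bt[is_poly].groupby("loc_id"):
        pts = ip[int(pid)]
        for j, (_, pt) in enumerate(pts.iterrows()):
            split = rows.copy()
            split["loc_type"] = "point"
            split["loc_id"] = f"poly{int(pid)}_pt{j}"
            split["row"] = int(pt["row"])
            split["col"] = int(pt["col"])
            split["exposure"] = rows["exposure"].to_numpy() * pt["weight"]
            split["deaths"] = rows["deaths"].to_numpy() * pt["weight"]
            parts.append(split)
    out = pd.concat(parts, ignore_index=True) if parts else bt.iloc[0:0].copy()
    return validate_bintable(out[BINTABLE_COLUMNS])
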