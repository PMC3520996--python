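"""Fishery-relevant products of the abundance projections.

Potential fishing grounds are grid cells whose predicted abundance meets
a minimum density — default 20 individuals per 100 m², the density
needed to sustain recruitment under harvest.  Present-day and future
ground maps are combined into a four-way change classification
(retained / gained / lost / never), summarized as a percent change in
harvestable abundance, and overlaid with March (late-summer) SST
categories (<17 °C, 17–20 °C, ≥20 °C) to flag projected expansion that
warm-season thermal stress would likely prevent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid, regrid_check
from .synthetic import SurveySet

__all__ = [
    "FishingGroundMap",
    "OverlayReport",
    "delineate_grounds",
    "classify_change",
    "percent_change_above_threshold",
    "march_overlay",
    "density_by_temperature_bins",
    "GROUND_THRESHOLD",
    "MARCH_BIN_EDGES",
    "CATEGORY_CODES",
]

#: minimum harvestable density, individuals per 100 m²
GROUND_THRESHOLD = 20.0
#: March SST category boundaries, °C; 17 °C falls in the middle bin
MARCH_BIN_EDGES = (17.0, 20.0)
#: integer codes of the change classes as written to categorical rasters
CATEGORY_CODES = {"never": 0, "lost": 1, "gained": 2, "retained": 3}


@dataclass
class FishingGroundMap:
    """Four-way change classification of potential fishing grounds."""

    categories: RasterGrid        # integer codes per CATEGORY_CODES, NaN on land
    threshold: float
    decade: int | None = None
    scenario: str | None = None
    species: str | None = None

    def counts(self) -> pd.Series:
        """Sea-cell count per change class; sums to the sea-cell total."""
        vals = self.categories.sea_values().astype(int)
        return pd.Series(
            {name: int(np.sum(vals == code)) for name, code in CATEGORY_CODES.items()}
        )


@dataclass
class OverlayReport:
    """Fractions of each region's sea cells per March-SST category.

    ``fractions`` is indexed by region with columns ``below_17``,
    ``17_to_20``, ``at_or_above_20``; each row sums to 1.
    """

    fractions: pd.DataFrame
    bin_edges: tuple[float, float] = MARCH_BIN_EDGES
    decade: int | None = None
    scenario: str | None = None


def delineate_grounds(abundance: RasterGrid, threshold: float = GROUND_THRESHOLD) -> RasterGrid:
    """Boolean grid of potential fishing grounds.

    A cell qualifies iff it is sea and its abundance is at or above the
    threshold (the comparison is inclusive).
    """
    ok = abundance.mask & (abundance.values >= threshold)
    values = np.where(abundance.mask, ok.astype(float), np.nan)
    return RasterGrid(values=values, geometry=abundance.geometry,
                      mask=abundance.mask.copy(), variable="fishing_ground")


def classify_change(
    current_grounds: RasterGrid,
    future_grounds: RasterGrid,
    threshold: float = GROUND_THRESHOLD,
    **labels,
) -> FishingGroundMap:
    """Classify each sea cell as retained, gained, lost or never.

    retained = ground now and in future; gained = future only;
    lost = current only; never = neither.  The classes partition the
    sea mask exactly.
    """
    if not regrid_check(current_grounds, future_grounds):
        raise ValueError("current and future ground grids must share geometry")
    cur = current_grounds.values == 1.0
    fut = future_grounds.values == 1.0
    mask = current_grounds.mask & future_grounds.mask
    codes = np.full(cur.shape, np.nan)
    codes[mask & cur & fut] = CATEGORY_CODES["retained"]
    codes[mask & cur & ~fut] = CATEGORY_CODES["lost"]
    codes[mask & ~cur & fut] = CATEGORY_CODES["gained"]
    codes[mask & ~cur & ~fut] = CATEGORY_CODES["never"]
    grid = RasterGrid(values=codes, geometry=current_grounds.geometry, mask=mask,
                      variable="ground_change")
    return FishingGroundMap(categories=grid, threshold=threshold, **labels)


def percent_change_above_threshold(
    current: RasterGrid,
    future: RasterGrid,
    threshold: float = GROUND_THRESHOLD,
) -> float:
    """Percent change in harvestable abundance between two projections.

    Harvestable abundance is the sum of abundance over cells at or above
    the threshold, each epoch using its own cells.  Undefined (raises)
    when the current harvestable abundance is zero.
    """
    if not regrid_check(current, future):
        raise ValueError("grids must share geometry")
    cur_mask = current.mask & (current.values >= threshold)
    fut_mask = future.mask & (future.values >= threshold)
    cur_total = float(np.sum(current.values[cur_mask])) if cur_mask.any() else 0.0
    fut_total = float(np.sum(future.values[fut_mask])) if fut_mask.any() else 0.0
    if cur_total == 0.0:
        raise ValueError(
            "percent change undefined: zero current harvestable abundance"
        )
    return 100.0 * (fut_total - cur_total) / cur_total


def march_overlay(
    march_sst: RasterGrid,
    regions: dict[str, np.ndarray],
    bin_edges: tuple[float, float] = MARCH_BIN_EDGES,
    area_weighted: bool = False,
    **labels,
) -> OverlayReport:
    """Fractions of each region in the March-SST thermal categories.

    ``regions`` maps region names (e.g. "study_area",
    "current_distribution", "expansion") to boolean masks on the March
    grid's geometry.  Bins are ``< lo``, ``[lo, hi)`` and ``>= hi``
    (default 17/20 °C).  With ``area_weighted`` cells are weighted by
    the cosine of their latitude instead of counted equally.
    """
    lo, hi = bin_edges
    rows = {}
    lat2d = march_sst.geometry.meshgrid()[1]
    for name, region in regions.items():
        sel = region & march_sst.mask
        if not sel.any():
            raise ValueError(f"region {name!r} contains no valid sea cells")
        t = march_sst.values[sel]
        w = np.cos(np.deg2rad(lat2d[sel])) if area_weighted else np.ones(t.size)
        total = w.sum()
        rows[name] = {
            "below_17": float(w[t < lo].sum() / total),
            "17_to_20": float(w[(t >= lo) & (t < hi)].sum() / total),
            "at_or_above_20": float(w[t >= hi].sum() / total),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return OverlayReport(fractions=df, bin_edges=bin_edges, **labels)


def density_by_temperature_bins(
    surveys: SurveySet,
    march_sst: RasterGrid,
    bin_edges: list[float] | None = None,
) -> pd.DataFrame:
    """Five-number summaries of survey density per March-SST bin.

    Each survey record is assigned the March SST of its grid cell; bins
    are left-closed right-open except the last, which is closed.
    Quartiles use linear interpolation (the type-7 rule).  Empty bins
    are reported with ``n = 0`` and NaN statistics.
    """
    if bin_edges is None:
        bin_edges = [march_sst.sea_values().min(), *MARCH_BIN_EDGES,
                     march_sst.sea_values().max() + 1e-9]
    g = march_sst.geometry
    df = surveys.records
    ci = np.rint((df["lon"].to_numpy() - g.lon_origin) / g.resolution).astype(int)
    ri = np.rint((df["lat"].to_numpy() - g.lat_origin) / g.resolution).astype(int)
    in_grid = (ri >= 0) & (ri < g.n_lat) & (ci >= 0) & (ci < g.n_lon)
    if not in_grid.all():
        raise ValueError("some survey records fall outside the March SST grid")
    march = march_sst.values[ri, ci]
    if not np.isfinite(march).all():
        raise ValueError("some survey records have no March SST value")
    counts = df["count_per_100m2"].to_numpy(dtype=float)
    rows = []
    edges = list(bin_edges)
    for i in range(len(edges) - 1):
        last = i == len(edges) - 2
        sel = (march >= edges[i]) & ((march <= edges[i + 1]) if last
                                     else (march < edges[i + 1]))
        d = counts[sel]
        row = {"bin_left": edges[i], "bin_right": edges[i + 1], "n": int(d.size)}
        if d.size:
            q = np.quantile(d, [0.0, 0.25, 0.5, 0.75, 1.0])
            row.update(min=q[0], q1=q[1], median=q[2], q3=q[3], max=q[4])
        else:
            row.update(min=np.nan, q1=np.nan, median=np.nan, q3=np.nan, max=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
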