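"""Range dynamics: thresholding, habitat geometry, and dispersal scenarios.

The analysis unit is the species' bioclimatic area of habitat (BAH): the
minimum convex polygon (MCP) of its cleaned records buffered by 100 km,
inside which suitable pixels are counted. Continuous suitability is
binarised at the maximum-training-sensitivity-plus-specificity (maxSSS)
threshold, future climate members are averaged into a consensus before
binarisation, and range change is the percent change in suitable pixel
counts between current and future under two bookkeeping rules:

* non-dispersal — the species cannot reach new pixels; future occupancy is
  the intersection of currently and future-suitable pixels (never a gain);
* full dispersal — the species may occupy any future-suitable pixel inside
  its BAH.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from .geometry import AzimuthalEqualArea
from .grids import GridSpec
from .occurrences import OccurrenceSet

DEFAULT_BUFFER_KM = 100.0


@dataclass
class SuitabilityMap:
    grid: GridSpec
    values: np.ndarray  # (n_rows, n_cols) in [0,1], NaN at nodata
    mask: np.ndarray    # True = valid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class BinaryRangeMap:
    grid: GridSpec
    suitable: np.ndarray  # bool
    mask: np.ndarray      # True = valid
    threshold_used: float
    scenario_label: str = "current"
    period_label: str = "current"
    dispersal_label: str = ""


@dataclass
class BAHGeometry:
    """MCP + buffer in geographic coordinates, with its equal-area twin."""

    mcp: shapely.Geometry
    buffered: shapely.Geometry
    buffer_km: float
    area_km2: float        # buffered area (the analysis mask)
    mcp_area_km2: float
    projection: AzimuthalEqualArea = field(repr=False)
    mcp_proj: shapely.Geometry = field(repr=False, default=None)
    buffered_proj: shapely.Geometry = field(repr=False, default=None)


@dataclass
class RangeChangeRecord:
    species_id: str
    scenario_label: str
    period_label: str
    dispersal: str
    current_cells: int
    future_cells: int
    change_percent: float


def max_sss_threshold(presence_scores: np.ndarray,
                      background_scores: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity over observed scores.

    A cell is suitable when its score is >= the threshold; sensitivity is the
    presence fraction classified suitable and specificity the background
    fraction classified unsuitable. Candidates are the observed scores; ties
    resolve to the smallest candidate attaining the maximum.
    """
    pres = np.sort(np.asarray(presence_scores, dtype=float).ravel())
    bg = np.sort(np.asarray(background_scores, dtype=float).ravel())
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([pres, bg]))
    sens = (pres.size - np.searchsorted(pres, cand, side="left")) / pres.size
    spec = np.searchsorted(bg, cand, side="left") / bg.size
    total = sens + spec
    return float(cand[np.argmax(total)])  # argmax returns the first (smallest)


def binarize(smap: SuitabilityMap, threshold: float,
             scenario_label: str = "current",
             period_label: str = "current") -> BinaryRangeMap:
    """Suitable iff suitability >= threshold; nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    suitable = np.where(smap.mask, smap.values >= threshold, False)
    return BinaryRangeMap(smap.grid, suitable, smap.mask.copy(), threshold,
                          scenario_label, period_label)


def ensemble_mean(member_maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Cell-wise mean of co-registered members; nodata if any member nodata."""
    if not member_maps:
        raise ValueError("empty member list")
    grid = member_maps[0].grid
    mask = np.logical_and.reduce([m.mask for m in member_maps])
    stackv = np.stack([m.values for m in member_maps])
    with np.errstate(invalid="ignore"):
        mean = np.where(mask, np.nanmean(stackv, axis=0), np.nan)
    return SuitabilityMap(grid, mean, mask)


def build_bah(occ: OccurrenceSet, buffer_km: float = DEFAULT_BUFFER_KM) -> BAHGeometry:
    """Convex hull of kept records, buffered in an equal-area projection.

    The projection is azimuthal equal-area centred on the records' centroid
    (spherical earth, R = 6371 km); degenerate hulls (2 records or collinear
    sets) buffer to a capsule/disc. Areas are computed in the projection.
    """
    lonlat = occ.kept_lonlat()
    if lonlat.shape[0] < 2:
        raise ValueError("need at least 2 records to build a BAH")
    proj = AzimuthalEqualArea(lonlat[:, 0].mean(), lonlat[:, 1].mean())
    x, y = proj.forward(lonlat[:, 0], lonlat[:, 1])
    mcp_proj = MultiPoint(np.column_stack([x, y])).convex_hull
    buffered_proj = mcp_proj.buffer(buffer_km) if buffer_km > 0 else mcp_proj
    return BAHGeometry(
        mcp=proj.unproject_geometry(mcp_proj),
        buffered=proj.unproject_geometry(buffered_proj),
        buffer_km=float(buffer_km),
        area_km2=float(buffered_proj.area),
        mcp_area_km2=float(mcp_proj.area),
        projection=proj,
        mcp_proj=mcp_proj,
        buffered_proj=buffered_proj,
    )


def bah_cell_mask(grid: GridSpec, bah: BAHGeometry,
                  geometry: str = "buffered") -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the BAH polygon
    (boundary included)."""
    lon, lat = grid.cell_centers()
    x, y = bah.projection.forward(lon.ravel(), lat.ravel())
    poly = bah.buffered_proj if geometry == "buffered" else bah.mcp_proj
    pts = shapely.points(np.column_stack([x, y]))
    inside = shapely.covers(poly, pts)
    return inside.reshape(grid.shape)


def range_change(current: BinaryRangeMap, future: BinaryRangeMap,
                 bah: BAHGeometry, dispersal: str,
                 species_id: str = "", nd_rule: str = "intersection"
                 ) -> RangeChangeRecord:
    """Percent change in suitable pixels inside the BAH under a dispersal rule.

    ``nd_rule='intersection'`` is the literal no-new-pixels rule (future
    occupancy = future AND current). ``nd_rule='clip-mcp'`` instead clips
    future suitability to the unbuffered MCP, which can produce small gains.
    """
    if current.grid != future.grid:
        raise ValueError("maps are not co-registered")
    in_bah = bah_cell_mask(current.grid, bah) & current.mask & future.mask
    cur = current.suitable & in_bah
    n_cur = int(cur.sum())
    if n_cur == 0:
        raise ValueError("empty current range inside the BAH")
    if dispersal == "non-dispersal":
        if nd_rule == "intersection":
            fut = future.suitable & cur
        elif nd_rule == "clip-mcp":
            fut = future.suitable & bah_cell_mask(current.grid, bah, "mcp") \
                  & current.mask & future.mask
        else:
            raise ValueError(f"unknown nd_rule {nd_rule!r}")
    elif dispersal == "full-dispersal":
        fut = future.suitable & in_bah
    else:
        raise ValueError(f"unknown dispersal label {dispersal!r}")
    n_fut = int(fut.sum())
    change = 100.0 * (n_fut - n_cur) / n_cur
    return RangeChangeRecord(species_id=species_id,
                             scenario_label=future.scenario_label,
                             period_label=future.period_label,
                             dispersal=dispersal,
                             current_cells=n_cur, future_cells=n_fut,
                             change_percent=change)


def stack_richness_change(per_species: list[tuple[BinaryRangeMap, BinaryRangeMap]]
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell species counts of loss (suitable now, not in future) and gain."""
    if not per_species:
        raise ValueError("empty species list")
    grid = per_species[0][0].grid
    loss = np.zeros(grid.shape, dtype=int)
    gain = np.zeros(grid.shape, dtype=int)
    for cur, fut in per_species:
        if cur.grid != grid or fut.grid != grid:
            raise ValueError("maps are not co-registered")
        loss += (cur.suitable & ~fut.suitable).astype(int)
        gain += (~cur.suitable & fut.suitable).astype(int)
    return loss, gain
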