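"""Occurrence-record cleaning for presence-only distribution modelling.

Raw aggregated occurrence data (GBIF-style) carries georeferencing errors,
duplicates and spatial sampling bias. The pipeline applied here, in fixed
order, is:

1. rectangular extent filter (default: eastern South America,
   latitudes 60S-15N, longitudes 90W-30W);
2. invalid-coordinate and duplicate removal ((0,0) treated as invalid, a
   common GBIF artefact; configurable);
3. kernel-density spatial-outlier removal (2-D Gaussian KDE, per-axis Scott
   bandwidth, drop the lowest-density quantile);
4. spatial thinning to a minimum nearest-neighbour great-circle distance
   (default 20 km) to reduce sampling-bias autocorrelation;

followed by a minimum-sample-size gate (default 10 records) below which a
species is not modelled. Records are never deleted: each carries a status
flag (``kept`` or ``dropped:<reason>``), so a cleaning report can account for
every input record.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import pairwise_haversine_km

KEPT = "kept"


@dataclass
class ExtentBox:
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("extent must have min < max on both axes")


#: study extent used for the Brazilian agroforestry species analysis
DEFAULT_EXTENT = ExtentBox(lat_min=-60.0, lat_max=15.0, lon_min=-90.0, lon_max=-30.0)


@dataclass
class OccurrenceSet:
    """A species' occurrence records with per-record provenance flags."""

    species_id: str
    growth_form: str
    records: pd.DataFrame  # columns: decimalLongitude, decimalLatitude, status, ...

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)
        if "status" not in self.records.columns:
            self.records = self.records.assign(status=KEPT)

    @property
    def kept(self) -> pd.DataFrame:
        return self.records[self.records["status"] == KEPT]

    @property
    def n_kept(self) -> int:
        return int((self.records["status"] == KEPT).sum())

    def kept_lonlat(self) -> np.ndarray:
        return self.kept[["decimalLongitude", "decimalLatitude"]].to_numpy(float)

    def with_status(self, drop_idx, reason: str) -> "OccurrenceSet":
        records = self.records.copy()
        records.loc[list(drop_idx), "status"] = f"dropped:{reason}"
        return replace(self, records=records)

    def drop_counts(self) -> dict[str, int]:
        return self.records["status"].value_counts().to_dict()


def read_occurrences_csv(path: str | Path, species_id: str | None = None,
                         growth_form: str = "unknown") -> list[OccurrenceSet]:
    """Read a Darwin-Core-style CSV (species, decimalLongitude, decimalLatitude,
    growthForm) into one OccurrenceSet per species."""
    df = pd.read_csv(path)
    out = []
    for sp, sub in df.groupby("species", sort=True):
        if species_id is not None and sp != species_id:
            continue
        gf = sub["growthForm"].iloc[0] if "growthForm" in sub else growth_form
        recs = sub[["decimalLongitude", "decimalLatitude"]].copy()
        out.append(OccurrenceSet(species_id=str(sp), growth_form=str(gf), records=recs))
    return out


def write_occurrences_csv(path: str | Path, occs: list[OccurrenceSet],
                          kept_only: bool = True) -> None:
    frames = []
    for occ in occs:
        df = occ.kept if kept_only else occ.records
        frames.append(pd.DataFrame({
            "species": occ.species_id,
            "decimalLongitude": df["decimalLongitude"],
            "decimalLatitude": df["decimalLatitude"],
            "growthForm": occ.growth_form,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cleaning_report(path: str | Path, occs: list[OccurrenceSet]) -> None:
    report = {occ.species_id: occ.drop_counts() for occ in occs}
    Path(path).write_text(json.dumps(report, indent=2))


# -- cleaning operations -----------------------------------------------------


def filter_extent(occ: OccurrenceSet, box: ExtentBox = DEFAULT_EXTENT) -> OccurrenceSet:
    """Flag kept records outside the box as dropped:extent (boundary kept)."""
    kept = occ.kept
    lon = pd.to_numeric(kept["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(kept["decimalLatitude"], errors="coerce")
    inside = ((lon >= box.lon_min) & (lon <= box.lon_max)
              & (lat >= box.lat_min) & (lat <= box.lat_max))
    # non-numeric coordinates are left for drop_invalid to classify
    outside = inside.fillna(True) == False  # noqa: E712
    return occ.with_status(kept.index[outside], "extent")


def drop_invalid(occ: OccurrenceSet, zero_zero_invalid: bool = True) -> OccurrenceSet:
    """Flag missing/non-numeric/out-of-range/(0,0) coordinates and collapse
    exact duplicates to a single kept record."""
    kept = occ.kept
    lon = pd.to_numeric(kept["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(kept["decimalLatitude"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    if zero_zero_invalid:
        bad |= (lon == 0) & (lat == 0)
    out = occ.with_status(kept.index[bad], "invalid")

    kept = out.kept
    dup = kept.duplicated(subset=["decimalLongitude", "decimalLatitude"], keep="first")
    return out.with_status(kept.index[dup], "duplicate")


def remove_density_outliers(occ: OccurrenceSet,
                            drop_quantile: float = 0.01) -> OccurrenceSet:
    """Drop the records in the lowest-density tail of a 2-D Gaussian KDE.

    Bandwidth is Scott's rule per axis (h_i = sd_i * n^(-1/6)). The drop count
    is ``floor(drop_quantile * n_kept)``, lowest densities first, ties broken
    by record order. Requires at least 5 kept records (otherwise a warning is
    issued and the set is returned unchanged).
    """
    if not 0.0 <= drop_quantile < 0.5:
        raise ValueError("drop_quantile must be in [0, 0.5)")
    kept = occ.kept
    n = len(kept)
    if n < 5:
        warnings.warn("fewer than 5 records; outlier removal skipped")
        return occ
    k = int(np.floor(drop_quantile * n))
    if k == 0:
        return occ
    xy = kept[["decimalLongitude", "decimalLatitude"]].to_numpy(float)
    sd = xy.std(axis=0, ddof=1)
    h = np.where(sd > 0, sd, 1e-9) * n ** (-1.0 / 6.0)
    diff = (xy[:, None, :] - xy[None, :, :]) / h
    dens = np.exp(-0.5 * (diff ** 2).sum(axis=2)).sum(axis=1)
    order = np.argsort(dens, kind="stable")  # ties broken by record order
    return occ.with_status(kept.index[order[:k]], "outlier")


def thin(occ: OccurrenceSet, min_distance_km: float = 20.0,
         seed: int = 0, n_tries: int = 10) -> OccurrenceSet:
    """Enforce a minimum pairwise great-circle distance between kept records.

    Each try iteratively drops the record with the most neighbours closer
    than ``min_distance_km`` (ties broken uniformly at random), until no two
    kept records conflict, then restores any dropped record that no longer
    conflicts — the randomised max-neighbour heuristic of standard thinning
    tools, which repeat with different tie-break draws and keep the largest
    retained set. All randomness derives from ``seed``.
    """
    if min_distance_km <= 0:
        raise ValueError("min_distance_km must be positive")
    kept = occ.kept
    n = len(kept)
    if n < 2:
        return occ
    rng = np.random.default_rng(seed)
    d = pairwise_haversine_km(kept[["decimalLongitude", "decimalLatitude"]].to_numpy(float))
    conflict = (d < min_distance_km)
    np.fill_diagonal(conflict, False)
    best = None
    for _ in range(max(1, n_tries)):
        alive = np.ones(n, dtype=bool)
        while True:
            deg = (conflict & alive[None, :]).sum(axis=1)
            deg[~alive] = 0
            dmax = deg.max()
            if dmax == 0:
                break
            ties = np.flatnonzero(deg == dmax)
            alive[rng.choice(ties)] = False
        # maximality pass: re-add formerly dropped records that now fit
        for i in np.flatnonzero(~alive):
            if not np.any(conflict[i] & alive):
                alive[i] = True
        if best is None or alive.sum() > best.sum():
            best = alive
    return occ.with_status(kept.index[~best], "thinned")


def passes_min_records(occ: OccurrenceSet, n_min: int = 10) -> bool:
    """True iff the species keeps enough records to be modelled."""
    return occ.n_kept >= n_min


def clean_pipeline(occ: OccurrenceSet, box: ExtentBox = DEFAULT_EXTENT,
                   drop_quantile: float = 0.01, thin_km: float = 20.0,
                   seed: int = 0) -> OccurrenceSet:
    """Extent -> invalid/duplicates -> density outliers -> thinning."""
    occ = filter_extent(occ, box)
    occ = drop_invalid(occ)
    occ = remove_density_outliers(occ, drop_quantile)
    return thin(occ, thin_km, seed)
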