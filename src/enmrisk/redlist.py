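"""Preliminary IUCN Red List categorisation and summary statistics.

Two routes into a threat category are implemented:

* criterion B (geographic range): B1 on the extent of occurrence (EOO, the
  MCP area) and B2 on the area of occupancy (AOO, occupied 2x2 km cells),
  using the standard IUCN thresholds (EOO < 100 / 5,000 / 20,000 km^2 and
  AOO < 10 / 500 / 2,000 km^2 for CR / EN / VU). The accompanying conditions
  (a-c: fragmentation, continuing decline, extreme fluctuation) are not
  computable from occurrence coordinates alone and are supplied as a count;
  a species qualifies only when at least two conditions are met, otherwise
  the category is advisory (NA).

* criterion A3c (projected habitat loss): a species whose bioclimatic area
  of habitat is projected to shrink by >= 30% is Vulnerable, >= 50%
  Endangered, >= 80% Critically Endangered.

The module also reproduces the study-level summary: per scenario/period/
dispersal column, the percentage of species in each category (percentages
are floored to one decimal, matching the convention of the published
numbers), the mean decline under two conventions, the maximum increase and
the count of species losing their entire habitat.

A transcription of the published 135-species range-change table ships as
package data (``data/table1_fixture.csv``), guarded by a checksum.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .geometry import AzimuthalEqualArea
from .occurrences import OccurrenceSet

#: IUCN criterion B thresholds, km^2
EOO_THRESHOLDS = {"CR": 100.0, "EN": 5_000.0, "VU": 20_000.0}
AOO_THRESHOLDS = {"CR": 10.0, "EN": 500.0, "VU": 2_000.0}

#: criterion A3c habitat-loss thresholds, percent
A3C_THRESHOLDS = {"CR": 80.0, "EN": 50.0, "VU": 30.0}

SEVERITY = {"NA": 0, "LC/NT": 0, "VU": 1, "EN": 2, "CR": 3}

TABLE1_SHA256 = "01acfb4a50a2c165d724671a6867c1145f96225e5e99f34920da9a8754702fa3"

SCENARIO_COLUMNS = ["nd_ssp245_4160", "nd_ssp585_4160", "nd_ssp245_6180",
                    "nd_ssp585_6180", "fd_ssp245_4160", "fd_ssp585_4160",
                    "fd_ssp245_6180", "fd_ssp585_6180"]


def _records_projection(occ: OccurrenceSet) -> tuple[np.ndarray, AzimuthalEqualArea]:
    lonlat = occ.kept_lonlat()
    if lonlat.shape[0] < 1:
        raise ValueError("need at least 1 kept record")
    proj = AzimuthalEqualArea(lonlat[:, 0].mean(), lonlat[:, 1].mean())
    return lonlat, proj


def aoo_km2(occ: OccurrenceSet, cell_km: float = 2.0) -> float:
    """Area of occupancy: occupied fixed-origin cells x cell area.

    Records are snapped to a ``cell_km`` grid anchored at the origin of the
    species-centred equal-area projection; invariant to duplicates and order.
    """
    lonlat, proj = _records_projection(occ)
    x, y = proj.forward(lonlat[:, 0], lonlat[:, 1])
    cells = set(zip(np.floor(x / cell_km).astype(int),
                    np.floor(y / cell_km).astype(int)))
    return len(cells) * cell_km ** 2


def eoo_km2(occ: OccurrenceSet, cell_km: float = 2.0) -> float:
    """Extent of occurrence: MCP area, floored at the AOO (IUCN rule).

    Degenerate record sets (fewer than 3 non-collinear points) have zero
    hull area and therefore return the AOO.
    """
    lonlat, proj = _records_projection(occ)
    x, y = proj.forward(lonlat[:, 0], lonlat[:, 1])
    hull = MultiPoint(np.column_stack([x, y])).convex_hull
    return max(float(hull.area), aoo_km2(occ, cell_km))


def _threshold_category(value: float, thresholds: dict[str, float]) -> str:
    for cat in ("CR", "EN", "VU"):
        if value < thresholds[cat]:
            return cat
    return "NA"


def category_from_geographic_range(eoo: float, aoo: float,
                                   conditions_met: int = 2) -> str:
    """Most severe of the B1 (EOO) and B2 (AOO) candidate categories.

    With fewer than two of conditions (a)-(c) met the thresholds are only
    advisory and the category is NA.
    """
    if not 0 <= conditions_met <= 3:
        raise ValueError("conditions_met must be in 0..3")
    cand_b1 = _threshold_category(eoo, EOO_THRESHOLDS)
    cand_b2 = _threshold_category(aoo, AOO_THRESHOLDS)
    best = max((cand_b1, cand_b2), key=lambda c: SEVERITY[c])
    if best == "NA" or conditions_met < 2:
        return "NA"
    return best


def category_from_loss(loss_percent: float) -> str:
    """A3c category from projected percent habitat loss (gains give LC/NT)."""
    if loss_percent >= A3C_THRESHOLDS["CR"]:
        return "CR"
    if loss_percent >= A3C_THRESHOLDS["EN"]:
        return "EN"
    if loss_percent >= A3C_THRESHOLDS["VU"]:
        return "VU"
    return "LC/NT"


@dataclass
class ThreatAssessment:
    species_id: str
    eoo_km2: float
    aoo_km2: float
    category_B: str
    loss_by_scenario: dict[str, float] = field(default_factory=dict)
    category_A3c: dict[str, str] = field(default_factory=dict)


def assess_species(occ: OccurrenceSet,
                   change_by_scenario: dict[str, float] | None = None,
                   conditions_met: int = 2, cell_km: float = 2.0
                   ) -> ThreatAssessment:
    """Preliminary assessment: criterion B plus A3c per scenario column."""
    eoo = eoo_km2(occ, cell_km)
    aoo = aoo_km2(occ, cell_km)
    losses, cats = {}, {}
    for key, change in (change_by_scenario or {}).items():
        losses[key] = -change
        cats[key] = category_from_loss(-change)
    return ThreatAssessment(species_id=occ.species_id, eoo_km2=eoo, aoo_km2=aoo,
                            category_B=category_from_geographic_range(
                                eoo, aoo, conditions_met),
                            loss_by_scenario=losses, category_A3c=cats)


# -- study-level summary -----------------------------------------------------


def floor1(x: float) -> float:
    """Floor to one decimal (the convention of the published percentages)."""
    return math.floor(x * 10.0 + 1e-9) / 10.0


@dataclass
class ColumnSummary:
    n_species: int
    n_vu: int
    n_en: int
    n_cr: int
    percent_threatened: float
    percent_vu: float
    percent_en: float
    percent_cr: float
    mean_decline_all: float       # mean of -change over all species
    mean_decline_declining: float  # mean of loss over declining species only
    max_increase: float
    n_total_loss: int             # species with change == -100


@dataclass
class SummaryReport:
    columns: dict[str, ColumnSummary]
    group_category_counts: pd.DataFrame  # per use group x category, n reaching it


def summarize_threat_table(change_table: pd.DataFrame,
                           columns: list[str] | None = None) -> SummaryReport:
    """Apply the A3c classification to every species x scenario change value.

    ``change_table`` must have one row per species with percent-change
    columns (negative = loss); missing cells raise with the offending
    species listed. Percentages use the full species count as denominator.
    """
    columns = columns or [c for c in SCENARIO_COLUMNS if c in change_table.columns]
    missing = change_table.loc[change_table[columns].isna().any(axis=1), "species"]
    if len(missing):
        raise ValueError(f"missing change values for: {', '.join(missing)}")
    n = len(change_table)
    out: dict[str, ColumnSummary] = {}
    for col in columns:
        change = change_table[col].to_numpy(float)
        loss = -change
        cats = np.array([category_from_loss(lo) for lo in loss])
        n_vu = int((cats == "VU").sum())
        n_en = int((cats == "EN").sum())
        n_cr = int((cats == "CR").sum())
        declining = loss[loss > 0]
        out[col] = ColumnSummary(
            n_species=n, n_vu=n_vu, n_en=n_en, n_cr=n_cr,
            percent_threatened=floor1(100.0 * (n_vu + n_en + n_cr) / n),
            percent_vu=floor1(100.0 * n_vu / n),
            percent_en=floor1(100.0 * n_en / n),
            percent_cr=floor1(100.0 * n_cr / n),
            mean_decline_all=float(loss.mean()),
            mean_decline_declining=float(declining.mean()) if declining.size else 0.0,
            max_increase=float(change.max()),
            n_total_loss=int((change == -100.0).sum()),
        )
    # per use group: species reaching each category in >= 1 scenario column
    rows = []
    if "use_group" in change_table.columns:
        for grp, sub in change_table.groupby("use_group", sort=True):
            losses = -sub[columns].to_numpy(float)
            reach = {cat: int((losses >= A3C_THRESHOLDS[cat]).any(axis=1).sum())
                     for cat in ("VU", "EN", "CR")}
            rows.append({"use_group": grp, "n_species": len(sub), **reach})
    groups = pd.DataFrame(rows)
    return SummaryReport(columns=out, group_category_counts=groups)


def load_table1_fixture(path: str | Path | None = None,
                        verify_checksum: bool = True) -> pd.DataFrame:
    """The packaged 135-species x 8-column range-change table."""
    if path is None:
        ref = resources.files("enmrisk.data") / "table1_fixture.csv"
        raw = ref.read_bytes()
    else:
        raw = Path(path).read_bytes()
    if verify_checksum and hashlib.sha256(raw).hexdigest() != TABLE1_SHA256:
        raise ValueError("table1 fixture failed its transcription checksum")
    from io import BytesIO
    df = pd.read_csv(BytesIO(raw))
    expected = ["species", "use_group"] + SCENARIO_COLUMNS
    if list(df.columns) != expected or len(df) != 135 or df.isna().any().any():
        raise ValueError("table1 fixture is malformed")
    return df
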