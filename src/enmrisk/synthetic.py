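"""Virtual species and synthetic climate landscapes.

Every downstream stage of the pipeline (cleaning, predictor selection, model
fitting, significance testing, range dynamics, Red List categorisation) can be
exercised end-to-end on data generated here, with the truth known exactly:

* climate layers are spatially autocorrelated Gaussian random fields,
  standardised to zero mean and unit variance over valid cells;
* a virtual species has a known linear+quadratic niche on min-max-scaled
  layers, with suitability ``1 - exp(-exp(eta))`` — the same complementary
  log-log response family the suitability model fits, so parameter recovery
  is well-posed;
* presence-only records are drawn with probability proportional to
  suitability (times an optional sampling-bias surface), with coordinate
  jitter, planted uniform outliers and exact duplicates emulating raw
  aggregated museum/GBIF data;
* future climate "GCM members" are the current stack plus a per-layer mean
  shift plus member-specific smooth noise.

All generators are pure functions of their inputs and the seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import ClimateStack, GridSpec
from .occurrences import OccurrenceSet


@dataclass
class VirtualSpecies:
    """A species with a known climatic niche on a synthetic landscape."""

    linear_coeffs: dict[str, float]
    quadratic_coeffs: dict[str, float]
    true_suitability: np.ndarray  # (n_rows, n_cols), NaN at nodata
    stack: ClimateStack
    growth_form: str = "herb"
    species_id: str = "virtual"


@dataclass
class FutureEnsembleSpec:
    """How to perturb the current climate into an ensemble of future members."""

    n_members: int = 8
    shifts: dict[str, float] = field(default_factory=dict)
    noise_scale: float = 0.0
    noise_range: float = 3.0  # smoothing radius of member noise, in cells
    scenario_label: str = "SSP2-4.5"
    period_label: str = "2041-2060"

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int],
                    autocorr_range: float) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if autocorr_range > 0:
        field_ = gaussian_filter(field_, sigma=autocorr_range, mode="nearest")
    return field_


def make_climate_stack(spec: GridSpec, variable_names: list[str],
                       autocorr_range: float = 5.0, seed: int = 0) -> ClimateStack:
    """Smoothed, standardised Gaussian random field per variable.

    ``autocorr_range`` is the Gaussian smoothing radius in cells; 0 gives
    spatially white layers. Each layer is standardised to zero mean / unit
    variance over valid cells, so layers are directly comparable and the
    min-max scaling downstream is well conditioned.
    """
    if not variable_names:
        raise ValueError("no predictors: variable_names is empty")
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be >= 0")
    rng = np.random.default_rng(seed)
    layers = []
    for _ in variable_names:
        f = _smoothed_field(rng, spec.shape, autocorr_range)
        f = (f - f.mean()) / f.std()
        layers.append(f)
    return ClimateStack(spec, list(variable_names), np.stack(layers))


def _minmax_scaled(stack: ClimateStack) -> dict[str, np.ndarray]:
    scaled = {}
    for name in stack.names:
        layer = stack.layer(name)
        vals = layer[stack.mask]
        lo, hi = vals.min(), vals.max()
        scaled[name] = (layer - lo) / (hi - lo) if hi > lo else np.zeros_like(layer)
    return scaled


def make_virtual_species(stack: ClimateStack,
                         linear_coeffs: dict[str, float],
                         quadratic_coeffs: dict[str, float],
                         seed: int = 0,
                         growth_form: str = "herb",
                         species_id: str = "virtual") -> VirtualSpecies:
    """True suitability ``1 - exp(-exp(eta))``, eta = sum(a_k z_k + b_k z_k^2).

    ``z_k`` are the stack's layers min-max-scaled over valid cells. Coefficient
    keys must name existing layers.
    """
    for name in list(linear_coeffs) + list(quadratic_coeffs):
        if name not in stack.names:
            raise ValueError(f"unknown variable name: {name!r}")
    z = _minmax_scaled(stack)
    eta = np.zeros(stack.grid.shape)
    for name, a in linear_coeffs.items():
        eta = eta + a * z[name]
    for name, b in quadratic_coeffs.items():
        eta = eta + b * z[name] ** 2
    suit = 1.0 - np.exp(-np.exp(eta))
    suit = np.where(stack.mask, suit, np.nan)
    return VirtualSpecies(dict(linear_coeffs), dict(quadratic_coeffs), suit,
                          stack, growth_form, species_id)


def sample_occurrences(vs: VirtualSpecies, n: int,
                       bias_surface: np.ndarray | None = None,
                       outlier_fraction: float = 0.0,
                       duplicate_fraction: float = 0.0,
                       seed: int = 0) -> OccurrenceSet:
    """Presence-only records: suitability-weighted cells + jittered coordinates.

    ``round(n * outlier_fraction)`` records are planted outliers drawn
    uniformly over valid cells (flagged in the ``planted_outlier`` column);
    ``round(n * duplicate_fraction)`` are exact copies of uniformly chosen
    retained records; the remainder are drawn with probability proportional
    to ``true_suitability * bias``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for frac in (outlier_fraction, duplicate_fraction):
        if not 0.0 <= frac < 1.0:
            raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    grid = vs.stack.grid
    mask = vs.stack.mask
    suit = np.where(mask, np.nan_to_num(vs.true_suitability), 0.0)
    if bias_surface is not None:
        suit = suit * np.asarray(bias_surface, dtype=float)
    p = suit.ravel()
    if p.sum() <= 0:
        raise ValueError("cannot sample: suitability x bias is zero everywhere")
    p = p / p.sum()

    n_out = int(round(n * outlier_fraction))
    n_dup = int(round(n * duplicate_fraction))
    n_core = n - n_out - n_dup

    core_cells = rng.choice(p.size, size=n_core, replace=True, p=p)
    valid = np.flatnonzero(mask.ravel())
    out_cells = rng.choice(valid, size=n_out, replace=True)

    cells = np.concatenate([core_cells, out_cells]).astype(int)
    rows, cols = np.divmod(cells, grid.n_cols)
    cs = grid.cell_size
    lon = grid.origin_lon + (cols + 0.5) * cs + rng.uniform(-cs / 2, cs / 2, cells.size)
    lat = grid.origin_lat + (rows + 0.5) * cs + rng.uniform(-cs / 2, cs / 2, cells.size)
    planted = np.zeros(cells.size, dtype=bool)
    planted[n_core:] = True

    if n_dup:
        src = rng.integers(0, cells.size, size=n_dup)
        lon = np.concatenate([lon, lon[src]])
        lat = np.concatenate([lat, lat[src]])
        planted = np.concatenate([planted, planted[src]])

    records = pd.DataFrame({
        "decimalLongitude": lon,
        "decimalLatitude": lat,
        "status": "kept",
        "planted_outlier": planted,
    })
    return OccurrenceSet(species_id=vs.species_id, growth_form=vs.growth_form,
                         records=records)


def make_future_ensemble(stack: ClimateStack, fspec: FutureEnsembleSpec,
                         seed: int = 0) -> list[ClimateStack]:
    """Future members: current + per-layer shift + member-specific smooth noise."""
    for name in fspec.shifts:
        if name not in stack.names:
            raise ValueError(f"shift names a layer not in the stack: {name!r}")
    rng = np.random.default_rng(seed)
    shift = np.array([fspec.shifts.get(name, 0.0) for name in stack.names])
    members = []
    for _ in range(fspec.n_members):
        data = stack.data + shift[:, None, None]
        if fspec.noise_scale > 0:
            noise = np.stack([
                _smoothed_field(rng, stack.grid.shape, fspec.noise_range)
                for _ in stack.names])
            # rescale after smoothing so noise_scale is the marginal sd
            sd = noise.std(axis=(1, 2), keepdims=True)
            noise = fspec.noise_scale * noise / np.where(sd > 0, sd, 1.0)
            data = data + noise
        members.append(ClimateStack(stack.grid, list(stack.names), data,
                                    stack.mask.copy()))
    return members


def write_truth_sidecar(path: str | Path, vs: VirtualSpecies,
                        occ: OccurrenceSet) -> None:
    """JSON record of the planted truth (niche coefficients, outlier indices)."""
    planted = occ.records.get("planted_outlier")
    sidecar = {
        "species_id": vs.species_id,
        "growth_form": vs.growth_form,
        "linear_coeffs": vs.linear_coeffs,
        "quadratic_coeffs": vs.quadratic_coeffs,
        "planted_outlier_indices":
            [] if planted is None else np.flatnonzero(planted.to_numpy()).tolist(),
    }
    Path(path).write_text(json.dumps(sidecar, indent=2))
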