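"""Null-model significance test for presence-only niche models.

Training AUC of a presence-only model is optimistically biased, and its
distribution under "no niche" depends strongly on the number of records.
The test fits the same model configuration to repeated draws of n random
cells from the landscape, forming a null AUC distribution; the observed
model is significant only if its AUC exceeds the null distribution's 95th
percentile. Because the null depends only on the landscape and n, one
distribution can be cached and shared across species with equal record
counts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import ClimateStack
from .maxent import build_features, fit_maxent, sample_background


@dataclass
class NullDistribution:
    n_records: int
    null_aucs: np.ndarray
    critical_value: float  # empirical 95th percentile (linear interpolation)
    level: float = 0.95

    @property
    def n_null(self) -> int:
        return int(self.null_aucs.size)


@dataclass
class SignificanceResult:
    observed_auc: float
    critical_value: float
    p_value: float
    significant: bool


_memory_cache: dict[tuple, NullDistribution] = {}


def null_auc_distribution(stack: ClimateStack, retained_names: list[str],
                          n_records: int, n_null: int = 100,
                          n_background: int = 10_000,
                          reg_multiplier: float = 1.0,
                          max_iterations: int = 500,
                          seed: int = 0, level: float = 0.95,
                          null_point_pool: np.ndarray | None = None,
                          use_cache: bool = True) -> NullDistribution:
    """Training AUCs of models fitted to random presences.

    Each of the ``n_null`` repetitions draws ``n_records`` cells uniformly
    without replacement (from ``null_point_pool`` if given — a hook for
    bias-corrected null sampling — else from all valid cells) and fits the
    identical model configuration against one shared background sample.
    """
    if n_records < 2:
        raise ValueError("n_records must be >= 2")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    key = (id(stack), tuple(retained_names), n_records, n_null, n_background,
           reg_multiplier, max_iterations, seed, level,
           None if null_point_pool is None else null_point_pool.tobytes())
    if use_cache and key in _memory_cache:
        return _memory_cache[key]

    rng = np.random.default_rng(seed)
    pool = (stack.valid_cell_indices() if null_point_pool is None
            else np.asarray(null_point_pool, dtype=int))
    if n_records > pool.size:
        raise ValueError("n_records exceeds the available cells")
    background_cells = sample_background(stack, n_background, rng)
    fspec = build_features(stack, retained_names, background_cells)
    F_bg = fspec.transform(stack.values_at_cells(background_cells, retained_names))

    aucs = np.empty(n_null)
    for i in range(n_null):
        cells = rng.choice(pool, size=n_records, replace=False)
        F_p = fspec.transform(stack.values_at_cells(cells, retained_names))
        aucs[i] = fit_maxent(F_p, F_bg, reg_multiplier, max_iterations).training_auc
    dist = NullDistribution(n_records=n_records, null_aucs=aucs,
                            critical_value=float(np.quantile(aucs, level)),
                            level=level)
    if use_cache:
        _memory_cache[key] = dist
    return dist


def test_significance(observed_auc: float,
                      null_dist: NullDistribution) -> SignificanceResult:
    """Significant iff observed AUC strictly exceeds the null critical value.

    The empirical p-value is ``(1 + #{null >= observed}) / (n_null + 1)``.
    """
    if not 0.0 <= observed_auc <= 1.0:
        raise ValueError("observed_auc must be in [0, 1]")
    n_ge = int((null_dist.null_aucs >= observed_auc).sum())
    p = (1 + n_ge) / (null_dist.n_null + 1)
    return SignificanceResult(observed_auc=float(observed_auc),
                              critical_value=null_dist.critical_value,
                              p_value=float(p),
                              significant=bool(observed_auc > null_dist.critical_value))


def save_null_distribution(path: str | Path, dist: NullDistribution) -> None:
    Path(path).write_text(json.dumps({
        "n_records": dist.n_records, "level": dist.level,
        "critical_value": dist.critical_value,
        "null_aucs": dist.null_aucs.tolist()}, indent=2))


def load_null_distribution(path: str | Path) -> NullDistribution:
    d = json.loads(Path(path).read_text())
    return NullDistribution(n_records=d["n_records"],
                            null_aucs=np.asarray(d["null_aucs"]),
                            critical_value=d["critical_value"], level=d["level"])
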