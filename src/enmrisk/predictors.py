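"""Predictor screening: growth-form candidate sets and stepwise VIF removal.

Multicollinear predictors inflate coefficient variance and make fitted
response curves hard to interpret. The screen used here is the variance
inflation factor, VIF_j = 1 / (1 - R^2_j), where R^2_j comes from an ordinary
least-squares regression of predictor j on all the others (intercept
included). Variables are removed one at a time, worst VIF first, until all
remaining VIFs are below the threshold (default 5).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VIF_THRESHOLD_DEFAULT = 5.0

#: the 19 standard bioclimatic variable names (WorldClim convention)
BIOCLIM_NAMES = [f"bio{i:02d}" for i in range(1, 20)]

#: growth forms recognised by the default candidate-set config
GROWTH_FORMS = ["epiphyte", "fern", "graminoid", "herb", "hydrophyte",
                "lithophyte", "shrub", "tree", "vine"]


@dataclass
class PredictorSet:
    growth_form: str
    candidate_names: list[str]
    retained_names: list[str]
    vif_trace: list[tuple[str, float]] = field(default_factory=list)


def vif(values: pd.DataFrame) -> pd.Series:
    """Per-variable variance inflation factors.

    Perfectly collinear variables get ``numpy.inf``. Requires more samples
    than variables and non-constant columns.
    """
    values = pd.DataFrame(values)
    n, p = values.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n <= p:
        raise ValueError("need more samples than variables")
    X = values.to_numpy(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant variable")
    out = {}
    for j, name in enumerate(values.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_step(values: pd.DataFrame, threshold: float = VIF_THRESHOLD_DEFAULT,
             growth_form: str = "unknown") -> PredictorSet:
    """Remove the worst-VIF variable until all VIFs are below ``threshold``.

    Tie-break on equal VIF: the alphabetically later name is removed, so the
    result does not depend on column order. Stops with a warning if fewer
    than 2 variables remain.
    """
    values = pd.DataFrame(values)
    candidates = list(values.columns)
    trace: list[tuple[str, float]] = []
    current = values
    while True:
        if current.shape[1] < 2:
            warnings.warn("fewer than 2 variables remain; stopping VIF stepping")
            break
        v = vif(current)
        worst = v.max()
        if worst < threshold:
            break
        ties = sorted(v.index[v == worst])
        removed = ties[-1]  # drop the later name alphabetically
        trace.append((removed, float(worst)))
        current = current.drop(columns=[removed])
    return PredictorSet(growth_form=growth_form, candidate_names=candidates,
                        retained_names=list(current.columns), vif_trace=trace)


def growth_form_candidates(growth_form: str,
                           config: dict[str, list[str]] | None = None) -> list[str]:
    """Candidate predictor names for a growth form.

    ``config`` maps growth form -> list of names, with an optional
    ``"default"`` entry. Without a config, every recognised growth form maps
    to all 19 bioclimatic variables.
    """
    if config is None:
        config = {gf: list(BIOCLIM_NAMES) for gf in GROWTH_FORMS}
    if growth_form in config:
        return list(config[growth_form])
    if "default" in config:
        return list(config["default"])
    raise KeyError(f"unknown growth form {growth_form!r} and no default entry")
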