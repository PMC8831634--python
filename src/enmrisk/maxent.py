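"""Maximum-entropy habitat suitability model (linear + quadratic features).

The model estimates a probability distribution p(x) over background cells
that maximises entropy subject to the fitted feature expectations matching
the presence sample, which is equivalent to the L1-regularised exponential
(Gibbs) family fit:

    maximise  (1/m) sum_presences lambda.f  -  log sum_background exp(lambda.f)
              -  sum_j beta_j |lambda_j|

with per-feature penalty beta_j = reg_multiplier * s_j / sqrt(m), where s_j
is the feature's standard deviation over the m presences (floored at 1e-6).
Features are the min-max-scaled predictors z_k and their squares z_k^2,
clamped to [0, 1] when projecting outside the training range so quadratic
terms cannot extrapolate unboundedly into novel climates.

Suitability uses the complementary log-log output,

    cloglog(x) = 1 - exp(-exp(H) * p_raw(x)),

with H the entropy of the fitted raw distribution over background; for a
completely uninformative model every cell gets 1 - 1/e ~ 0.632.

The optimisation is convex; it is solved by L-BFGS-B on the positive/negative
split lambda = u - v (u, v >= 0), which turns the L1 penalty into a smooth
bound-constrained problem.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import ClimateStack
from .occurrences import OccurrenceSet

CONVERGENCE_TOL = 1e-5


@dataclass
class FeatureSpec:
    """Scaling bounds and the linear+quadratic feature layout."""

    variable_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @property
    def feature_names(self) -> list[str]:
        return list(self.variable_names) + [f"{n}^2" for n in self.variable_names]

    @property
    def n_features(self) -> int:
        return 2 * len(self.variable_names)

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Min-max scale raw predictor values, clamping to [0, 1]."""
        X = np.asarray(X, dtype=float)
        z = (X - self.mins) / (self.maxs - self.mins)
        return np.clip(z, 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(n, 2d) feature matrix: all linear terms, then all squares."""
        z = self.scale(X)
        return np.hstack([z, z ** 2])


@dataclass
class ModelFit:
    feature_names: list[str]
    lam: np.ndarray
    log_partition: float
    entropy_H: float
    training_auc: float
    n_iterations_used: int
    objective_trace: list[float] = field(default_factory=list, repr=False)


@dataclass
class EnsembleFit:
    replicates: list[ModelFit]
    mean_map: np.ndarray  # (n_rows, n_cols), NaN at nodata
    auc_mean: float
    auc_sd: float
    feature_spec: FeatureSpec
    background_cells: np.ndarray
    presence_cells: np.ndarray


def build_features(stack: ClimateStack, retained_names: list[str],
                   background_cells: np.ndarray) -> FeatureSpec:
    """Feature spec with min-max bounds taken over the background sample."""
    if len(background_cells) == 0:
        raise ValueError("background is empty")
    vals = stack.values_at_cells(background_cells, retained_names)
    mins = vals.min(axis=0)
    maxs = vals.max(axis=0)
    if np.any(maxs <= mins):
        bad = [n for n, lo, hi in zip(retained_names, mins, maxs) if hi <= lo]
        raise ValueError(f"degenerate predictor (constant over background): {bad}")
    return FeatureSpec(list(retained_names), mins, maxs)


def fit_maxent(presence_features: np.ndarray, background_features: np.ndarray,
               reg_multiplier: float = 1.0, max_iterations: int = 500,
               feature_names: list[str] | None = None) -> ModelFit:
    """Fit the L1-penalised maximum-entropy model; see module docstring."""
    F_p = np.asarray(presence_features, dtype=float)
    F_b = np.asarray(background_features, dtype=float)
    if not (np.all(np.isfinite(F_p)) and np.all(np.isfinite(F_b))):
        raise ValueError("non-finite feature values")
    m, d = F_p.shape
    if m < 2:
        raise ValueError("need at least 2 presences")
    if F_b.shape[0] < m:
        raise ValueError("background must be at least as large as the presence set")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(d)]

    mean_p = F_p.mean(axis=0)
    beta = reg_multiplier * np.maximum(F_p.std(axis=0), 1e-6) / np.sqrt(m)
    trace: list[float] = []

    def objective(uv):
        lam = uv[:d] - uv[d:]
        scores = F_b @ lam
        logZ = logsumexp(scores)
        p = np.exp(scores - logZ)
        nll = -(mean_p @ lam) + logZ + beta @ (uv[:d] + uv[d:])
        grad_lam = -mean_p + F_b.T @ p
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return nll, grad

    x0 = np.zeros(2 * d)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * d),
                   callback=lambda xk: trace.append(objective(xk)[0]),
                   options={"maxiter": max_iterations, "ftol": 1e-14,
                            "gtol": CONVERGENCE_TOL})
    lam = res.x[:d] - res.x[d:]
    scores_b = F_b @ lam
    logZ = float(logsumexp(scores_b))
    log_p = scores_b - logZ
    H = float(-(np.exp(log_p) @ log_p))
    fit = ModelFit(feature_names=list(feature_names), lam=lam,
                   log_partition=logZ, entropy_H=H, training_auc=np.nan,
                   n_iterations_used=int(res.nit), objective_trace=trace)
    fit.training_auc = auc(predict_cloglog(fit, F_p), predict_cloglog(fit, F_b))
    return fit


def predict_cloglog(fit: ModelFit, feature_values: np.ndarray) -> np.ndarray:
    """Suitability in [0, 1]: ``1 - exp(-exp(H) * p_raw)``."""
    F = np.asarray(feature_values, dtype=float)
    log_p_raw = F @ fit.lam - fit.log_partition
    # clip the double exponent: beyond +-700 the cloglog saturates anyway
    return 1.0 - np.exp(-np.exp(np.clip(fit.entropy_H + log_p_raw, -700.0, 700.0)))


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    pres = np.asarray(presence_scores, dtype=float).ravel()
    bg = np.asarray(background_scores, dtype=float).ravel()
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pres, bg]))
    u = ranks[:pres.size].sum() - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * bg.size))


def sample_background(stack: ClimateStack, n_background: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of valid cells without replacement, capped at availability."""
    valid = stack.valid_cell_indices()
    n = min(n_background, valid.size)
    return rng.choice(valid, size=n, replace=False)


def fit_bootstrap(occ: OccurrenceSet, stack: ClimateStack,
                  retained_names: list[str] | None = None,
                  n_reps: int = 100, n_background: int = 10_000,
                  reg_multiplier: float = 1.0, max_iterations: int = 500,
                  seed: int = 0) -> EnsembleFit:
    """Bootstrap-replicated fit with one shared background sample.

    Each replicate resamples the presences with replacement (same size);
    the background sample is drawn once per species, mirroring the standard
    tool's behaviour and stabilising AUC comparisons across replicates. The
    ensemble suitability map is the cell-wise mean of replicate cloglog maps.
    """
    rng = np.random.default_rng(seed)
    names = retained_names if retained_names is not None else stack.names
    background_cells = sample_background(stack, n_background, rng)
    lonlat = occ.kept_lonlat()
    m = lonlat.shape[0]
    if background_cells.size < m:
        raise ValueError("background smaller than the presence set")
    fspec = build_features(stack, names, background_cells)

    row, col = stack.grid.cell_of(lonlat[:, 0], lonlat[:, 1])
    presence_cells = row * stack.grid.n_cols + col
    F_pres_all = fspec.transform(stack.values_at_cells(presence_cells, names))
    F_bg = fspec.transform(stack.values_at_cells(background_cells, names))

    valid = stack.valid_cell_indices()
    F_valid = fspec.transform(stack.values_at_cells(valid, names))

    fits, aucs = [], []
    mean_map = np.full(stack.grid.shape, np.nan)
    acc = np.zeros(valid.size)
    for _ in range(n_reps):
        take = rng.integers(0, m, size=m)
        fit = fit_maxent(F_pres_all[take], F_bg, reg_multiplier,
                         max_iterations, fspec.feature_names)
        fits.append(fit)
        aucs.append(fit.training_auc)
        acc += predict_cloglog(fit, F_valid)
    mean_map.ravel()[valid] = acc / n_reps
    return EnsembleFit(replicates=fits, mean_map=mean_map,
                       auc_mean=float(np.mean(aucs)),
                       auc_sd=float(np.std(aucs, ddof=1)) if n_reps > 1 else 0.0,
                       feature_spec=fspec, background_cells=background_cells,
                       presence_cells=presence_cells)


def response_curve(fit: ModelFit, fspec: FeatureSpec, variable_name: str,
                   n_steps: int = 100,
                   background_means: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-strip response: vary one predictor across its background
    range with every other predictor held at its background mean."""
    if variable_name not in fspec.variable_names:
        raise ValueError(f"{variable_name!r} not in the feature spec")
    j = fspec.variable_names.index(variable_name)
    if background_means is None:
        background_means = (fspec.mins + fspec.maxs) / 2.0
    values = np.linspace(fspec.mins[j], fspec.maxs[j], n_steps)
    X = np.tile(np.asarray(background_means, dtype=float), (n_steps, 1))
    X[:, j] = values
    return values, predict_cloglog(fit, fspec.transform(X))
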