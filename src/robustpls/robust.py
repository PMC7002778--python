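"""Robust weight functions, scale estimators, and robust linear PLS.

Implements the non-kernel robust calibration ladder:

* PRM  — partial robust M-regression: iteratively reweighted PLS with a
  generalized weight ``w_i = w_i^r * w_i^x`` combining a residual weight
  (standardized by the MAD scale) and a score-leverage weight (distance of
  each score row to the spatial median, standardized by the median
  distance).
* PRMM — an MM-type refinement: the PRM fit supplies initial estimates and
  residuals, a high-breakdown LTS scale of those residuals is then held
  fixed while the M-iterations continue.
* PRGM6 — a GM6-type one-step Newton-Raphson update on the score space
  with MVE-based robust-Mahalanobis leverage weights and an LMS residual
  scale.

Weight families follow the PRM literature: the "fair" function
``w(z) = 1/(1 + |z/c|)^2`` (default, c = 4) and Huber's
``w(z) = min(1, c/|z|)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import RegressionDataset
from .exceptions import ConfigurationError, DegenerateDataError
from .pls import PLSModel, weighted_refit

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826


# ---------------------------------------------------------------------------
# Weight functions and scale estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightFunctionSpec:
    """A bounded, monotone nonincreasing weight function w(|z|) in (0, 1]."""

    family: str = "fair"  # "fair" or "huber"
    tuning_c: float = 4.0

    def __post_init__(self) -> None:
        if self.family not in ("fair", "huber"):
            raise ConfigurationError(f"unknown weight family {self.family!r}")
        if self.tuning_c <= 0:
            raise ConfigurationError("tuning_c must be positive")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.abs(np.asarray(z, dtype=float))
        if self.family == "fair":
            return 1.0 / (1.0 + z / self.tuning_c) ** 2
        with np.errstate(divide="ignore"):
            return np.minimum(1.0, np.where(z > 0, self.tuning_c / z, np.inf))


def raw_mad(values: np.ndarray) -> float:
    """Median absolute deviation about the median, no consistency factor."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def mad_scale(residuals: np.ndarray) -> float:
    """MAD scale with the Gaussian consistency factor 1.4826.

    Returns 0 for a constant vector; callers must guard.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 2:
        raise DegenerateDataError("mad_scale needs at least two residuals")
    return MAD_CONSISTENCY * raw_mad(residuals)


def lts_scale(residuals: np.ndarray, h: int | None = None, seed: int | None = None) -> float:
    """Least-trimmed-squares scale: rms of the h smallest squared residuals,
    with the truncated-normal consistency correction.

    ``seed`` is accepted for API symmetry with subsampling-based robust
    estimators; the trimmed scale itself is deterministic.
    """
    del seed
    r = np.asarray(residuals, dtype=float).ravel()
    n = r.size
    if n < 2:
        raise DegenerateDataError("lts_scale needs at least two residuals")
    if h is None:
        h = n // 2 + 1
    if not 2 <= h <= n:
        raise ConfigurationError(f"h={h} outside [2, {n}]")
    r2 = np.sort(r**2)[:h]
    alpha = h / n
    qa = stats.norm.ppf((1.0 + alpha) / 2.0)
    correction = 1.0 - 2.0 * qa * stats.norm.pdf(qa) / alpha
    return float(np.sqrt(np.mean(r2) / correction))


def lms_scale(residuals: np.ndarray, p: int) -> float:
    """Least-median-of-squares scale: 1.4826 (1 + 5/(n - p)) median|r|."""
    r = np.asarray(residuals, dtype=float).ravel()
    n = r.size
    if n < 2:
        raise DegenerateDataError("lms_scale needs at least two residuals")
    if n <= p:
        raise ConfigurationError("lms_scale requires n > p")
    return MAD_CONSISTENCY * (1.0 + 5.0 / (n - p)) * float(np.median(np.abs(r)))


def l1_median(V: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Spatial (geometric) median of the rows of V by Weiszfeld iteration.

    Points coinciding with the current iterate are handled by the standard
    distance floor, which makes the iteration well defined everywhere.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[0] == 1:
        return V[0].copy()
    center = np.median(V, axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(V - center, axis=1)
        d = np.maximum(d, 1e-12)
        inv = 1.0 / d
        new = (inv @ V) / inv.sum()
        if np.linalg.norm(new - center) < tol:
            return new
        center = new
    return center


def residual_weights(residuals: np.ndarray, scale: float, spec: WeightFunctionSpec) -> np.ndarray:
    """Weights of standardized residuals, w(f_i / scale)."""
    if scale <= 0:
        raise DegenerateDataError("residual scale must be positive")
    return spec(np.asarray(residuals, dtype=float) / scale)


def score_weights(V: np.ndarray, spec: WeightFunctionSpec) -> np.ndarray:
    """Leverage weights from score-space distances to the spatial median.

    Distances are standardized by their median; an observation with weight
    near zero is a suspected leverage point.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[0] < 3:
        raise DegenerateDataError("score_weights needs at least three rows")
    center = l1_median(V)
    d = np.linalg.norm(V - center, axis=1)
    med = float(np.median(d))
    if med <= 0:
        raise DegenerateDataError("median score distance is zero")
    return spec(d / med)


# ---------------------------------------------------------------------------
# IRLS machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustPLSConfig:
    """Settings shared by the robust (and kernel-robust) PLS variants.

    ``scale_estimator`` records the residual-scale family; each estimator
    pins its own choice by definition (PRM: mad, PRMM: lts, PRGM6: lms),
    so the field is informational unless a custom pipeline consumes it.
    """

    n_components: int = 2
    residual_weight: WeightFunctionSpec = field(default_factory=WeightFunctionSpec)
    score_weight: WeightFunctionSpec = field(default_factory=WeightFunctionSpec)
    max_irls_iter: int = 30
    irls_tol: float = 1e-6
    scale_estimator: str = "mad"
    seed: int = 0
    gm6_initial: str = "prmm"          # or "lts"
    gm6_psi_c: float = 1.345           # Huber psi tuning constant
    leverage_flag_threshold: float = 0.01
    potential_c: float = 3.0           # cut-off constant for DRGP potentials
    mve_trials: int = 500

    def __post_init__(self) -> None:
        if self.max_irls_iter < 1:
            raise ConfigurationError("max_irls_iter must be at least 1")
        if self.irls_tol <= 0:
            raise ConfigurationError("irls_tol must be positive")
        if self.gm6_initial not in ("prmm", "lts"):
            raise ConfigurationError("gm6_initial must be 'prmm' or 'lts'")


@dataclass
class IRLSState:
    """Trace of the final accepted IRLS iteration."""

    iteration: int
    residuals: np.ndarray
    scale: float
    weights: np.ndarray
    coef_change: float
    converged: bool
    objective: float
    leverage_flags: np.ndarray


def _initial_weights(data: RegressionDataset, config: RobustPLSConfig) -> np.ndarray:
    """Starting generalized weights, from robustly centered raw data."""
    r0 = data.y - np.median(data.y)
    s0 = mad_scale(r0)
    wr = residual_weights(r0, s0, config.residual_weight) if s0 > 0 else np.ones(data.n)
    try:
        wx = score_weights(data.x, config.score_weight)
    except DegenerateDataError:
        wx = np.ones(data.n)
    return wr * wx


def _clip_components(data: RegressionDataset, l: int) -> int:
    return max(1, min(l, data.n - 1, data.m))


def _irls(
    data: RegressionDataset,
    config: RobustPLSConfig,
    weights0: np.ndarray,
    fixed_scale: float | None,
) -> tuple[PLSModel, IRLSState]:
    """Shared IRLS loop for PRM (MAD scale) and PRMM (fixed LTS scale).

    The weighted objective sum(w_i f_i^2) is monitored; an iteration that
    increases it is rolled back and the loop stops at the previous iterate.
    """
    l = _clip_components(data, config.n_components)
    w = np.maximum(np.asarray(weights0, dtype=float), 1e-12)
    best: tuple[PLSModel, IRLSState] | None = None
    prev_coef: np.ndarray | None = None
    prev_objective = np.inf
    converged = False
    for it in range(1, config.max_irls_iter + 1):
        model = weighted_refit(data, w, l)
        f = data.y - model.fitted
        objective = float(np.sum(w * f**2))
        if objective > prev_objective * (1.0 + 1e-10):
            logger.debug("IRLS objective increased at iteration %d; rolling back", it)
            break
        scale = fixed_scale if fixed_scale is not None else mad_scale(f)
        if scale <= 0:  # essentially perfect fit
            scale = max(float(np.abs(f).max()), 1e-12)
            converged = True
        wr = residual_weights(f, scale, config.residual_weight)
        V_all = model.transform(data.x)
        try:
            wx = score_weights(V_all, config.score_weight)
        except DegenerateDataError:
            wx = np.ones(data.n)
        coef_change = (
            np.inf if prev_coef is None
            else float(np.linalg.norm(model.coef - prev_coef)
                       / max(np.linalg.norm(prev_coef), 1e-12))
        )
        state = IRLSState(
            iteration=it,
            residuals=f,
            scale=float(scale),
            weights=w.copy(),
            coef_change=coef_change,
            converged=converged or coef_change < config.irls_tol,
            objective=objective,
            leverage_flags=wx < config.leverage_flag_threshold,
        )
        best = (model, state)
        prev_objective = objective
        prev_coef = model.coef
        if state.converged:
            converged = True
            break
        w = np.maximum(wr * wx, 1e-12)
    assert best is not None
    if not best[1].converged:
        logger.warning("IRLS did not converge within %d iterations", config.max_irls_iter)
    return best


def prm_fit(data: RegressionDataset, config: RobustPLSConfig) -> tuple[PLSModel, IRLSState]:
    """Partial robust M-regression by iteratively reweighted PLS."""
    return _irls(data, config, _initial_weights(data, config), fixed_scale=None)


def prmm_fit(data: RegressionDataset, config: RobustPLSConfig) -> tuple[PLSModel, IRLSState]:
    """Partial robust MM-regression.

    Stage 1 is a PRM fit; stage 2 freezes the LTS scale of its residuals
    and continues the M-iterations with residual weights standardized by
    that scale.  The returned estimate never has a larger weighted
    objective (evaluated at the fixed LTS scale) than the stage-1 estimate,
    the defining inequality of the MM construction.
    """
    l = _clip_components(data, config.n_components)
    model0, state0 = prm_fit(data, config)
    f0 = data.y - model0.fitted
    h = (data.n + l + 1) // 2
    sigma_lts = lts_scale(f0, h=h)
    if sigma_lts <= 0:
        return model0, state0

    def objective_at(model: PLSModel) -> float:
        f = data.y - model.fitted
        wr = residual_weights(f, sigma_lts, config.residual_weight)
        V_all = model.transform(data.x)
        try:
            wx = score_weights(V_all, config.score_weight)
        except DegenerateDataError:
            wx = np.ones(data.n)
        return float(np.sum(wr * wx * f**2))

    model1, state1 = _irls(data, config, state0.weights, fixed_scale=sigma_lts)
    if objective_at(model1) > objective_at(model0) * (1.0 + 1e-10):
        logger.debug("PRMM stage-2 objective above stage-1; keeping stage-1 estimate")
        return model0, state1
    return model1, state1


# ---------------------------------------------------------------------------
# GM6 one-step estimator
# ---------------------------------------------------------------------------

def _huber_psi(z: np.ndarray, c: float) -> np.ndarray:
    return np.clip(z, -c, c)


def _huber_psi_prime(z: np.ndarray, c: float) -> np.ndarray:
    return (np.abs(z) <= c).astype(float)


def _lts_on_scores(V: np.ndarray, y: np.ndarray, seed: int, n_subsets: int = 500) -> np.ndarray:
    """Elemental-subset LTS regression of y on score columns (no intercept;
    both are centered), refined with two concentration steps."""
    n, p = V.shape
    h = (n + p + 1) // 2
    rng = np.random.default_rng(seed)
    best_b, best_crit = None, np.inf
    for _ in range(n_subsets):
        idx = rng.choice(n, size=p, replace=False)
        try:
            b = np.linalg.solve(V[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        r2 = np.sort((y - V @ b) ** 2)
        crit = float(r2[:h].sum())
        if crit < best_crit:
            best_crit, best_b = crit, b
    if best_b is None:
        raise DegenerateDataError("all LTS elemental subsets were singular")
    for _ in range(2):  # concentration steps
        keep = np.argsort((y - V @ best_b) ** 2)[:h]
        best_b, *_ = np.linalg.lstsq(V[keep], y[keep], rcond=None)
    return best_b


def gm6_fit(
    data: RegressionDataset,
    config: RobustPLSConfig,
) -> PLSModel:
    """GM6-type robust PLS: one Newton-Raphson step on the score space.

    An initial high-efficiency robust fit (PRMM by default, LTS on scores
    via ``config.gm6_initial``) supplies the score matrix V, the initial
    inner coefficients and residuals.  Leverage weights
    ``w_i = min(1, chi2_{0.95,l} / RM_i^2)`` come from MVE-based robust
    Mahalanobis distances on V, the residual scale from the LMS formula,
    and a single Newton-Raphson step with Huber's psi produces the final
    coefficients, mapped back to the predictor space through the PLS
    rotation.
    """
    from .diagnostics import mve_fit, robust_mahalanobis  # local import: avoid cycle

    l = _clip_components(data, config.n_components)
    init_model, _ = prmm_fit(data, config)
    V = init_model.transform(data.x)  # unweighted scores of all rows
    y_c = data.y - init_model.y_center
    if config.gm6_initial == "lts":
        a0 = _lts_on_scores(V, y_c, seed=config.seed)
    else:
        a0, *_ = np.linalg.lstsq(
            V * np.sqrt(init_model.obs_weights)[:, None],
            y_c * np.sqrt(init_model.obs_weights), rcond=None,
        )
    r = y_c - V @ a0

    est = mve_fit(V, n_trials=config.mve_trials, seed=config.seed)
    rm2 = robust_mahalanobis(V, est)
    chi = stats.chi2.ppf(0.95, df=V.shape[1])
    with np.errstate(divide="ignore"):
        w = np.minimum(1.0, np.where(rm2 > 0, chi / rm2, np.inf))

    sigma = lms_scale(r, p=V.shape[1])
    if sigma <= 0:
        sigma = max(float(np.abs(r).max()), 1e-12)
    c = config.gm6_psi_c
    z = r / (sigma * w)
    B = _huber_psi_prime(z, c)
    G = V.T @ (B[:, None] * V)
    rhs = V.T @ (sigma * w * _huber_psi(z, c))
    try:
        step = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        logger.warning("singular V'BV in GM6 update; using ridge-regularized solve")
        ridge = 1e-8 * max(np.trace(G), 1.0)
        step = np.linalg.solve(G + ridge * np.eye(G.shape[0]), rhs)
    a1 = a0 + step

    coef = init_model.rotations @ a1
    fitted = (data.x - init_model.x_center) @ coef + init_model.y_center
    return PLSModel(
        n_components=init_model.n_components,
        x_weights=init_model.x_weights,
        x_scores=init_model.x_scores,
        x_loadings=init_model.x_loadings,
        y_loadings=a1,
        rotations=init_model.rotations,
        coef=coef,
        x_center=init_model.x_center,
        y_center=init_model.y_center,
        obs_weights=w,
        fitted=fitted,
    )
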