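"""Kernel PLS and its robust variants.

The kernel trick replaces the explicit feature map of a nonlinear PLS with
Gram-matrix evaluations: for the Gaussian kernel

    K_ij = exp(-||x_i - x_j||^2 / sigma2),

NIPALS runs directly on the double-centered Gram matrix, deflating
``K <- (I - vv')K(I - vv')`` and ``y <- (I - vv')y`` per extracted unit-norm
score ``v``.  Prediction uses the dual form

    y_hat = K_v U (V'KU)^{-1} V' y,

with the test Gram matrix centered against the training rows.

Observation weighting enters through a diagonal matrix ``Omega`` acting on
the implicit feature rows, ``K~ = Omega K Omega`` and ``y~ = Omega y``:

* KPRM iterates PRM's generalized weights in kernel space with
  ``Omega_ii = sqrt(w_i)``, so the weighted objective is sum(w_i f_i^2);
* KPDRGP alternates kernel-NIPALS fits with the DRGP leverage diagnostic
  on the kernel score matrix, deleting confirmed rows (``Omega_ii = 0``)
  and refitting until the flagged set stabilizes.

Centering statistics are computed with the same weights, which makes a 0/1
weight matrix exactly equivalent to physically removing the zero rows; the
printed uniform double-centering formulas are the special case of equal
weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data import RegressionDataset
from .exceptions import ConfigurationError, DegenerateDataError, DimensionError
from .robust import (
    RobustPLSConfig,
    IRLSState,
    mad_scale,
    residual_weights,
    score_weights,
)
from .diagnostics import DRGPResult, drgp_run

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kernels and centering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth.  ``sigma2="auto"`` resolves to the total
    (non-robust) variance of the training predictors."""

    family: str = "gaussian"   # "gaussian" or "linear"
    sigma2: float | str = "auto"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "linear"):
            raise ConfigurationError(f"unknown kernel family {self.family!r}")
        if self.sigma2 != "auto" and not (isinstance(self.sigma2, (int, float)) and self.sigma2 > 0):
            raise ConfigurationError("sigma2 must be positive or 'auto'")


def gaussian_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """Gaussian Gram matrix K_ij = exp(-||a_i - b_j||^2 / sigma2)."""
    if sigma2 <= 0:
        raise ConfigurationError("sigma2 must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DimensionError("kernel inputs must have matching column counts")
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / sigma2)


def resolve_sigma2(X: np.ndarray) -> float:
    """Default Gaussian bandwidth: the total variance of the training data,
    i.e. the sum over columns of the per-column sample variances (reducing
    to the scalar variance for a single predictor)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise DegenerateDataError("resolve_sigma2 needs at least two rows")
    total = float(X.var(axis=0, ddof=1).sum())
    if total <= 0:
        raise ConfigurationError("training data has zero total variance")
    return total


def _evaluate_kernel(spec: KernelSpec, A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    if spec.family == "gaussian":
        return gaussian_kernel(A, B, sigma2)
    return np.atleast_2d(np.asarray(A, float)) @ np.atleast_2d(np.asarray(B, float)).T


@dataclass
class KernelCenterStats:
    """Training statistics needed to center test Gram matrices."""

    col_stat: np.ndarray   # (K a), weighted column means of the training Gram
    grand: float           # a' K a
    a: np.ndarray          # centering weights, sum to 1


def center_kernel(K: np.ndarray, a: np.ndarray | None = None) -> tuple[np.ndarray, KernelCenterStats]:
    """Double-center a training Gram matrix.

    With uniform weights this is the textbook ``(I - 11'/n) K (I - 11'/n)``;
    a weight vector ``a`` (nonnegative, summing to 1) centers the implicit
    feature rows at their a-weighted mean instead.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape[0] != K.shape[1]:
        raise DimensionError("training Gram matrix must be square")
    if a is None:
        a = np.full(n, 1.0 / n)
    else:
        a = np.asarray(a, dtype=float)
        if a.shape[0] != n or np.any(a < 0) or not np.isclose(a.sum(), 1.0):
            raise ConfigurationError("centering weights must be nonnegative and sum to 1")
    ka = K @ a
    grand = float(a @ ka)
    Kc = K - ka[None, :] - ka[:, None] + grand
    return Kc, KernelCenterStats(col_stat=ka, grand=grand, a=a)


def center_kernel_test(K_v: np.ndarray, stats: KernelCenterStats) -> np.ndarray:
    """Center a test Gram matrix (n_v x n, built against the same training
    rows) using the stored training statistics."""
    K_v = np.atleast_2d(np.asarray(K_v, dtype=float))
    if K_v.shape[1] != stats.col_stat.shape[0]:
        raise DimensionError("test Gram matrix column count does not match training")
    row_stat = K_v @ stats.a
    return K_v - stats.col_stat[None, :] - row_stat[:, None] + stats.grand


# ---------------------------------------------------------------------------
# Kernel NIPALS
# ---------------------------------------------------------------------------

@dataclass
class KernelPLSModel:
    """A fitted kernel PLS1 model (possibly observation-weighted).

    The model keeps the training predictors, the diagonal weights omega,
    the centering statistics and the dual quantities (U, V, alpha) needed
    to evaluate the dual prediction formula on new data.
    """

    spec: KernelSpec
    sigma2: float
    x_train: np.ndarray
    omega: np.ndarray            # (n,), diagonal of Omega
    stats: KernelCenterStats
    K_centered: np.ndarray       # weighted-centered training Gram (n, n)
    scores: np.ndarray           # V, (n, l), orthonormal columns
    y_scores: np.ndarray         # U, (n, l)
    alpha: np.ndarray            # dual coefficients, (n,)
    proj: np.ndarray             # U (V'K~U)^{-1}, (n, l): right factor of transform
    y_center: float
    y_scale: float
    n_components: int
    fitted: np.ndarray           # (n,), fitted values for the original rows

    def _test_rows(self, x_new: np.ndarray) -> np.ndarray:
        K_v = _evaluate_kernel(self.spec, x_new, self.x_train, self.sigma2)
        return center_kernel_test(K_v, self.stats) * self.omega[None, :]

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return kpls_predict(self, x_new)

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Kernel score coordinates of new rows: k~(x) U (V'K~U)^{-1}."""
        return self._test_rows(np.atleast_2d(np.asarray(x_new, float))) @ self.proj


def kernel_nipals(
    K_centered: np.ndarray,
    y_centered: np.ndarray,
    n_components: int,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract kernel PLS components from a centered Gram matrix.

    Per component the latent y-score ``u`` is initialized from the current
    response, ``v = Ku`` is normalized, the y-side weight updates ``u``, and
    the pair is iterated until the normalized u changes by less than
    ``tol`` (for a univariate response this converges in one pass).  K and
    y are then deflated with ``I - vv'``.

    Returns the score matrix V (orthonormal columns) and the y-score
    matrix U.  Extraction stops early, with a log message, if the kernel
    score norm vanishes.
    """
    K = np.asarray(K_centered, dtype=float).copy()
    y = np.asarray(y_centered, dtype=float).ravel().copy()
    n = K.shape[0]
    l = int(n_components)
    if not 1 <= l <= n - 1:
        raise DimensionError(f"n_components={l} outside [1, n-1] = [1, {n - 1}]")
    V = np.zeros((n, l))
    U = np.zeros((n, l))
    n_kept = 0
    for g in range(l):
        norm_y = np.linalg.norm(y)
        if norm_y < 1e-12:
            logger.debug("response exhausted after %d kernel components", g)
            break
        u = y / norm_y
        v = np.zeros(n)
        for _ in range(max_iter):
            w = K @ u
            norm_w = np.linalg.norm(w)
            if norm_w < 1e-12:
                break
            v = w / norm_w
            c = float(y @ v)
            u_new = y * c
            norm_u = np.linalg.norm(u_new)
            if norm_u < 1e-12:
                break
            u_new = u_new / norm_u
            if np.linalg.norm(u_new - u) < tol:
                u = u_new
                break
            u = u_new
        if np.linalg.norm(v) < 1e-12:
            logger.warning("zero kernel score norm at component %d; stopping early", g + 1)
            break
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        U[:, g] = y  # pre-deflation residual response; column scale cancels
        V[:, g] = v
        P = np.eye(n) - np.outer(v, v)
        K = P @ K @ P
        y = y - v * float(v @ y)
        n_kept += 1
    if n_kept == 0:
        raise DegenerateDataError("no kernel PLS component could be extracted")
    return V[:, :n_kept], U[:, :n_kept]


def _fit_weighted_kpls(
    data: RegressionDataset,
    spec: KernelSpec,
    n_components: int,
    omega: np.ndarray,
    K_full: np.ndarray,
    sigma2: float,
    normalize_y: bool,
    tol: float = 1e-4,
) -> KernelPLSModel:
    """Shared fitting path for KPLS/KPRM/KPDRGP given diagonal weights."""
    n = data.n
    w2 = omega**2
    if not np.any(w2 > 0):
        raise DegenerateDataError("all kernel observation weights are zero")
    a = w2 / w2.sum()
    Kc, stats = center_kernel(K_full, a)
    y_center = float(a @ data.y)
    y_c = data.y - y_center
    if normalize_y:
        y_scale = float(np.sqrt(np.sum(a * y_c**2)))
        if y_scale <= 0:
            raise DegenerateDataError("response has zero variance under the weights")
    else:
        y_scale = 1.0
    y_t = omega * y_c / y_scale
    K_t = Kc * omega[None, :] * omega[:, None]

    n_active = int(np.count_nonzero(omega))
    l = max(1, min(int(n_components), n_active - 1))
    V, U = kernel_nipals(K_t, y_t, l, tol=tol)
    M = V.T @ (K_t @ U)
    try:
        inner = np.linalg.solve(M, np.eye(M.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("singular V'K~U in kernel PLS") from exc
    proj = U @ inner
    alpha = proj @ (V.T @ y_t)
    fitted_rows = Kc * omega[None, :]  # centered kernel rows against weighted features
    fitted = fitted_rows @ alpha * y_scale + y_center
    return KernelPLSModel(
        spec=spec,
        sigma2=sigma2,
        x_train=np.array(data.x, dtype=float),
        omega=np.asarray(omega, dtype=float),
        stats=stats,
        K_centered=Kc,
        scores=V,
        y_scores=U,
        alpha=alpha,
        proj=proj,
        y_center=y_center,
        y_scale=y_scale,
        n_components=V.shape[1],
        fitted=fitted,
    )


def kpls_fit(
    data: RegressionDataset,
    n_components: int,
    spec: KernelSpec | None = None,
    tol: float = 1e-4,
    normalize_y: bool = False,
) -> KernelPLSModel:
    """Fit unweighted kernel PLS1."""
    spec = spec or KernelSpec()
    sigma2 = resolve_sigma2(data.x) if spec.sigma2 == "auto" else float(spec.sigma2)
    K = _evaluate_kernel(spec, data.x, data.x, sigma2)
    return _fit_weighted_kpls(
        data, spec, n_components, np.ones(data.n), K, sigma2, normalize_y, tol=tol
    )


def kpls_predict(model: KernelPLSModel, x_new: np.ndarray) -> np.ndarray:
    """Dual-form prediction: center the test Gram matrix against the
    training rows and apply the stored dual coefficients."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.x_train.shape[1]:
        raise DimensionError(
            f"expected {model.x_train.shape[1]} columns, got {x_new.shape[1]}"
        )
    return model._test_rows(x_new) @ model.alpha * model.y_scale + model.y_center


@dataclass
class KernelRobustModel:
    """A robust kernel PLS fit: the base model, its observation weights and
    the diagnostic trace that produced them."""

    base: KernelPLSModel
    weights: np.ndarray                      # generalized weights (KPRM) or 0/1 (KPDRGP)
    diagnostics: IRLSState | DRGPResult | None
    n_refits: int

    @property
    def flags(self) -> np.ndarray:
        if isinstance(self.diagnostics, DRGPResult):
            return self.diagnostics.final_flags
        return self.weights <= 0

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return kpls_predict(self.base, x_new)


def kprm_fit(
    data: RegressionDataset,
    config: RobustPLSConfig,
    spec: KernelSpec | None = None,
) -> KernelRobustModel:
    """Kernel PRM: iteratively reweighted kernel PLS.

    The weighted Gram matrix is ``Omega K Omega`` with
    ``Omega_ii = sqrt(w_i)``, the kernel analogue of scaling feature rows
    by the square root of the generalized PRM weight.  Residual weights use
    the MAD scale of all-row residuals; leverage weights use kernel score
    coordinates of all rows (computed through the dual transform, so
    downweighted rows are not artificially shrunk).
    """
    spec = spec or KernelSpec()
    sigma2 = resolve_sigma2(data.x) if spec.sigma2 == "auto" else float(spec.sigma2)
    K = _evaluate_kernel(spec, data.x, data.x, sigma2)

    r0 = data.y - np.median(data.y)
    s0 = mad_scale(r0)
    wr = residual_weights(r0, s0, config.residual_weight) if s0 > 0 else np.ones(data.n)
    try:
        wx = score_weights(data.x, config.score_weight)
    except DegenerateDataError:
        wx = np.ones(data.n)
    w = np.maximum(wr * wx, 1e-12)

    best_model: KernelPLSModel | None = None
    state: IRLSState | None = None
    prev_fitted: np.ndarray | None = None
    n_refits = 0
    for it in range(1, config.max_irls_iter + 1):
        model = _fit_weighted_kpls(
            data, spec, config.n_components, np.sqrt(w), K, sigma2, normalize_y=False
        )
        n_refits += 1
        f = data.y - model.fitted
        scale = mad_scale(f)
        converged = False
        if scale <= 0:
            scale = max(float(np.abs(f).max()), 1e-12)
            converged = True
        wr = residual_weights(f, scale, config.residual_weight)
        V_all = model.K_centered * model.omega[None, :] @ model.proj
        try:
            wx = score_weights(V_all, config.score_weight)
        except DegenerateDataError:
            wx = np.ones(data.n)
        change = (
            np.inf if prev_fitted is None
            else float(np.linalg.norm(model.fitted - prev_fitted)
                       / max(np.linalg.norm(prev_fitted), 1e-12))
        )
        state = IRLSState(
            iteration=it,
            residuals=f,
            scale=float(scale),
            weights=w.copy(),
            coef_change=change,
            converged=converged or change < config.irls_tol,
            objective=float(np.sum(w * f**2)),
            leverage_flags=wx < config.leverage_flag_threshold,
        )
        best_model = model
        prev_fitted = model.fitted
        if state.converged:
            break
        w = np.maximum(wr * wx, 1e-12)
    assert best_model is not None and state is not None
    if not state.converged:
        logger.warning("KPRM IRLS did not converge within %d iterations", config.max_irls_iter)
    return KernelRobustModel(base=best_model, weights=state.weights,
                             diagnostics=state, n_refits=n_refits)


def kpdrgp_fit(
    data: RegressionDataset,
    config: RobustPLSConfig,
    spec: KernelSpec | None = None,
    max_cycles: int = 1,
) -> KernelRobustModel:
    """Kernel partial DRGP: kernel PLS with DRGP screening and refitting.

    Cycle: fit kernel PLS on the surviving rows (0/1 weighted Gram matrix,
    response centered and scaled to unit variance over the survivors), run
    the DRGP diagnostic on the per-observation pair of kernel X-side and
    y-side score coordinates of the survivors, delete newly confirmed
    rows, and refit.  Flags are monotone — once deleted, a row stays
    deleted — and the cycle stops when the flagged set is unchanged or
    ``max_cycles`` is reached.  ``max_cycles=0`` skips the diagnostic
    entirely and returns the plain (y-normalized) kernel fit.

    The y-side score matrix U has rank one beyond the span of V (every
    column is a deflation of the response within span{y, V}), so the pair
    space (v_i, u_i) is represented full-rank — and, by affine invariance
    of the Mahalanobis distance, without loss — as the l+1 columns
    [V, y-normalized].  Including the y-side coordinate is what lets the
    leverage diagnostic see vertical outliers, which are invisible in the
    X-side kernel score geometry alone.
    """
    spec = spec or KernelSpec()
    sigma2 = resolve_sigma2(data.x) if spec.sigma2 == "auto" else float(spec.sigma2)
    K = _evaluate_kernel(spec, data.x, data.x, sigma2)
    n = data.n
    flags = np.zeros(n, dtype=bool)
    model = _fit_weighted_kpls(
        data, spec, config.n_components, np.ones(n), K, sigma2, normalize_y=True
    )
    n_refits = 1
    last_result: DRGPResult | None = None
    for cycle in range(max_cycles):
        if n - int(flags.sum()) < config.n_components + 2:
            raise DegenerateDataError(
                f"only {n - int(flags.sum())} rows survive; too few for "
                f"{config.n_components} components"
            )
        # score every row (deleted ones as test rows through the dual
        # transform) so each cycle re-diagnoses the full dataset against
        # the current fit rather than peeling the surviving boundary
        scores_all = (model.K_centered * model.omega[None, :]) @ model.proj
        y_side = (data.y - model.y_center) / model.y_scale
        pair = np.column_stack([scores_all, y_side])
        last_result = drgp_run(
            pair,
            c=config.potential_c,
            mve_trials=config.mve_trials,
            seed=int((config.seed + 1000003 * cycle) % (2**31 - 1)),
        )
        new = np.flatnonzero(last_result.final_flags & ~flags)
        if new.size == 0:
            break
        flags[new] = True  # monotone: once deleted, a row stays deleted
        omega = (~flags).astype(float)
        model = _fit_weighted_kpls(
            data, spec, config.n_components, omega, K, sigma2, normalize_y=True
        )
        n_refits += 1
    if last_result is None:  # max_cycles == 0: diagnostic disabled
        last_result = DRGPResult(
            rmd2=np.zeros(n), rmd_cutoff=np.inf, suspects=np.array([], dtype=int),
            potentials=np.zeros(n), potential_cutoff=np.inf,
            final_flags=np.zeros(n, dtype=bool), obs_weights=np.ones(n),
        )
    last_result = replace(
        last_result, final_flags=flags.copy(), obs_weights=(~flags).astype(float)
    )
    return KernelRobustModel(base=model, weights=(~flags).astype(float),
                             diagnostics=last_result, n_refits=n_refits)
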