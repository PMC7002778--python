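"""Linear PLS1 via NIPALS, with optional per-observation weights.

This is the algebraic backbone that every robust and kernelized variant in
the package reuses.  The model is the standard univariate-response partial
least squares decomposition

    X = V P' + E,      y = V q + f,

with unit-norm weight vectors W extracted sequentially from the deflated
cross-covariance, scores ``V``, loadings ``P``, and the implied regression
vector ``b = W (P'W)^{-1} q`` applied to column-centered data.

Weighted fits scale rows by the square root of their observation weight and
center with weighted means, so that a weight of zero removes an observation
exactly and the optimized criterion is the weighted residual sum of
squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import RegressionDataset
from .exceptions import DegenerateDataError, DimensionError

logger = logging.getLogger(__name__)

_EPS_WEIGHT_NORM = 1e-12


@dataclass
class PLSModel:
    """A fitted (possibly weighted) linear PLS1 model.

    ``x_scores`` are the scores of the (weight-scaled) training rows used
    during extraction; :meth:`transform` projects unscaled rows, which is
    what leverage diagnostics operate on.
    """

    n_components: int
    x_weights: np.ndarray      # W, (m, l), unit-norm columns
    x_scores: np.ndarray       # V, (n, l), unit-norm columns
    x_loadings: np.ndarray     # P, (m, l)
    y_loadings: np.ndarray     # q, (l,)
    rotations: np.ndarray      # W* = W (P'W)^{-1}, (m, l)
    coef: np.ndarray           # b_pls, (m,)
    x_center: np.ndarray       # (m,)
    y_center: float
    obs_weights: np.ndarray    # (n,), the weights the fit used
    fitted: np.ndarray         # (n,), fitted values for the original rows

    @property
    def inner_coef(self) -> np.ndarray:
        """Inner-relation coefficients; with unit-norm scores these fold
        into ``y_loadings`` and are identically one."""
        return np.ones(self.n_components)

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Project rows onto the latent space: (x - x_center) @ W*."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x_new.shape[1] != self.x_center.shape[0]:
            raise DimensionError(
                f"expected {self.x_center.shape[0]} columns, got {x_new.shape[1]}"
            )
        return (x_new - self.x_center) @ self.rotations

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return pls_predict(self, x_new)


def nipals_fit(
    data: RegressionDataset,
    n_components: int,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> PLSModel:
    """Fit PLS1 by sequential NIPALS extraction with deflation.

    Per component: ``w ∝ X'y`` (for a univariate response the inner power
    loop converges in a single pass, so it is evaluated directly),
    ``v = Xw`` normalized, ``p = X'v``, ``q = y'v``, then ``X ← X - v p'``
    and ``y ← y - v q``.  The sign of each weight vector is fixed by making
    its largest-magnitude element positive, so extracted directions are
    reproducible across runs and platforms.

    ``tol``/``max_iter`` bound the inner loop of the general algorithm; for
    PLS1 they are honored trivially.

    Raises
    ------
    DimensionError
        If ``n_components`` exceeds ``min(n - 1, m)``.
    DegenerateDataError
        If the (weighted) response has essentially zero variance.
    """
    del tol, max_iter  # inner loop is exact for a univariate response
    n, m = data.n, data.m
    l = int(n_components)
    if not 1 <= l <= min(n - 1, m):
        raise DimensionError(
            f"n_components={l} outside [1, min(n-1, m)] = [1, {min(n - 1, m)}]"
        )
    w_obs = data.weights_or_ones()
    x_center, y_center = data.weighted_centers()
    sw = np.sqrt(w_obs)
    X = (data.x - x_center) * sw[:, None]
    y = (data.y - y_center) * sw
    if float(y @ y) <= 1e-24 * max(1.0, float(np.abs(data.y).max()) ** 2):
        raise DegenerateDataError("response has zero variance under the given weights")

    W = np.zeros((m, l))
    V = np.zeros((n, l))
    P = np.zeros((m, l))
    q = np.zeros(l)
    n_kept = 0
    for g in range(l):
        s = X.T @ y
        norm_s = np.linalg.norm(s)
        if norm_s < _EPS_WEIGHT_NORM:
            logger.warning(
                "degenerate weight vector at component %d; returning %d components",
                g + 1, g,
            )
            break
        w = s / norm_s
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:  # deterministic sign convention
            w = -w
        v = X @ w
        norm_v = np.linalg.norm(v)
        if norm_v < _EPS_WEIGHT_NORM:
            logger.warning("degenerate score at component %d; stopping early", g + 1)
            break
        v = v / norm_v
        p = X.T @ v
        qg = float(y @ v)
        X = X - np.outer(v, p)
        y = y - v * qg
        W[:, g], V[:, g], P[:, g], q[g] = w, v, p, qg
        n_kept += 1

    if n_kept == 0:
        raise DegenerateDataError("no PLS component could be extracted")
    W, V, P, q = W[:, :n_kept], V[:, :n_kept], P[:, :n_kept], q[:n_kept]
    rotations = W @ np.linalg.inv(P.T @ W)
    coef = rotations @ q
    fitted = (data.x - x_center) @ coef + y_center
    return PLSModel(
        n_components=n_kept,
        x_weights=W,
        x_scores=V,
        x_loadings=P,
        y_loadings=q,
        rotations=rotations,
        coef=coef,
        x_center=x_center,
        y_center=y_center,
        obs_weights=w_obs,
        fitted=fitted,
    )


def pls_predict(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    """Predict responses for new rows: ``(x - x_center) b + y_center``."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.x_center.shape[0]:
        raise DimensionError(
            f"expected {model.x_center.shape[0]} columns, got {x_new.shape[1]}"
        )
    return (x_new - model.x_center) @ model.coef + model.y_center


def weighted_refit(
    data: RegressionDataset,
    weights: np.ndarray,
    n_components: int,
    tol: float = 1e-4,
) -> PLSModel:
    """Refit PLS1 under new observation weights.

    Equivalent to :func:`nipals_fit` on a dataset whose rows are
    premultiplied by the square root of the weights, with weighted
    centering.  Zero weights delete observations exactly.
    """
    return nipals_fit(data.with_weights(np.asarray(weights, dtype=float)),
                      n_components, tol=tol)
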