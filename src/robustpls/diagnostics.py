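"""MVE robust location/shape and the DRGP leverage diagnostic.

The two-step DRGP (diagnostic robust generalized potential) procedure
confirms multiple high-leverage points on any score matrix:

1. *Screening.* Robust squared Mahalanobis distances ``RM2_i`` from a
   minimum-volume-ellipsoid (MVE) location/shape flag suspects above
   ``median(RM2) + 3 MAD(RM2)`` (plain MAD here, no consistency factor).
2. *Confirmation.* With the suspect group D deleted, group-deleted hat
   diagonals ``w_ii^(-D)`` of ``V (V_R'V_R)^{-1} V'`` give generalized
   potentials ``p_ii* = w/(1-w)`` for retained rows and ``w`` for deleted
   rows.  Suspects whose potential does not exceed
   ``median(p*) + c MAD(p*)/0.6475`` are put back one at a time — smallest
   potential first, recomputing after each return — until every remaining
   suspect exceeds the cut-off.

The two cut-offs deliberately use different MAD scalings (raw in step 1,
divided by 0.6475 in step 2); both are exposed as named helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import RegressionDataset
from .exceptions import DegenerateDataError, DimensionError
from .pls import PLSModel, nipals_fit, weighted_refit
from .robust import RobustPLSConfig, raw_mad, _clip_components

logger = logging.getLogger(__name__)


@dataclass
class MVEEstimate:
    """Robust location and shape from resampling-based MVE."""

    location: np.ndarray     # (l,)
    shape: np.ndarray        # (l, l), symmetric positive definite
    best_volume: float       # log-volume criterion of the winning subset
    n_trials: int
    seed: int


@dataclass
class DRGPResult:
    """Per-observation output of one DRGP pass."""

    rmd2: np.ndarray            # squared robust Mahalanobis distances
    rmd_cutoff: float
    suspects: np.ndarray        # indices flagged in the screening step
    potentials: np.ndarray      # generalized potentials at the final D
    potential_cutoff: float
    final_flags: np.ndarray     # boolean, confirmed high-leverage/outlier rows
    obs_weights: np.ndarray     # 0/1, the complement of final_flags

    @property
    def n_flagged(self) -> int:
        return int(self.final_flags.sum())


def mve_fit(V: np.ndarray, n_trials: int = 500, seed: int = 0) -> MVEEstimate:
    """Classical resampling MVE on the rows of V.

    Each trial draws an elemental (l+1)-subset, computes its mean and
    covariance, and inflates the ellipsoid to cover h = floor((n+l+1)/2)
    points; the minimum-volume candidate wins.  The reported location and
    shape are the classical moments of the h points covered by the winning
    ellipsoid (as in the classical MINVOL-style implementations — the raw
    elemental covariance is far too anisotropic to use directly), rescaled
    by ``median(d^2) / chi2_{0.5, l}`` for consistency at the normal
    model.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, l = V.shape
    if n <= l + 1:
        raise DegenerateDataError(f"MVE needs n > l + 1 (got n={n}, l={l})")
    h = (n + l + 1) // 2
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_trials):
        idx = rng.choice(n, size=l + 1, replace=False)
        sub = V[idx]
        loc = sub.mean(axis=0)
        cov = np.atleast_2d(np.cov(sub, rowvar=False))
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(logdet):
            continue
        try:
            diff = V - loc
            d2 = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
        except np.linalg.LinAlgError:
            continue
        s = float(np.sort(d2)[h - 1])  # inflation factor covering h points
        if s <= 0:
            continue
        log_volume = logdet + l * np.log(s)
        if best is None or log_volume < best[0]:
            best = (log_volume, d2)
    if best is None:
        raise DegenerateDataError("every MVE elemental subset was singular")
    log_volume, d2_best = best
    covered = np.argsort(d2_best)[:h]
    loc = V[covered].mean(axis=0)
    cov = np.atleast_2d(np.cov(V[covered], rowvar=False))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise DegenerateDataError("covered-subset covariance is singular")
    diff = V - loc
    d2 = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
    shape = cov * (float(np.median(d2)) / stats.chi2.ppf(0.5, df=l))
    shape = 0.5 * (shape + shape.T)
    return MVEEstimate(location=loc, shape=shape, best_volume=float(log_volume),
                       n_trials=n_trials, seed=seed)


def robust_mahalanobis(V: np.ndarray, est: MVEEstimate) -> np.ndarray:
    """Squared distances (v_i - m)' C^{-1} (v_i - m) under the MVE estimate."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if V.shape[1] != est.location.shape[0]:
        raise DimensionError("score dimension does not match the MVE estimate")
    diff = V - est.location
    try:
        from scipy.linalg import cho_factor, cho_solve
        cf = cho_factor(est.shape, lower=True)
        sol = cho_solve(cf, diff.T)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(est.shape)
        logger.warning("ill-conditioned MVE shape (cond=%.3g); using eigh solve", cond)
        vals, vecs = np.linalg.eigh(est.shape)
        vals = np.maximum(vals, 1e-12 * vals.max())
        sol = vecs @ ((vecs.T @ diff.T) / vals[:, None])
    return np.einsum("ij,ij->i", diff, sol.T)


def rmd_cutoff(rmd2: np.ndarray) -> float:
    """Screening cut-off: median(RM2) + 3 * raw MAD(RM2)."""
    rmd2 = np.asarray(rmd2, dtype=float)
    if rmd2.size < 3:
        raise DegenerateDataError("rmd_cutoff needs at least three distances")
    return float(np.median(rmd2) + 3.0 * raw_mad(rmd2))


def generalized_potentials(V: np.ndarray, deleted: np.ndarray) -> np.ndarray:
    """Generalized potentials for all rows, given a deleted index set.

    ``w_ii^(-D)`` is the i-th diagonal of ``V (V_R'V_R)^{-1} V'`` where R is
    the retained set; the potential is ``w/(1-w)`` for retained rows and
    ``w`` itself for deleted rows.  With D empty this reduces to
    ``h_ii/(1-h_ii)`` on ordinary hat diagonals.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, l = V.shape
    deleted = np.asarray(deleted, dtype=int)
    mask_deleted = np.zeros(n, dtype=bool)
    mask_deleted[deleted] = True
    VR = V[~mask_deleted]
    if VR.shape[0] <= l:
        raise DegenerateDataError(
            "retained set too small to invert V_R'V_R; shrink the deleted set"
        )
    G = VR.T @ VR
    try:
        sol = np.linalg.solve(G, V.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "singular V_R'V_R; shrink the deleted set"
        ) from exc
    w = np.einsum("ij,ji->i", V, sol)
    p = np.empty(n)
    retained = ~mask_deleted
    denom = 1.0 - w[retained]
    with np.errstate(divide="ignore"):
        p[retained] = np.where(denom > 1e-12, w[retained] / np.maximum(denom, 1e-300), np.inf)
    p[mask_deleted] = w[mask_deleted]
    return p


def potential_cutoff(potentials: np.ndarray, c: float = 3.0) -> float:
    """Confirmation cut-off: median(p*) + c * MAD(p*)/0.6475."""
    p = np.asarray(potentials, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size == 0:
        raise DegenerateDataError("no finite potentials")
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med))) / 0.6475
    return med + c * mad


def drgp_run(
    V: np.ndarray,
    c: float = 3.0,
    mve_trials: int = 500,
    seed: int = 0,
) -> DRGPResult:
    """Run the full two-step DRGP with its put-back loop on a score matrix."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, l = V.shape
    est = mve_fit(V, n_trials=mve_trials, seed=seed)
    rmd2 = robust_mahalanobis(V, est)
    cutoff = rmd_cutoff(rmd2)
    suspects = np.flatnonzero(rmd2 > cutoff)

    # the retained set must stay large enough to invert V_R'V_R
    max_deleted = n - l - 1
    if suspects.size > max_deleted:
        keep = np.argsort(rmd2[suspects])[::-1][:max_deleted]
        logger.warning(
            "screening flagged %d of %d rows; keeping the %d most distant suspects",
            suspects.size, n, max_deleted,
        )
        suspects = np.sort(suspects[keep])

    deleted = list(suspects)
    potentials = generalized_potentials(V, np.asarray(deleted, dtype=int))
    cut = potential_cutoff(potentials, c)
    while deleted:
        below = [i for i in deleted if potentials[i] <= cut]
        if not below:
            break
        put_back = min(below, key=lambda i: potentials[i])
        deleted.remove(put_back)
        potentials = generalized_potentials(V, np.asarray(deleted, dtype=int))
        cut = potential_cutoff(potentials, c)

    flags = np.zeros(n, dtype=bool)
    flags[deleted] = True
    return DRGPResult(
        rmd2=rmd2,
        rmd_cutoff=cutoff,
        suspects=suspects,
        potentials=potentials,
        potential_cutoff=cut,
        final_flags=flags,
        obs_weights=(~flags).astype(float),
    )


def prdrgp_fit(
    data: RegressionDataset,
    config: RobustPLSConfig,
) -> tuple[PLSModel, DRGPResult]:
    """Linear PLS with DRGP screening on its score matrix.

    Fits plain PLS, runs DRGP on the (column-centered, unweighted) score
    matrix, then refits with the resulting 0/1 weights so confirmed rows
    are excluded exactly.
    """
    l = _clip_components(data, config.n_components)
    model = nipals_fit(data, l)
    V = model.transform(data.x)
    result = drgp_run(V, c=config.potential_c, mve_trials=config.mve_trials,
                      seed=config.seed)
    if result.n_flagged == 0:
        return model, result
    refit = weighted_refit(data, result.obs_weights, l)
    return refit, result
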