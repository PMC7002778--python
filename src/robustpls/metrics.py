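"""Desirability-index metrics for calibration models.

Definitions follow chemometrics convention:

* RMSE  = sqrt(mean(e^2))            with e = y_true - y_pred
* Bias  = mean(e)
* SE    = SEP = sqrt(sum((e - bias)^2) / (n - 1))  (bias-corrected)
* R2    = squared Pearson correlation between measured and predicted
* RPD   = sd(y_true) / SE

An optional nonnegative weight vector produces the weighted analogues
(weighted means and weighted correlation, with an effective-n correction
for SE); robust fits report their training metrics this way so that
deleted or downweighted observations do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, DimensionError


@dataclass
class MetricsReport:
    rmse: float
    r2: float
    rpd: float
    bias: float
    se: float
    n: int
    dataset_label: str = ""

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "r2": self.r2, "rpd": self.rpd,
                "bias": self.bias, "se": self.se, "n": self.n}


def _alternative_r2(y_true: np.ndarray, y_pred: np.ndarray, w: np.ndarray) -> float:
    """1 - SSE/SST, the regression-through-truth alternative definition."""
    yb = np.sum(w * y_true) / w.sum()
    sse = float(np.sum(w * (y_true - y_pred) ** 2))
    sst = float(np.sum(w * (y_true - yb) ** 2))
    if sst <= 0:
        raise DegenerateDataError("y_true has zero variance")
    return 1.0 - sse / sst


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    weights: np.ndarray | None = None,
    label: str = "",
    r2_definition: str = "pearson",
) -> MetricsReport:
    """Compute the desirability-index report for one prediction set.

    ``r2_definition`` is ``"pearson"`` (default) or ``"explained"``
    (1 - SSE/SST).  A constant ``y_true`` raises; a constant ``y_pred``
    yields R2 = 0 by convention.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise DimensionError("y_true and y_pred must have equal lengths")
    n = y_true.size
    if n < 2:
        raise DegenerateDataError("metrics need at least two observations")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape[0] != n or np.any(w < 0) or not np.any(w > 0):
        raise DegenerateDataError("weights must be nonnegative with a positive sum")
    sw = w.sum()
    # effective sample size for the (n-1) style corrections
    n_eff = sw**2 / float(np.sum(w**2))
    if n_eff <= 1:
        raise DegenerateDataError("fewer than two effective observations")

    e = y_true - y_pred
    rmse = float(np.sqrt(np.sum(w * e**2) / sw))
    bias = float(np.sum(w * e) / sw)
    se = float(np.sqrt(np.sum(w * (e - bias) ** 2) / sw * n_eff / (n_eff - 1)))

    yt_c = y_true - np.sum(w * y_true) / sw
    yp_c = y_pred - np.sum(w * y_pred) / sw
    var_t = float(np.sum(w * yt_c**2))
    var_p = float(np.sum(w * yp_c**2))
    if var_t <= 0:
        raise DegenerateDataError("y_true has zero variance; R2/RPD undefined")
    if r2_definition == "explained":
        r2 = _alternative_r2(y_true, y_pred, w)
    elif var_p <= 0:
        r2 = 0.0
    else:
        r2 = float((np.sum(w * yt_c * yp_c)) ** 2 / (var_t * var_p))

    sd_true = float(np.sqrt(var_t / sw * n_eff / (n_eff - 1)))
    rpd = float(sd_true / se) if se > 0 else float("inf")
    return MetricsReport(rmse=rmse, r2=r2, rpd=rpd, bias=bias, se=se,
                         n=n, dataset_label=label)
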