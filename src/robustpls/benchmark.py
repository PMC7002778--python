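"""The sine calibration study: fit the full method ladder and summarize.

``run_sine_study`` repeats the contaminated-sine experiment over seeded
replicates: simulate a 41-point training set with 7 injected vertical
outliers and a 101-point noisy test grid, fit each requested method,
and score training and test predictions with the desirability indices.
Training metrics are weighted by each method's final observation weights
(all ones for the non-robust fits, 0/1 for the DRGP-based fits), so a
robust method is judged on the observations it actually retained; test
metrics are always unweighted.

Replicate results are aggregated by the median, which is robust to an
occasional non-converged replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .data import RegressionDataset
from .exceptions import RobustPLSError
from .kernel import KernelSpec, kpdrgp_fit, kpls_fit, kprm_fit
from .metrics import compute_metrics
from .pls import nipals_fit
from .robust import RobustPLSConfig, gm6_fit, prm_fit, prmm_fit
from .diagnostics import prdrgp_fit
from .simulate import SineSimConfig, simulate_sine, simulate_sine_test

logger = logging.getLogger(__name__)

METHODS = ("pls", "prm", "prmm", "prgm6", "prdrgp", "kpls", "kprm", "kpdrgp")
KERNEL_METHODS = ("kpls", "kprm", "kpdrgp")

DEFAULT_KERNEL_COMPONENTS = 3  # default latent dimension for n = 41 kernel fits


@dataclass
class FitResult:
    """One fitted method: predictions, per-row weights and outlier flags."""

    method: str
    fitted: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray]
    weights: np.ndarray
    flags: np.ndarray | None
    model: object


def fit_method(
    method: str,
    data: RegressionDataset,
    n_components: int,
    seed: int = 0,
    config: RobustPLSConfig | None = None,
    kernel: KernelSpec | None = None,
) -> FitResult:
    """Fit one named method and return a uniform result wrapper.

    For linear methods the component count is clipped to ``min(n-1, m)``;
    for kernel methods to ``n-1``.
    """
    if method not in METHODS:
        raise RobustPLSError(f"unknown method {method!r}; choose from {METHODS}")
    cfg = config or RobustPLSConfig()
    cfg = replace(cfg, n_components=n_components, seed=seed)
    ones = np.ones(data.n)
    if method == "pls":
        l = max(1, min(n_components, data.n - 1, data.m))
        model = nipals_fit(data, l)
        return FitResult(method, model.fitted, model.predict, ones, None, model)
    if method == "prm":
        model, state = prm_fit(data, cfg)
        return FitResult(method, model.fitted, model.predict, state.weights, None, model)
    if method == "prmm":
        model, state = prmm_fit(data, cfg)
        return FitResult(method, model.fitted, model.predict, state.weights, None, model)
    if method == "prgm6":
        model = gm6_fit(data, cfg)
        return FitResult(method, model.fitted, model.predict, model.obs_weights, None, model)
    if method == "prdrgp":
        model, diag = prdrgp_fit(data, cfg)
        return FitResult(method, model.fitted, model.predict, diag.obs_weights,
                         diag.final_flags, model)
    if method == "kpls":
        model = kpls_fit(data, n_components, spec=kernel)
        return FitResult(method, model.fitted, model.predict, ones, None, model)
    if method == "kprm":
        rm = kprm_fit(data, cfg, spec=kernel)
        return FitResult(method, rm.base.fitted, rm.predict, rm.weights, None, rm)
    rm = kpdrgp_fit(data, cfg, spec=kernel)
    return FitResult(method, rm.base.fitted, rm.predict, rm.weights, rm.flags, rm)


def _replicate_seed(seed: int, rep: int) -> int:
    return int((seed * 1000003 + 7919 * rep) % (2**31 - 1))


def run_sine_study(
    replicates: int = 25,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    config: SineSimConfig | None = None,
    kernel_components: int = DEFAULT_KERNEL_COMPONENTS,
    linear_components: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the replicated sine study.

    Returns ``(metrics, recovery)``: a long-format metrics table with one
    row per (replicate, method, split) and, for the flagging methods, a
    recovery table with true/false outlier counts per replicate.
    """
    base = config or SineSimConfig()
    rows: list[dict] = []
    recovery: list[dict] = []
    for rep in range(replicates):
        rep_seed = _replicate_seed(seed, rep)
        cfg = replace(base, seed=rep_seed)
        train = simulate_sine(cfg)
        test = simulate_sine_test(cfg)
        data = train.to_regression()
        for method in methods:
            l = kernel_components if method in KERNEL_METHODS else (
                linear_components or kernel_components)
            try:
                fit = fit_method(method, data, l, seed=rep_seed)
            except RobustPLSError as exc:
                logger.warning("replicate %d: %s failed: %s", rep, method, exc)
                continue
            rep_train = compute_metrics(train.y, fit.fitted, weights=fit.weights,
                                        label="training")
            rep_test = compute_metrics(test.y, fit.predict(test.x), label="testing")
            for split, report in (("training", rep_train), ("testing", rep_test)):
                rows.append({"replicate": rep, "method": method, "split": split,
                             **report.as_dict()})
            if fit.flags is not None:
                recovery.append({
                    "replicate": rep,
                    "method": method,
                    "n_flagged": int(fit.flags.sum()),
                    "n_true_flagged": int((fit.flags & train.truth_flags).sum()),
                    "n_false_flagged": int((fit.flags & ~train.truth_flags).sum()),
                    "n_injected": int(train.truth_flags.sum()),
                })
    return pd.DataFrame(rows), pd.DataFrame(recovery)


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregated summary shaped like the study's results table:
    one row per (split, metric), one column per method."""
    long = metrics.melt(
        id_vars=["replicate", "method", "split"],
        value_vars=["rmse", "r2", "rpd", "bias", "se"],
        var_name="metric",
    )
    table = long.pivot_table(index=["split", "metric"], columns="method",
                             values="value", aggfunc="median")
    ordered = [m for m in METHODS if m in table.columns]
    return table[ordered]


def run_sine_benchmark(
    config: SineSimConfig | None = None,
    methods: tuple[str, ...] = METHODS,
    replicates: int = 25,
    seed: int = 0,
    out_dir: str | Path | None = None,
    kernel_components: int = DEFAULT_KERNEL_COMPONENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the study and optionally write long and summary CSV files."""
    metrics, recovery = run_sine_study(
        replicates=replicates, seed=seed, methods=methods, config=config,
        kernel_components=kernel_components,
    )
    summary = summarize(metrics)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "sine_metrics_long.csv", index=False)
        summary.to_csv(out / "sine_summary.csv")
        if len(recovery):
            recovery.to_csv(out / "sine_outlier_recovery.csv", index=False)
    return metrics, summary
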