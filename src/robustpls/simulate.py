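"""Synthetic data generators.

Two study designs are provided:

* a one-predictor sine calibration problem, ``y = sin(-3/4 x) + e`` on
  ``x in [0, 10]``, with a small number of gross vertical outliers injected
  at fixed sample positions of the sorted training set — a hard nonlinearity
  test on which linear calibration methods are expected to fail; and
* NIR-like spectra built from overlapping Gaussian absorption peaks whose
  amplitudes are tied (possibly nonlinearly) to a latent concentration, with
  multiplicative scatter and a smooth additive baseline, optionally
  contaminated with response outliers and high-leverage spectra.

Every generator takes an explicit integer seed and is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .data import RegressionDataset
from .exceptions import ConfigurationError

SINE_FREQUENCY = -0.75  # y = sin(-3/4 x)

DEFAULT_OUTLIER_INDICES = (10, 12, 18, 19, 28, 33, 36)  # 1-based


def _derive_seed(seed: int, salt: int) -> int:
    """Mix a user seed with a stream salt, staying below 2**31."""
    return int((seed * 2654435761 + salt) % (2**31 - 1))


@dataclass(frozen=True)
class SineSimConfig:
    """Configuration of the sine calibration simulation.

    ``outlier_indices`` are 1-based positions within the x-sorted training
    set.  ``outlier_shift`` is the magnitude of the injected vertical shift;
    ``None`` draws an independent Uniform(1, 2) magnitude per outlier (the
    sine has unit amplitude, so shifts of 1-2 response units are unambiguous
    vertical outliers).  The shift is directed away from the curve, i.e.
    opposite in sign to the noiseless response.
    """

    n_train: int = 41
    n_test: int = 101
    x_range: tuple[float, float] = (0.0, 10.0)
    noise_sd: float = 0.05
    outlier_indices: tuple[int, ...] = DEFAULT_OUTLIER_INDICES
    outlier_shift: float | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.x_range
        if not lo < hi:
            raise ConfigurationError("x_range lower bound must be below upper bound")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.n_train < 2 or self.n_test < 2:
            raise ConfigurationError("need at least two train and test samples")
        idx = tuple(self.outlier_indices)
        if len(set(idx)) != len(idx):
            raise ConfigurationError("outlier_indices must be distinct")
        for i in idx:
            if not 1 <= i <= self.n_train:
                raise ConfigurationError(
                    f"outlier index {i} outside [1, {self.n_train}]"
                )
        if self.outlier_shift is not None and self.outlier_shift <= 0:
            raise ConfigurationError("outlier_shift must be positive")


@dataclass
class SimulatedDataset:
    """A generated dataset together with its ground truth.

    ``truth_flags`` marks the rows whose response (or spectrum) was
    deliberately corrupted; ``y_true`` is the noiseless, uncontaminated
    response, kept for diagnostics.
    """

    x: np.ndarray
    y: np.ndarray
    truth_flags: np.ndarray
    y_true: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def to_regression(self) -> RegressionDataset:
        return RegressionDataset(self.x, self.y)


def sine_truth(x: np.ndarray) -> np.ndarray:
    """Noiseless response of the sine study."""
    return np.sin(SINE_FREQUENCY * np.asarray(x, dtype=float))


def simulate_sine(config: SineSimConfig) -> SimulatedDataset:
    """Generate the contaminated sine training set.

    Training abscissae are iid Uniform over ``x_range`` and sorted
    ascending, the response is ``sin(-3/4 x)`` plus N(0, noise_sd^2) noise,
    and the configured rows receive an additional vertical shift directed
    away from the curve.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    x = np.sort(rng.uniform(*config.x_range, size=config.n_train))
    y_true = sine_truth(x)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_train) if config.noise_sd > 0 else np.zeros(config.n_train)
    y = y_true + noise
    flags = np.zeros(config.n_train, dtype=bool)
    for idx1 in config.outlier_indices:
        i = idx1 - 1
        mag = config.outlier_shift if config.outlier_shift is not None else rng.uniform(1.0, 2.0)
        sign = -1.0 if y_true[i] >= 0 else 1.0  # push across and away from the curve
        y[i] = y[i] + sign * mag
        flags[i] = True
    meta = {"kind": "sine_train", "config": asdict(config)}
    return SimulatedDataset(x[:, None], y, flags, y_true, meta)


def simulate_sine_test(config: SineSimConfig) -> SimulatedDataset:
    """Generate the sine test set: an equally spaced grid, no outliers.

    The test responses carry the same N(0, noise_sd^2) noise model as the
    training set; the noiseless truth is available as ``y_true``.
    """
    config.validate()
    rng = np.random.default_rng(_derive_seed(config.seed, 101))
    x = np.linspace(*config.x_range, config.n_test)
    y_true = sine_truth(x)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_test) if config.noise_sd > 0 else np.zeros(config.n_test)
    meta = {"kind": "sine_test", "config": asdict(config)}
    return SimulatedDataset(x[:, None], y_true + noise, np.zeros(config.n_test, dtype=bool), y_true, meta)


def _saturating_link(y: np.ndarray) -> np.ndarray:
    # bounded, concave link on the percentage scale; maps [0, 100] -> [0, 1]
    return (1.0 - np.exp(-y / 35.0)) / (1.0 - np.exp(-100.0 / 35.0))


def simulate_nir(
    n: int = 960,
    m: int = 489,
    n_peaks: int = 6,
    scatter_sd: float = 0.05,
    baseline_sd: float = 0.1,
    nonlinearity: float = 0.5,
    contamination_rate: float = 0.05,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate NIR-like spectra with a latent concentration response.

    Each spectrum is a sum of ``n_peaks`` Gaussian absorption bands whose
    amplitudes depend on a latent concentration ``y`` (a bounded percentage)
    through a mixture of a linear and a saturating link controlled by
    ``nonlinearity`` in [0, 1].  Rows are degraded by multiplicative scatter
    ``(1 + N(0, scatter_sd^2))`` and a smooth additive quadratic baseline
    with N(0, baseline_sd^2) coefficients.  A ``contamination_rate``
    fraction of rows is corrupted — alternately a gross response shift
    (outlier) and an inflated/spiked spectrum (high leverage) — and flagged
    in ``truth_flags``.
    """
    if min(n, m, n_peaks) < 1:
        raise ConfigurationError("n, m and n_peaks must all be at least 1")
    if not 0.0 <= contamination_rate < 0.5:
        raise ConfigurationError("contamination_rate must lie in [0, 0.5)")
    if scatter_sd < 0 or baseline_sd < 0:
        raise ConfigurationError("scatter_sd and baseline_sd must be nonnegative")
    if not 0.0 <= nonlinearity <= 1.0:
        raise ConfigurationError("nonlinearity must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, m)  # normalized wavelength axis
    centers = rng.uniform(0.05, 0.95, size=n_peaks)
    widths = rng.uniform(0.03, 0.12, size=n_peaks)
    profiles = np.exp(-0.5 * ((t[None, :] - centers[:, None]) / widths[:, None]) ** 2)

    y = rng.uniform(10.0, 90.0, size=n)
    base = rng.uniform(0.1, 0.3, size=n_peaks)
    gain = rng.uniform(0.5, 1.5, size=n_peaks)
    link = (1.0 - nonlinearity) * (y / 100.0) + nonlinearity * _saturating_link(y)
    amplitudes = base[None, :] + np.outer(link, gain)
    x = amplitudes @ profiles

    if baseline_sd > 0:
        basis = np.vstack([np.ones(m), t, t**2])
        coefs = rng.normal(0.0, baseline_sd, size=(n, 3))
        x = x + coefs @ basis
    if scatter_sd > 0:
        x = x * (1.0 + rng.normal(0.0, scatter_sd, size=n))[:, None]

    y_true = y.copy()
    flags = np.zeros(n, dtype=bool)
    n_bad = int(round(contamination_rate * n))
    if n_bad > 0:
        bad = rng.choice(n, size=n_bad, replace=False)
        for k, i in enumerate(bad):
            flags[i] = True
            if k % 2 == 0:  # response outlier
                y[i] = y[i] + rng.choice([-1.0, 1.0]) * rng.uniform(15.0, 30.0)
            else:  # high-leverage spectrum
                x[i] = x[i] * rng.uniform(1.5, 2.5) + rng.uniform(0.5, 1.0)
    meta = {
        "kind": "nir",
        "n": n,
        "m": m,
        "n_peaks": n_peaks,
        "scatter_sd": scatter_sd,
        "baseline_sd": baseline_sd,
        "nonlinearity": nonlinearity,
        "contamination_rate": contamination_rate,
        "seed": seed,
    }
    return SimulatedDataset(x, y, flags, y_true, meta)
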