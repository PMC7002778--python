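"""Core data container shared by every estimator in the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, DegenerateDataError


@dataclass
class RegressionDataset:
    """A paired predictor matrix and univariate response.

    Parameters
    ----------
    x : ndarray of shape (n, m)
        Predictor matrix, e.g. NIR absorbance spectra with one column per
        wavelength.
    y : ndarray of shape (n,)
        Response vector (e.g. an oil-content percentage).
    obs_weights : ndarray of shape (n,), optional
        Nonnegative per-observation weights.  ``None`` means all ones.
        A weight of zero removes the observation from any weighted fit.
    """

    x: np.ndarray
    y: np.ndarray
    obs_weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape[0] != self.y.shape[0]:
            raise DimensionError(
                f"x has {self.x.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.obs_weights is not None:
            w = np.asarray(self.obs_weights, dtype=float).ravel()
            if w.shape[0] != self.y.shape[0]:
                raise DimensionError("obs_weights length does not match n")
            if np.any(w < 0):
                raise DegenerateDataError("obs_weights must be nonnegative")
            if not np.any(w > 0):
                raise DegenerateDataError("obs_weights are all zero")
            self.obs_weights = w

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]

    def weights_or_ones(self) -> np.ndarray:
        if self.obs_weights is None:
            return np.ones(self.n)
        return self.obs_weights

    def weighted_centers(self) -> tuple[np.ndarray, float]:
        """Weighted column means of ``x`` and weighted mean of ``y``."""
        w = self.weights_or_ones()
        s = w.sum()
        return (w @ self.x) / s, float(w @ self.y / s)

    def with_weights(self, weights: np.ndarray) -> "RegressionDataset":
        return RegressionDataset(self.x, self.y, obs_weights=weights)
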