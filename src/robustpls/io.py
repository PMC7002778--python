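"""CSV/YAML input and output.

Datasets travel as plain CSV with columns ``x_1..x_m``, ``y`` and an
optional ``is_outlier`` truth column; generation metadata goes to a YAML
sidecar next to the data file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import RegressionDataset
from .exceptions import ConfigurationError
from .simulate import SimulatedDataset


def read_dataset(path: str | Path, response: str = "y") -> RegressionDataset:
    """Read a delimited dataset; every non-reserved column is a predictor.

    Raises a parse error naming the offending column/line for ragged or
    non-numeric input, and an explicit error if the response column is
    missing.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if response not in frame.columns:
        raise ConfigurationError(
            f"{path} has no response column named {response!r}; "
            f"columns are {list(frame.columns)[:8]}..."
        )
    reserved = {response, "is_outlier", "id"}
    x_cols = [c for c in frame.columns if c not in reserved]
    sub = frame[x_cols + [response]]
    bad = sub.columns[~sub.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ConfigurationError(f"non-numeric columns in {path}: {list(bad)}")
    if sub.isna().any().any():
        col = sub.columns[sub.isna().any()][0]
        line = int(sub[sub[col].isna()].index[0]) + 2  # header + 1-based
        raise ConfigurationError(f"missing value in column {col!r} near line {line} of {path}")
    return RegressionDataset(sub[x_cols].to_numpy(float), sub[response].to_numpy(float))


def write_dataset(path: str | Path, dataset: SimulatedDataset) -> None:
    """Write a simulated dataset as CSV plus a YAML metadata sidecar."""
    path = Path(path)
    m = dataset.x.shape[1]
    frame = pd.DataFrame(dataset.x, columns=[f"x_{j + 1}" for j in range(m)])
    frame["y"] = dataset.y
    frame["is_outlier"] = dataset.truth_flags.astype(int)
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(".meta.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(dataset.meta, fh, default_flow_style=False)


def write_predictions(path: str | Path, table: pd.DataFrame) -> None:
    """Write a prediction table (id, y_hat, flag, weight, ...) as CSV."""
    pd.DataFrame(table).to_csv(path, index=False)
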