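"""Regression evaluation metrics: RMSE, MAE and MAPE.

All three are computed over the n evaluated samples:

    RMSE = sqrt( (1/n) Σ (y_i − ŷ_i)² )        [label units]
    MAE  = (1/n) Σ |y_i − ŷ_i|                  [label units]
    MAPE = (1/n) Σ |y_i − ŷ_i| / y_i            [dimensionless fraction]

MAPE divides by the true label, so it is undefined whenever a label is zero;
in that case RMSE/MAE are still reported and the report flags MAPE as
undefined (NaN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    mape: float            # NaN when undefined
    n: int
    mape_defined: bool = True

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae,
                "mape": None if not self.mape_defined else self.mape, "n": self.n}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compute_metrics(labels, predictions) -> MetricsReport:
    """RMSE/MAE/MAPE of predictions against true labels."""
    y = np.asarray(labels, dtype=np.float64)
    yh = np.asarray(predictions, dtype=np.float64)
    if y.shape != yh.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("labels and predictions must be equal-length non-empty 1-D arrays")
    err = y - yh
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.any(y == 0):
        return MetricsReport(rmse=rmse, mae=mae, mape=float("nan"), n=y.size, mape_defined=False)
    mape = float(np.mean(np.abs(err) / np.abs(y)))
    return MetricsReport(rmse=rmse, mae=mae, mape=mape, n=y.size)


def residuals_frame(labels, predictions, names=None) -> pd.DataFrame:
    """Per-sample residual table for CSV export."""
    y = np.asarray(labels, dtype=np.float64)
    yh = np.asarray(predictions, dtype=np.float64)
    frame = pd.DataFrame({
        "label": y,
        "prediction": yh,
        "residual": yh - y,
        "abs_error": np.abs(yh - y),
    })
    if names is not None:
        frame.insert(0, "filename", list(names))
    return frame
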