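"""Evaluation metric suite for FPAR and NPP validation.

Implements the coefficient of determination R², explained variance score
(EVS, with population 1/n variances), mean squared error, root mean
squared error, mean absolute error and mean absolute percentage error
(reported in percent). Metrics that are undefined for a given input
(MAPE with a zero observation, R²/EVS with constant observations) are
carried as ``None`` with an explanatory flag, never silently dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class EvalReport:
    """Goodness-of-fit report for one observed/predicted pair of vectors."""

    r2: float | None
    evs: float | None
    mse: float
    rmse: float
    mae: float
    mape: float | None  # percent
    n: int
    flags: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "evs": self.evs, "mse": self.mse, "rmse": self.rmse,
            "mae": self.mae, "mape": self.mape, "n": self.n, "flags": self.flags,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def evaluate(observed, predicted) -> EvalReport:
    """Compute the full metric suite.

    Parameters
    ----------
    observed, predicted : array-like, same length >= 2
        Reference values y and model predictions y-hat.
    """
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("non-finite values in input")

    n = y.size
    resid = y - yhat
    mse = float(np.mean(resid ** 2))
    mae = float(np.mean(np.abs(resid)))
    rmse = math.sqrt(mse)
    flags: dict[str, str] = {}

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = evs = None
        flags["r2"] = flags["evs"] = "undefined: observed values have zero variance"
    else:
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        evs = 1.0 - float(np.var(resid)) / float(np.var(y))

    if np.any(y == 0.0):
        mape = None
        flags["mape"] = "undefined: observed vector contains zeros"
    else:
        mape = float(np.mean(np.abs(resid / y))) * 100.0

    return EvalReport(r2=r2, evs=evs, mse=mse, rmse=rmse, mae=mae,
                      mape=mape, n=n, flags=flags)
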