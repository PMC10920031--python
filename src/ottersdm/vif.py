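"""Stepwise variance-inflation-factor screening of the covariate table.

VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing covariate j (with an
intercept) on all other covariates.  Stepwise elimination repeatedly drops
the single worst offender until every remaining VIF is at or below the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError

#: R^2 values this close to 1 are treated as exact collinearity
_COLLINEAR_R2 = 1.0 - 1e-10


@dataclass
class VifStep:
    step: int
    vifs: dict[str, float]
    dropped: str | None


@dataclass
class VifReport:
    steps: list[VifStep]
    retained: list[str]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "retained": self.retained,
            "steps": [{"step": s.step, "vifs": s.vifs, "dropped": s.dropped}
                      for s in self.steps],
        }


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    arr = np.asarray(table, float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def vif(table) -> dict[str, float]:
    """Variance inflation factor of each column of a cell-by-covariate table.

    Exact collinearity yields ``inf``; a zero-variance column is an error.
    """
    df = _as_frame(table)
    if df.shape[1] < 2:
        raise ArgumentError("need at least 2 covariates")
    if df.shape[0] < df.shape[1] + 1:
        raise ArgumentError("need more rows than covariates")
    X = df.to_numpy(float)
    Xc = X - X.mean(axis=0)
    sst = (Xc**2).sum(axis=0)
    for j, name in enumerate(df.columns):
        if sst[j] == 0:
            raise ArgumentError(f"covariate {name!r} has zero variance")
    out: dict[str, float] = {}
    for j, name in enumerate(df.columns):
        others = np.delete(Xc, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, Xc[:, j], rcond=None)
        resid = Xc[:, j] - others @ coef
        r2 = 1.0 - (resid**2).sum() / sst[j]
        out[name] = float("inf") if r2 >= _COLLINEAR_R2 else 1.0 / (1.0 - r2)
    return out


def stepwise_vif(table, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the largest-VIF covariate while any exceeds threshold.

    Ties are broken toward the earlier column in input order.  Dropping the
    second-to-last covariate (leaving a single column, for which VIF is
    undefined) raises: the threshold is too strict for the table.
    """
    df = _as_frame(table)
    steps: list[VifStep] = []
    current = df
    step = 0
    while True:
        vifs = vif(current)
        worst = max(vifs.values())
        if worst <= threshold:
            steps.append(VifStep(step=step, vifs=vifs, dropped=None))
            break
        # first column attaining the max (ties -> earlier input order)
        dropped = next(name for name in current.columns if vifs[name] == worst)
        steps.append(VifStep(step=step, vifs=vifs, dropped=dropped))
        current = current.drop(columns=[dropped])
        step += 1
        if current.shape[1] < 2:
            raise DegenerateInputError(
                f"threshold {threshold} eliminates all covariates")
    return VifReport(steps=steps, retained=list(current.columns),
                     threshold=float(threshold))
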