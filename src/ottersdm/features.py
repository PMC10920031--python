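"""Feature construction and default regularization for the MaxEnt model.

Covariates are min-max scaled to [0, 1] over the training sample (presence
plus background); features derive from the scaled value z:

* L (linear):     z itself
* Q (quadratic):  z**2
* H (hinge):      forward hinges max(0, (z - k)/(1 - k)) and reverse hinges
                  max(0, (k - z)/k) at evenly spaced interior knots k

Every feature lies in [0, 1]; at projection time covariate values are
clamped to the training bounds before scaling, so projected features stay
in [0, 1] as well.  Feature columns constant over the training sample are
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError

log = logging.getLogger(__name__)

FEATURE_SETS = ("L", "LQ", "H", "LQH")
#: canonical ordering used for selection tie-breaks
FEATURE_SET_ORDER = {fs: i for i, fs in enumerate(FEATURE_SETS)}

#: per-class default regularization schedule, interpolated on the number of
#: presences with flat extrapolation beyond the anchors; hinge is constant
REG_SCHEDULE = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "hinge": ([0, 1], [0.5, 0.5]),
}


@dataclass
class FeatureSpec:
    """Feature-class choice, penalty multiplier, and training scaling bounds."""

    feature_set: str = "L"
    rm: float = 1.0
    hinge_knots: int = 50
    covariates: list[str] = field(default_factory=list)
    lower: np.ndarray | None = None   # per-covariate training minima
    upper: np.ndarray | None = None   # per-covariate training maxima

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ArgumentError(f"feature_set must be one of {FEATURE_SETS}")
        if not self.rm > 0:
            raise ArgumentError("regularization multiplier must be > 0")
        if self.hinge_knots < 2:
            raise ArgumentError("hinge_knots must be >= 2")

    def with_bounds(self, X: np.ndarray, covariates: list[str]) -> "FeatureSpec":
        lower = X.min(axis=0)
        upper = X.max(axis=0)
        return FeatureSpec(feature_set=self.feature_set, rm=self.rm,
                           hinge_knots=self.hinge_knots,
                           covariates=list(covariates), lower=lower, upper=upper)


@dataclass
class FeatureColumn:
    covariate: str
    feature_type: str        # 'linear' | 'quadratic' | 'hinge'
    knot: float | None = None
    direction: str | None = None   # 'forward' | 'reverse' for hinges


@dataclass
class FeatureMatrix:
    values: np.ndarray                 # (n_samples, n_features), entries in [0, 1]
    columns: list[FeatureColumn]

    @property
    def n_features(self) -> int:
        return len(self.columns)


def scale_covariates(X: np.ndarray, spec: FeatureSpec, clamp: bool = True) -> np.ndarray:
    """Min-max scale raw covariate values using the spec's training bounds."""
    if spec.lower is None or spec.upper is None:
        raise ArgumentError("spec carries no scaling bounds; call with_bounds first")
    X = np.asarray(X, float)
    span = np.where(spec.upper > spec.lower, spec.upper - spec.lower, 1.0)
    Z = (X - spec.lower) / span
    if clamp:
        Z = np.clip(Z, 0.0, 1.0)
    return Z


def hinge_knot_positions(n_knots: int) -> np.ndarray:
    """Evenly spaced interior knots over (0, 1)."""
    return np.arange(1, n_knots + 1) / (n_knots + 1)


def build_features(X: np.ndarray, spec: FeatureSpec,
                   drop_constant: bool = True) -> FeatureMatrix:
    """Derive the feature matrix from raw covariate values.

    ``X`` is (n_samples, n_covariates) in the order of ``spec.covariates``.
    With ``drop_constant`` (training mode) columns constant over the sample
    are removed; projection should pass the training matrix's column list
    via :func:`project_features` instead.
    """
    if X.ndim != 2 or X.shape[0] == 0:
        raise ArgumentError("X must be a non-empty 2-D sample matrix")
    if np.isnan(X).any():
        raise ArgumentError("NaN in covariate values")
    if len(spec.covariates) != X.shape[1]:
        raise ArgumentError("X width differs from spec.covariates")
    Z = scale_covariates(X, spec)
    cols: list[np.ndarray] = []
    meta: list[FeatureColumn] = []
    knots = hinge_knot_positions(spec.hinge_knots)
    for j, name in enumerate(spec.covariates):
        z = Z[:, j]
        if "L" in spec.feature_set:
            cols.append(z)
            meta.append(FeatureColumn(name, "linear"))
        if "Q" in spec.feature_set:
            cols.append(z**2)
            meta.append(FeatureColumn(name, "quadratic"))
        if "H" in spec.feature_set:
            for k in knots:
                cols.append(np.maximum(0.0, (z - k) / (1.0 - k)))
                meta.append(FeatureColumn(name, "hinge", knot=float(k),
                                          direction="forward"))
            for k in knots:
                cols.append(np.maximum(0.0, (k - z) / k))
                meta.append(FeatureColumn(name, "hinge", knot=float(k),
                                          direction="reverse"))
    if not cols:
        return FeatureMatrix(values=np.empty((X.shape[0], 0)), columns=[])
    F = np.column_stack(cols)
    if drop_constant:
        keep = F.max(axis=0) > F.min(axis=0)
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("build_features: dropped %d constant feature columns", n_drop)
        F = F[:, keep]
        meta = [m for m, k in zip(meta, keep) if k]
    return FeatureMatrix(values=F, columns=meta)


def project_features(X: np.ndarray, spec: FeatureSpec,
                     columns: list[FeatureColumn]) -> np.ndarray:
    """Evaluate the training feature columns at new covariate values.

    Projection clamps covariates to the training [0, 1] scaled bounds, then
    evaluates exactly the columns retained at training time.
    """
    Z = scale_covariates(np.asarray(X, float), spec)
    idx = {name: j for j, name in enumerate(spec.covariates)}
    out = np.empty((Z.shape[0], len(columns)))
    for i, col in enumerate(columns):
        z = Z[:, idx[col.covariate]]
        if col.feature_type == "linear":
            out[:, i] = z
        elif col.feature_type == "quadratic":
            out[:, i] = z**2
        else:
            k = col.knot
            if col.direction == "forward":
                out[:, i] = np.maximum(0.0, (z - k) / (1.0 - k))
            else:
                out[:, i] = np.maximum(0.0, (k - z) / k)
    return out


def default_regularization(columns: list[FeatureColumn], n_presences: int) -> np.ndarray:
    """Per-feature base penalty from the sample-size-interpolated schedule.

    Linear and quadratic features share the interpolated schedule; hinge
    features carry the constant 0.5.  Values are flat-extrapolated outside
    the anchor range.  These bases are scaled at fit time by the
    regularization multiplier and the feature's presence-sample standard
    deviation bound.
    """
    if n_presences < 1:
        raise ArgumentError("n_presences must be >= 1")
    out = np.empty(len(columns))
    for i, col in enumerate(columns):
        anchors, betas = REG_SCHEDULE[col.feature_type]
        out[i] = np.interp(n_presences, anchors, betas)
    return out


def fit_time_regularization(F_presence: np.ndarray, columns: list[FeatureColumn],
                            rm: float) -> np.ndarray:
    """The effective per-feature lasso penalties beta_j * rm.

    beta_j = max(0.001 * feature range, hinge identifiability bound,
    sd_presence(f_j) * schedule_j / sqrt(m)), then scaled by the multiplier.
    """
    m = F_presence.shape[0]
    base = default_regularization(columns, m)
    sd = F_presence.std(axis=0, ddof=1) if m > 1 else np.zeros(len(columns))
    beta = sd * base / np.sqrt(max(m, 1))
    is_hinge = np.array([c.feature_type == "hinge" for c in columns])
    if is_hinge.any() and m >= 1:
        mindev = (F_presence.max(axis=0) - F_presence.mean(axis=0)) * 2.0 / np.sqrt(m)
        beta = np.where(is_hinge, np.maximum(beta, mindev), beta)
    beta = np.maximum(beta, 0.001)  # features live in [0, 1]; range bound
    return rm * beta
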