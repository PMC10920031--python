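"""Lasso-penalized maximum-entropy presence-background model.

The model estimates a Gibbs density over landscape cells,
``P(x) = exp(lambda . f(x)) / (N Z)``, by minimizing the penalized
negative log-likelihood

    J(lambda) = -(1/m) sum_presences lambda . f(x_i)
                + log Z_background(lambda)
                + sum_j rm * beta_j * |lambda_j|,

with ``Z_background = (1/N) sum_background exp(lambda . f(x))``.  J is
convex; it is minimized by cyclic coordinate descent with per-coordinate
proximal Newton steps (soft-thresholding), with step halving so the
objective is non-increasing at every accepted update.

Usage follows the model/results convention::

    model = MaxEnt(presence_X, background_X, covariates=names, feature_set="L", rm=1.0)
    res = model.fit()
    res.summary()
    res.predict(new_X, transform="cloglog")
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .errors import ArgumentError, DegenerateInputError
from .features import (
    FeatureColumn,
    FeatureMatrix,
    FeatureSpec,
    build_features,
    fit_time_regularization,
    project_features,
)
from .grids import CovariateStack, RasterGrid

log = logging.getLogger(__name__)

#: |Spearman rho| below which a response curve is reported as directionless
DIRECTION_RHO_MIN = 0.05


class MaxEnt:
    """Presence-background maximum-entropy model (unfitted).

    Parameters
    ----------
    presence_X, background_X
        Raw covariate matrices (rows = cells, columns = covariates in the
        order of ``covariates``).
    covariates
        Covariate names; defaults to ``x0..xp``.
    feature_set, rm, hinge_knots
        Feature classes ('L', 'LQ', 'H', 'LQH'), regularization multiplier,
        and hinge knots per direction.
    add_presences_to_background
        Include presence cells in the background sample used for the
        partition function (the reference behavior).
    """

    def __init__(self, presence_X, background_X, covariates=None,
                 feature_set: str = "L", rm: float = 1.0, hinge_knots: int = 50,
                 add_presences_to_background: bool = True):
        self.presence_X = np.atleast_2d(np.asarray(presence_X, float))
        self.background_X = np.atleast_2d(np.asarray(background_X, float))
        if self.presence_X.shape[1] != self.background_X.shape[1]:
            raise ArgumentError("presence and background covariate widths differ")
        if self.presence_X.shape[0] < 2:
            raise DegenerateInputError("need at least 2 presence cells")
        if self.background_X.shape[0] < self.presence_X.shape[0]:
            raise ArgumentError("need at least as many background as presence cells")
        if np.isnan(self.presence_X).any() or np.isnan(self.background_X).any():
            raise ArgumentError("NaN in covariate values")
        p = self.presence_X.shape[1]
        self.covariates = (list(covariates) if covariates is not None
                           else [f"x{j}" for j in range(p)])
        if len(self.covariates) != p:
            raise ArgumentError("covariate name count differs from matrix width")
        self.spec = FeatureSpec(feature_set=feature_set, rm=rm,
                                hinge_knots=hinge_knots).with_bounds(
            np.vstack([self.presence_X, self.background_X]), self.covariates)
        self.add_presences_to_background = add_presences_to_background

    @classmethod
    def from_cells(cls, stack: CovariateStack, presences, background,
                   covariates=None, **kwargs) -> "MaxEnt":
        """Build from a covariate stack and presence/background cell sets."""
        names = list(covariates) if covariates is not None else stack.names
        P = stack.values_at_cells(presences.rows, presences.cols, names)
        B = stack.values_at_cells(background.rows, background.cols, names)
        return cls(P, B, covariates=names, **kwargs)

    # -- fitting ------------------------------------------------------------
    def fit(self, tol: float = 1e-6, max_sweeps: int = 1000) -> "MaxEntResults":
        m = self.presence_X.shape[0]
        X_all = np.vstack([self.presence_X, self.background_X])
        fm = build_features(X_all, self.spec)
        F_pres = fm.values[:m]
        F_part = fm.values if self.add_presences_to_background else fm.values[m:]
        penalties = (fit_time_regularization(F_pres, fm.columns, self.spec.rm)
                     if fm.n_features else np.empty(0))
        lam, trace = _coordinate_descent(
            F_pres, F_part, penalties, [c.covariate for c in fm.columns],
            tol=tol, max_sweeps=max_sweeps)
        return MaxEntResults(model=self, columns=fm.columns, params=lam,
                             penalties=penalties, **trace)


def _objective_parts(a, F_part, lam, penalties):
    eta = F_part @ lam
    logZN = logsumexp(eta)  # log(N * Z)
    nll = -float(a @ lam) + float(logZN) - np.log(F_part.shape[0])
    pen = float(penalties @ np.abs(lam)) if lam.size else 0.0
    return nll, pen


def _fast_logsumexp(eta: np.ndarray) -> float:
    mx = eta.max()
    return float(np.log(np.exp(eta - mx).sum()) + mx)


def _coordinate_descent(F_pres, F_part, penalties, col_covariates,
                        tol=1e-6, max_sweeps=1000):
    """Cyclic proximal coordinate descent on the penalized objective."""
    n_feat = F_part.shape[1]
    N = F_part.shape[0]
    logN = np.log(N)
    lam = np.zeros(n_feat)
    credits: dict[str, float] = {}
    objective_path: list[float] = []
    if n_feat == 0:
        return lam, dict(converged=True, n_sweeps=0, credits=credits,
                         objective_path=[float(logN) - logN])
    a = F_pres.mean(axis=0)
    eta = np.zeros(N)
    logZN = _fast_logsumexp(eta)
    nll = -float(a @ lam) + logZN - logN
    pen = 0.0
    obj = nll + pen
    objective_path.append(obj)
    converged = False
    sweeps = 0
    order = np.arange(n_feat)
    active: np.ndarray | None = None
    while sweeps < max_sweeps:
        full = active is None or sweeps % 5 == 0
        idx = order if full else active
        max_delta = 0.0
        for j in idx:
            fj = F_part[:, j]
            w = np.exp(eta - logZN)          # background Gibbs weights, sum 1
            Ef = float(w @ fj)
            Ef2 = float(w @ (fj * fj))
            g = -a[j] + Ef
            h = max(Ef2 - Ef * Ef, 1e-10)
            t = h * lam[j] - g
            target = np.sign(t) * max(abs(t) - penalties[j], 0.0) / h
            delta = target - lam[j]
            if delta == 0.0:
                continue
            # step halving keeps the exact objective non-increasing
            for _ in range(30):
                new_lam_j = lam[j] + delta
                new_eta = eta + delta * fj
                new_logZN = _fast_logsumexp(new_eta)
                new_nll = nll + a[j] * lam[j] - a[j] * new_lam_j \
                    + (new_logZN - logZN)
                new_pen = pen + penalties[j] * (abs(new_lam_j) - abs(lam[j]))
                if new_nll + new_pen <= obj + 1e-12:
                    break
                delta *= 0.5
            else:
                continue  # no acceptable step; leave coordinate unchanged
            credits[col_covariates[j]] = credits.get(col_covariates[j], 0.0) \
                + (nll - new_nll)
            lam[j] = new_lam_j
            eta = new_eta
            logZN = new_logZN
            nll, pen = new_nll, new_pen
            obj = nll + pen
            max_delta = max(max_delta, abs(delta))
        sweeps += 1
        objective_path.append(obj)
        active = order[lam != 0.0]
        if max_delta < tol:
            if full:
                converged = True
                break
            active = None  # force a verifying full sweep
    if not converged:
        log.warning("coordinate descent hit the sweep cap (%d) without "
                    "converging; returning best iterate", max_sweeps)
    return lam, dict(converged=converged, n_sweeps=sweeps, credits=credits,
                     objective_path=objective_path)


@dataclass
class MaxEntResults:
    """Fitted MaxEnt model: coefficients, normalizers, reports, prediction."""

    model: MaxEnt
    columns: list[FeatureColumn]
    params: np.ndarray
    penalties: np.ndarray
    converged: bool
    n_sweeps: int
    credits: dict[str, float]
    objective_path: list[float]

    def __post_init__(self) -> None:
        spec = self.model.spec
        X_bg = (np.vstack([self.model.presence_X, self.model.background_X])
                if self.model.add_presences_to_background else self.model.background_X)
        F_bg = project_features(X_bg, spec, self.columns) if self.columns else \
            np.empty((X_bg.shape[0], 0))
        eta = F_bg @ self.params if self.params.size else np.zeros(X_bg.shape[0])
        #: log(N * Z): the log partition total over the background sample
        self.log_partition = float(logsumexp(eta))
        log_p = eta - self.log_partition
        p = np.exp(log_p)
        #: entropy of the fitted background distribution
        self.entropy = float(-(p @ log_p))
        self.n_background_ = X_bg.shape[0]

    # -- basic accessors ----------------------------------------------------
    @property
    def spec(self) -> FeatureSpec:
        return self.model.spec

    @property
    def k_nonzero(self) -> int:
        return int(np.count_nonzero(self.params))

    @property
    def objective(self) -> float:
        return self.objective_path[-1]

    def kkt_violation(self) -> float:
        """Max violation of the stationarity conditions (0 at an exact optimum)."""
        if not self.params.size:
            return 0.0
        spec = self.model.spec
        m = self.model.presence_X.shape[0]
        X_all = np.vstack([self.model.presence_X, self.model.background_X])
        F = project_features(X_all, spec, self.columns)
        F_pres = F[:m]
        F_part = F if self.model.add_presences_to_background else F[m:]
        a = F_pres.mean(axis=0)
        eta = F_part @ self.params
        w = np.exp(eta - logsumexp(eta))
        grad = -a + F_part.T @ w
        viol = np.where(self.params != 0,
                        np.abs(grad + np.sign(self.params) * self.penalties),
                        np.maximum(np.abs(grad) - self.penalties, 0.0))
        return float(viol.max())

    # -- prediction ---------------------------------------------------------
    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if not self.columns:
            return np.zeros(X.shape[0])
        F = project_features(X, self.model.spec, self.columns)
        return F @ self.params

    def predict(self, X, transform: str = "cloglog") -> np.ndarray:
        """Score covariate rows; 'raw' sums to 1 over the background sample,
        'cloglog' maps raw through 1 - exp(-e^H * raw) into (0, 1)."""
        eta = self.linear_predictor(X)
        raw = np.exp(eta - self.log_partition)
        if transform == "raw":
            return raw
        if transform == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ArgumentError(f"unknown transform {transform!r}")

    def predict_cells(self, stack: CovariateStack, cells,
                      transform: str = "cloglog") -> np.ndarray:
        X = stack.values_at_cells(cells.rows, cells.cols, self.model.covariates)
        return self.predict(X, transform=transform)

    def predict_grid(self, stack: CovariateStack, domain_mask=None,
                     transform: str = "cloglog") -> RasterGrid:
        """Project the model over every valid (optionally domain-masked) cell."""
        grid = stack.grid
        valid = ~stack.nodata_mask
        if domain_mask is not None:
            valid = valid & domain_mask
        rr, cc = np.nonzero(valid)
        X = stack.values_at_cells(rr, cc, self.model.covariates)
        scores = self.predict(X, transform=transform)
        values = np.zeros(grid.shape)
        values[rr, cc] = scores
        return grid.copy(values=values, nodata_mask=~valid)

    # -- habitat-association reports ---------------------------------------
    def percent_contribution(self) -> pd.Series:
        """Training-path credit of objective gain per covariate, as percents.

        Each accepted coefficient update's decrease in the unpenalized
        negative log-likelihood is credited to the updated feature's source
        covariate; negative totals floor at 0 and the rest normalize to 100.
        """
        credit = np.array([max(self.credits.get(c, 0.0), 0.0)
                           for c in self.model.covariates])
        total = credit.sum()
        if total > 0:
            credit = 100.0 * credit / total
        return pd.Series(credit, index=self.model.covariates,
                         name="percent_contribution")

    def permutation_importance(self, n_iter: int = 120, seed: int = 0) -> pd.Series:
        """Mean training-AUC drop when a covariate's values are permuted
        jointly across the presence+background sample, normalized to 100."""
        from .evaluate import auc  # local import; evaluate builds on this module

        if n_iter < 1:
            raise ArgumentError("n_iter must be >= 1")
        rng = np.random.default_rng(seed)
        m = self.model.presence_X.shape[0]
        X_all = np.vstack([self.model.presence_X, self.model.background_X])
        base_eta = self.linear_predictor(X_all)
        base_auc = auc(base_eta[:m], base_eta[m:])
        drops = np.zeros(len(self.model.covariates))
        nonzero_cov = {c.covariate for c, lam in zip(self.columns, self.params)
                       if lam != 0.0}
        for j, name in enumerate(self.model.covariates):
            if name not in nonzero_cov:
                continue  # permuting an unused covariate cannot move the score
            acc = 0.0
            for _ in range(n_iter):
                Xp = X_all.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                eta = self.linear_predictor(Xp)
                acc += base_auc - auc(eta[:m], eta[m:])
            drops[j] = max(acc / n_iter, 0.0)
        total = drops.sum()
        if total > 0:
            drops = 100.0 * drops / total
        return pd.Series(drops, index=self.model.covariates,
                         name="permutation_importance")

    def response_curves(self, n_points: int = 100) -> dict[str, pd.DataFrame]:
        """Marginal response of cloglog output to each covariate, others held
        at their background means."""
        out = {}
        bg_mean = self.model.background_X.mean(axis=0)
        for j, name in enumerate(self.model.covariates):
            lo = self.model.spec.lower[j]
            hi = self.model.spec.upper[j]
            vals = np.linspace(lo, hi, n_points)
            X = np.tile(bg_mean, (n_points, 1))
            X[:, j] = vals
            out[name] = pd.DataFrame({"value": vals,
                                      "cloglog": self.predict(X, "cloglog")})
        return out

    def relationship_directions(self, n_points: int = 100) -> pd.Series:
        """'Positive'/'Negative' by the Spearman correlation between covariate
        value and its response curve; 'NA' when the covariate has no nonzero
        feature coefficient or the correlation is negligible."""
        curves = self.response_curves(n_points)
        nonzero_cov = {c.covariate for c, lam in zip(self.columns, self.params)
                       if lam != 0.0}
        directions = {}
        for name, df in curves.items():
            if name not in nonzero_cov or df["cloglog"].nunique() == 1:
                directions[name] = "NA"
                continue
            rho = spearmanr(df["value"], df["cloglog"]).statistic
            if not np.isfinite(rho) or abs(rho) < DIRECTION_RHO_MIN:
                directions[name] = "NA"
            else:
                directions[name] = "Positive" if rho > 0 else "Negative"
        return pd.Series(directions, name="relationship_direction")

    def contribution_report(self, n_iter: int = 120, seed: int = 0) -> pd.DataFrame:
        """Percent contribution, permutation importance, and direction."""
        return pd.DataFrame({
            "percent_contribution": self.percent_contribution(),
            "permutation_importance": self.permutation_importance(n_iter, seed),
            "relationship_direction": self.relationship_directions(),
        })

    # -- reporting / serialization ------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": [c.covariate for c in self.columns],
            "feature_type": [c.feature_type for c in self.columns],
            "knot": [c.knot for c in self.columns],
            "direction": [c.direction for c in self.columns],
            "coefficient": self.params,
            "penalty": self.penalties,
        })

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 57,
            f"Feature set:            {spec.feature_set}   (rm = {spec.rm:g})",
            f"Presences / background: {self.model.presence_X.shape[0]} / "
            f"{self.model.background_X.shape[0]}",
            f"Features (nonzero):     {len(self.columns)} ({self.k_nonzero})",
            f"Converged:              {self.converged} in {self.n_sweeps} sweeps",
            f"Penalized objective:    {self.objective:.6f}",
            f"Background entropy H:   {self.entropy:.4f}",
            "-" * 57,
            f"{'covariate':<20}{'sum|coef|':>12}{'n_nonzero':>10}{'contrib%':>12}",
        ]
        contrib = self.percent_contribution()
        for name in self.model.covariates:
            mask = np.array([c.covariate == name for c in self.columns])
            lines.append(f"{name:<20}{np.abs(self.params[mask]).sum():>12.4f}"
                         f"{int(np.count_nonzero(self.params[mask])):>10}"
                         f"{contrib[name]:>12.2f}")
        lines.append("=" * 57)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        spec = self.model.spec
        return {
            "feature_set": spec.feature_set,
            "rm": spec.rm,
            "hinge_knots": spec.hinge_knots,
            "covariates": self.model.covariates,
            "lower": spec.lower.tolist(),
            "upper": spec.upper.tolist(),
            "columns": [{"covariate": c.covariate, "feature_type": c.feature_type,
                         "knot": c.knot, "direction": c.direction}
                        for c in self.columns],
            "coefficients": self.params.tolist(),
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "converged": self.converged,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class FrozenMaxEnt:
    """A deserialized fitted model, sufficient for projection."""

    def __init__(self, d: dict):
        self.covariates = list(d["covariates"])
        self.spec = FeatureSpec(feature_set=d["feature_set"], rm=d["rm"],
                                hinge_knots=d["hinge_knots"],
                                covariates=self.covariates,
                                lower=np.array(d["lower"]),
                                upper=np.array(d["upper"]))
        self.columns = [FeatureColumn(**c) for c in d["columns"]]
        self.params = np.array(d["coefficients"])
        self.log_partition = float(d["log_partition"])
        self.entropy = float(d["entropy"])

    @classmethod
    def load(cls, path) -> "FrozenMaxEnt":
        with open(path) as fh:
            return cls(json.load(fh))

    def predict(self, X, transform: str = "cloglog") -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        F = (project_features(X, self.spec, self.columns)
             if self.columns else np.empty((X.shape[0], 0)))
        eta = F @ self.params if self.params.size else np.zeros(X.shape[0])
        raw = np.exp(eta - self.log_partition)
        if transform == "raw":
            return raw
        if transform == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ArgumentError(f"unknown transform {transform!r}")

    def predict_grid(self, stack: CovariateStack, domain_mask=None,
                     transform: str = "cloglog") -> RasterGrid:
        grid = stack.grid
        valid = ~stack.nodata_mask
        if domain_mask is not None:
            valid = valid & domain_mask
        rr, cc = np.nonzero(valid)
        X = stack.values_at_cells(rr, cc, self.covariates)
        values = np.zeros(grid.shape)
        values[rr, cc] = self.predict(X, transform=transform)
        return grid.copy(values=values, nodata_mask=~valid)
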