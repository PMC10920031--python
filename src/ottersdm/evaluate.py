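"""Cross-validated evaluation metrics, AICc, the tuning grid, and selection.

Metrics follow the presence-background convention: background cells serve as
the contrast class for AUC, calibration presences set the 10%-omission
threshold, and AICc standardizes raw model output to a probability mass over
all landscape cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ArgumentError, DegenerateInputError
from .features import FEATURE_SET_ORDER, FEATURE_SETS
from .grids import CellSet, CovariateStack
from .maxent import MaxEnt, MaxEntResults

METRICS = ("auc_train", "auc_val", "auc_diff", "or10")


# ---------------------------------------------------------------------------
# primitive metrics

def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 P(tie)."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ArgumentError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))  # midranks handle ties exactly
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def or10(calibration_scores, test_scores, omission: float = 0.10) -> float:
    """Omission rate at the threshold omitting 10% of calibration records.

    Threshold is the linear-interpolation 10th percentile of the calibration
    presence scores; the rate is the fraction of test presence scores
    strictly below it.
    """
    cal = np.asarray(calibration_scores, float)
    test = np.asarray(test_scores, float)
    if cal.size == 0:
        raise ArgumentError("calibration scores must be nonempty")
    if test.size == 0:
        raise DegenerateInputError("empty test set")
    threshold = np.percentile(cal, 100.0 * omission)
    return float(np.mean(test < threshold))


# ---------------------------------------------------------------------------
# fold partitioning

@dataclass
class FoldPartition:
    """Random k-fold assignment of presences; fold sizes differ by <= 1."""

    k: int
    assignment: np.ndarray
    seed: int

    @classmethod
    def make(cls, n: int, k: int, seed: int) -> "FoldPartition":
        if k < 2:
            raise ArgumentError("k must be >= 2")
        if k > n:
            raise ArgumentError(f"k={k} exceeds {n} presences")
        rng = np.random.default_rng(seed)
        assignment = np.resize(np.arange(1, k + 1), n)  # sizes differ by <= 1
        rng.shuffle(assignment)
        return cls(k=k, assignment=assignment, seed=seed)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k + 1)[1:]

    def train_test(self, fold: int):
        test = self.assignment == fold
        return ~test, test


def kfold_partition(presences: CellSet, k: int, seed: int) -> FoldPartition:
    return FoldPartition.make(len(presences), k, seed)


# ---------------------------------------------------------------------------
# cross-validated metrics

@dataclass
class EvalMetrics:
    """Per-fold and averaged AUC_train / AUC_val / AUC_diff / OR10."""

    per_fold: pd.DataFrame   # columns METRICS + n_presence_train/test

    @property
    def means(self) -> pd.Series:
        return self.per_fold[list(METRICS)].mean(axis=0)

    def __getattr__(self, name: str):
        if name in METRICS:
            return float(self.means[name])
        raise AttributeError(name)


def cross_validate(presence_X: np.ndarray, background_X: np.ndarray,
                   partition: FoldPartition, covariates=None,
                   transform: str = "cloglog", **model_kwargs) -> EvalMetrics:
    """k-fold cross-validation of a single candidate model.

    Each fold's model is calibrated on the remaining folds' presences
    against the full background sample; both calibration and withheld
    presences are scored against that same background (no background
    partitioning).  AUC_diff is differenced per fold, then averaged.
    """
    rows = []
    for fold in range(1, partition.k + 1):
        train, test = partition.train_test(fold)
        res = MaxEnt(presence_X[train], background_X,
                     covariates=covariates, **model_kwargs).fit()
        bg_scores = res.predict(background_X, transform=transform)
        train_scores = res.predict(presence_X[train], transform=transform)
        test_scores = res.predict(presence_X[test], transform=transform)
        auc_train = auc(train_scores, bg_scores)
        auc_val = auc(test_scores, bg_scores)
        rows.append({
            "fold": fold,
            "auc_train": auc_train,
            "auc_val": auc_val,
            "auc_diff": auc_train - auc_val,
            "or10": or10(train_scores, test_scores),
            "n_presence_train": int(train.sum()),
            "n_presence_test": int(test.sum()),
        })
    return EvalMetrics(per_fold=pd.DataFrame(rows).set_index("fold"))


# ---------------------------------------------------------------------------
# AICc

def aicc_from_loglik(lnL: float, K: int, n: int) -> float:
    if n - K - 1 <= 0:
        return float("nan")
    return 2.0 * K - 2.0 * lnL + 2.0 * K * (K + 1) / (n - K - 1)


def aicc(results: MaxEntResults, presence_X: np.ndarray,
         landscape_X: np.ndarray) -> tuple[float, int, float]:
    """(AICc, K, lnL) of a full-data fit under the landscape-normalized
    likelihood convention: raw output standardized to sum to 1 over all
    landscape cells; K = nonzero coefficients."""
    raw_land = results.predict(landscape_X, transform="raw")
    raw_pres = results.predict(presence_X, transform="raw")
    total = raw_land.sum()
    lnL = float(np.log(raw_pres / total).sum())
    K = results.k_nonzero
    n = presence_X.shape[0]
    return aicc_from_loglik(lnL, K, n), K, lnL


# ---------------------------------------------------------------------------
# tuning grid

@dataclass
class CandidateRecord:
    feature_set: str
    rm: float
    metrics: EvalMetrics | None
    aicc: float
    K: int
    lnL: float
    results: MaxEntResults | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class TuningResults:
    """All candidate records over the feature-set x rm grid."""

    records: list[CandidateRecord]

    def table(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"feature_set": rec.feature_set, "rm": rec.rm,
                   "aicc": rec.aicc, "K": rec.K, "lnL": rec.lnL,
                   "error": rec.error}
            if rec.metrics is not None:
                row.update(rec.metrics.means.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def chosen_sequential(self) -> CandidateRecord:
        return select_sequential(self)

    @property
    def chosen_aicc(self) -> CandidateRecord:
        return select_aicc(self)


def tune(presence_X: np.ndarray, background_X: np.ndarray,
         partition: FoldPartition, landscape_X: np.ndarray,
         feature_sets=FEATURE_SETS, rm_values=(1, 2, 3, 4, 5),
         covariates=None, hinge_knots: int = 50,
         keep_results: bool = False) -> TuningResults:
    """Fit and evaluate every (feature_set, rm) candidate.

    Per candidate: k-fold CV metrics plus a full-presence refit for AICc
    (raw output standardized over ``landscape_X``).  A failing candidate is
    flagged and does not interrupt the grid.
    """
    if not len(feature_sets) or not len(rm_values):
        raise ArgumentError("feature_sets and rm_values must be nonempty")
    records = []
    for fs in feature_sets:
        for rm in rm_values:
            try:
                metrics = cross_validate(presence_X, background_X, partition,
                                         covariates=covariates, feature_set=fs,
                                         rm=rm, hinge_knots=hinge_knots)
                full = MaxEnt(presence_X, background_X, covariates=covariates,
                              feature_set=fs, rm=rm,
                              hinge_knots=hinge_knots).fit()
                ic, K, lnL = aicc(full, presence_X, landscape_X)
                records.append(CandidateRecord(
                    feature_set=fs, rm=float(rm), metrics=metrics, aicc=ic,
                    K=K, lnL=lnL, results=full if keep_results else None))
            except Exception as exc:  # flag, keep the rest of the grid
                records.append(CandidateRecord(
                    feature_set=fs, rm=float(rm), metrics=None,
                    aicc=float("nan"), K=0, lnL=float("nan"), error=str(exc)))
    return TuningResults(records=records)


# ---------------------------------------------------------------------------
# model selection

def select_sequential(results: TuningResults) -> CandidateRecord:
    """Lowest mean OR10, then highest mean AUC_val, then lowest rm, then
    feature-set order L < LQ < H < LQH."""
    valid = [r for r in results.records if r.ok and r.metrics is not None]
    if not valid:
        raise DegenerateInputError("no valid candidate records")
    return min(valid, key=lambda r: (round(r.metrics.or10, 12),
                                     -round(r.metrics.auc_val, 12),
                                     r.rm,
                                     FEATURE_SET_ORDER.get(r.feature_set, 99)))


def select_aicc(results: TuningResults) -> CandidateRecord:
    """Lowest finite AICc; ties go to the model with fewer parameters."""
    valid = [r for r in results.records if r.ok and np.isfinite(r.aicc)]
    if not valid:
        raise DegenerateInputError("no candidate with finite AICc")
    return min(valid, key=lambda r: (r.aicc, r.K))
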