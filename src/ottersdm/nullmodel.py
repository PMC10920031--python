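"""Randomized-presence null distributions and significance comparison.

The empirical model's discrimination (AUC_train, AUC_val) and overfitting
(AUC_diff, OR10) metrics are referenced against a null distribution built by
refitting the chosen model specification on randomly placed "presences"
drawn from the survey domain, holding the background sample and the
empirical background sample and fold structure fixed so metrics are
directly comparable.  Each null iteration draws one random occurrence set
the size of the empirical presence set, partitions it with the empirical
fold assignment, and runs the identical cross-validation: per fold it
calibrates on the drawn training folds and validates on the drawn withheld
fold, then averages the folds.  Because the null statistic is computed by
exactly the same procedure as the empirical one — only with occurrences
placed at random — the two are exchangeable under a habitat-indifferent
species, which is what makes the standardized effect sizes and quantile
positions well calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ArgumentError, DegenerateInputError
from .evaluate import METRICS, FoldPartition, auc, or10
from .grids import CellSet, CovariateStack
from .maxent import MaxEnt

#: favorable direction of each metric for the one-sided test
DIRECTIONS = {"auc_train": "greater", "auc_val": "greater",
              "auc_diff": "less", "or10": "less"}
QUANTILES = (0.01, 0.05, 0.95, 0.99)


@dataclass
class NullDistribution:
    """Per-iteration null metrics with summary statistics."""

    samples: pd.DataFrame     # n_iter rows, columns METRICS
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.samples)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.samples.mean(axis=0),
                             "sd": self.samples.std(axis=0, ddof=1)})

    def quantiles(self, qs=QUANTILES) -> pd.DataFrame:
        return self.samples.quantile(list(qs))

    @staticmethod
    def concat(a: "NullDistribution", b: "NullDistribution") -> "NullDistribution":
        return NullDistribution(
            samples=pd.concat([a.samples, b.samples], ignore_index=True),
            seed=a.seed)


def run_nulls(domain_X: np.ndarray, background_X: np.ndarray,
              presence_X: np.ndarray, partition: FoldPartition,
              n_iter: int = 1000, seed: int = 0, start: int = 0,
              covariates=None, transform: str = "cloglog",
              **model_kwargs) -> NullDistribution:
    """Build the null metric distribution for one model specification.

    ``domain_X`` holds covariate rows of every available (survey-domain)
    cell from which random occurrences are drawn; ``presence_X`` and
    ``partition`` are the empirical presences and their fold structure (the
    null draw matches the presence count and reuses the fold assignment);
    the background sample is the empirical one.  Iteration ``i`` is seeded
    by ``(seed, start + i)``, so two half-runs with matching offsets
    concatenate to one full run.
    """
    if n_iter < 1:
        raise ArgumentError("n_iter must be >= 1")
    domain_X = np.asarray(domain_X, float)
    presence_X = np.asarray(presence_X, float)
    n_total = partition.assignment.size
    if presence_X.shape[0] != n_total:
        raise ArgumentError("partition size differs from the presence count")
    if domain_X.shape[0] < n_total:
        raise DegenerateInputError(
            f"domain has {domain_X.shape[0]} cells, fewer than the "
            f"{n_total} needed per occurrence draw")
    rows = []
    for i in range(n_iter):
        rng = np.random.default_rng([seed, start + i])
        draw = domain_X[rng.choice(domain_X.shape[0], size=n_total,
                                   replace=False)]
        fold_rows = []
        for fold in range(1, partition.k + 1):
            train, test = partition.train_test(fold)
            res = MaxEnt(draw[train], background_X,
                         covariates=covariates, **model_kwargs).fit()
            bg = res.predict(background_X, transform=transform)
            cal = res.predict(draw[train], transform=transform)
            tst = res.predict(draw[test], transform=transform)
            a_tr = auc(cal, bg)
            a_va = auc(tst, bg)
            fold_rows.append((a_tr, a_va, a_tr - a_va, or10(cal, tst)))
        rows.append(np.mean(fold_rows, axis=0))
    samples = pd.DataFrame(rows, columns=list(METRICS))
    return NullDistribution(samples=samples, seed=seed)


@dataclass
class NullComparison:
    """Empirical-vs-null effect sizes, p-values, and quantile positions."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def compare(empirical: dict[str, float] | pd.Series,
            null: NullDistribution) -> NullComparison:
    """Standardized effect sizes (z) and one-sided p-values per metric.

    z = (empirical - null mean) / null SD; the normal-tail p is taken in
    the metric's favorable direction (greater for the AUCs, less for the
    overfitting metrics).  An empirical-rank p against the null samples is
    reported alongside; with a degenerate null (SD = 0) the rank p stands
    in for the normal one and the row is flagged.
    """
    empirical = pd.Series(empirical)
    rows = []
    for metric in METRICS:
        if metric not in empirical.index:
            continue
        emp = float(empirical[metric])
        samp = null.samples[metric].to_numpy()
        mean = float(samp.mean())
        sd = float(samp.std(ddof=1))
        direction = DIRECTIONS[metric]
        degenerate = sd == 0.0
        if degenerate:
            z = float("nan")
        else:
            z = (emp - mean) / sd
        if direction == "greater":
            p_rank = (1.0 + np.sum(samp >= emp)) / (samp.size + 1.0)
            p_norm = float(norm.sf(z)) if not degenerate else p_rank
        else:
            p_rank = (1.0 + np.sum(samp <= emp)) / (samp.size + 1.0)
            p_norm = float(norm.cdf(z)) if not degenerate else p_rank
        q = {f"q{int(100 * qq):02d}": float(np.quantile(samp, qq))
             for qq in QUANTILES}
        rows.append({"metric": metric, "empirical": emp, "null_mean": mean,
                     "null_sd": sd, "z": z, "p": p_norm, "p_rank": float(p_rank),
                     "direction": direction, "degenerate_null": degenerate, **q})
    return NullComparison(table=pd.DataFrame(rows).set_index("metric"))


def plot_null_histograms(null: NullDistribution,
                         empirical: dict[str, float] | pd.Series | None = None,
                         path=None):
    """Four-panel histogram of the null metrics with quantile/median lines
    and (optionally) the empirical value marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(6, 10))
    for ax, metric in zip(axes, METRICS):
        samp = null.samples[metric]
        ax.hist(samp, bins=30, color="0.75")
        for qq, color in ((0.05, "tab:blue"), (0.95, "tab:blue"),
                          (0.01, "tab:purple"), (0.99, "tab:purple")):
            ax.axvline(samp.quantile(qq), color=color, linestyle="--", lw=1)
        ax.axvline(samp.median(), color="tab:blue", lw=1.5)
        if empirical is not None and metric in pd.Series(empirical).index:
            ax.axvline(float(pd.Series(empirical)[metric]), color="tab:red", lw=1.5)
        ax.set_xlabel(metric)
        ax.set_ylabel("frequency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
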