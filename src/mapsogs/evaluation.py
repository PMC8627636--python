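"""Final-subset evaluation and multi-method benchmark arithmetic.

Selected subsets are scored with leave-one-out cross-validation (LOOCV):
n single-sample folds for an n-sample dataset, accuracy reported as a
percentage. For comparing several selection methods across several
datasets the module provides per-dataset ranking (rank 1 = highest
accuracy, ties averaged), average ranks, and the Friedman test

    chi2 = 12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2,  df = k - 1,

with an optional tie correction; p-values come from the chi-square upper
tail. Display values are rounded half-up to two decimals while raw values
are preserved.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset
from .filtering import GeneSubset
from .objectives import make_classifier

__all__ = [
    "loocv_accuracy",
    "rank_methods",
    "friedman_statistic",
    "summarize_benchmark",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (display rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def loocv_accuracy(
    dataset: ExpressionDataset,
    subset: GeneSubset,
    classifier_spec: str = "svm",
    seed: int = 0,
) -> float:
    """Leave-one-out accuracy (%) of a classifier on the subset's columns."""
    if len(subset) == 0:
        raise ValueError("cannot evaluate an empty gene subset")
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    X = dataset.values[:, subset.mask(dataset.gene_ids)]
    y = dataset.label_array()
    correct = 0
    for i in range(dataset.n_samples):
        train = np.ones(dataset.n_samples, dtype=bool)
        train[i] = False
        clf = make_classifier(classifier_spec, seed)
        clf.fit(X[train], y[train])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return 100.0 * correct / dataset.n_samples


def rank_methods(table: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset ranks (1 = highest accuracy; ties averaged) plus averages.

    ``table`` has datasets as rows and methods as columns, complete. The
    returned frame has the same shape plus an ``"average"`` row whose raw
    mean rank is also provided half-up-rounded in ``attrs["display"]``.
    """
    if table.isna().any().any():
        raise ValueError("accuracy table has missing cells")
    ranks = table.rank(axis=1, ascending=False, method="average")
    average = ranks.mean(axis=0)
    out = pd.concat([ranks, average.to_frame("average").T])
    out.attrs["display"] = {m: round_half_up(v) for m, v in average.items()}
    return out


def friedman_statistic(
    rank_matrix, tie_corrected: bool = False
) -> tuple[float, int, float]:
    """Friedman chi-square from an (n datasets x k methods) rank matrix.

    Returns (chi2, df, p). The tie-corrected variant divides by
    1 - sum(t^3 - t) / (n k (k^2 - 1)) over tie groups within each dataset.
    """
    ranks = np.asarray(rank_matrix, dtype=float)
    if ranks.ndim != 2:
        raise ValueError("rank matrix must be 2-D")
    n, k = ranks.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 methods")
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
    if tie_corrected:
        correction = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            correction += float(np.sum(counts**3 - counts))
        denom = 1.0 - correction / (n * k * (k**2 - 1))
        if denom <= 0:
            chi2 = 0.0
        else:
            chi2 = chi2 / denom
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def summarize_benchmark(
    accuracy_tables: dict[str, pd.DataFrame],
    gene_counts: pd.DataFrame | None = None,
) -> dict:
    """Aggregate a multi-classifier benchmark into the standard summaries.

    ``accuracy_tables`` maps classifier name -> (datasets x methods) accuracy
    table in percent. Returns, per classifier: raw and display column means,
    pairwise mean improvements of the first method over each other method,
    the rank table with average ranks, and the Friedman statistic computed
    from those ranks. ``gene_counts`` (datasets x methods) is summarized by
    column means.
    """
    report: dict = {"classifiers": {}}
    for clf_name, table in accuracy_tables.items():
        if table.isna().any().any():
            raise ValueError(f"accuracy table for {clf_name!r} has missing cells")
        means = table.mean(axis=0)
        ranks = rank_methods(table)
        rank_rows = ranks.drop(index="average")
        if len(rank_rows) >= 2 and table.shape[1] >= 2:
            chi2, df, p = friedman_statistic(rank_rows.to_numpy())
            friedman = {"chi_square": chi2, "df": df, "p_value": p}
        else:
            friedman = None  # needs >= 2 datasets and methods
        first = table.columns[0]
        improvements = {
            other: float(means[first] - means[other])
            for other in table.columns
            if other != first
        }
        report["classifiers"][clf_name] = {
            "mean_accuracy": {m: float(v) for m, v in means.items()},
            "mean_accuracy_display": {m: round_half_up(v) for m, v in means.items()},
            "improvement_over": improvements,
            "average_ranks": {m: float(v) for m, v in ranks.loc["average"].items()},
            "average_ranks_display": ranks.attrs["display"],
            "friedman": friedman,
        }
    if gene_counts is not None:
        means = gene_counts.mean(axis=0)
        report["gene_counts"] = {
            "mean": {m: float(v) for m, v in means.items()},
            "mean_display": {m: round_half_up(v) for m, v in means.items()},
        }
    return report
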