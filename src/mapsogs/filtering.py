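"""Fisher-score relevance ranking and gene pre-filtering.

The Fisher score of a gene is the ratio of its between-class scatter to its
within-class scatter,

    score(g) = sum_k n_k (mean_k - mean)^2 / sum_k n_k var_k,

with population (n_k-weighted) class variances. High-scoring genes separate
the classes well individually. Scores drive three things: the pre-filter
that shrinks the search space, the selection probabilities used to seed the
swarm, and the gene ordering used by the repair operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionDataset

__all__ = [
    "FisherScores",
    "GeneSubset",
    "fisher_scores",
    "filter_genes",
    "normalize_scores",
    "SCORE_CAP",
]

# Sentinel for perfectly separating genes: between-class scatter > 0 with
# zero within-class scatter. Finite so downstream min-max scaling stays sane.
SCORE_CAP = 1e12


@dataclass(frozen=True)
class FisherScores:
    """Per-gene Fisher scores plus the per-class summary statistics."""

    gene_ids: tuple
    scores: np.ndarray            # (n_genes,)
    class_means: np.ndarray       # (n_classes, n_genes)
    class_variances: np.ndarray   # (n_classes, n_genes), population variances
    overall_means: np.ndarray     # (n_genes,)
    classes: tuple

    def __post_init__(self):
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("one score per gene required")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("scores must be finite and non-negative")

    def as_dict(self) -> dict:
        return dict(zip(self.gene_ids, self.scores.tolist()))

    def score_of(self, gene_id: str) -> float:
        return float(self.scores[self.gene_ids.index(gene_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "fisher_score": self.scores}
        )


@dataclass(frozen=True)
class GeneSubset:
    """An ordered subset of a dataset's genes (order = original gene order)."""

    gene_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in subset")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __contains__(self, gene_id) -> bool:
        return gene_id in set(self.gene_ids)

    def mask(self, all_gene_ids) -> np.ndarray:
        members = set(self.gene_ids)
        return np.array([g in members for g in all_gene_ids], dtype=bool)

    @classmethod
    def from_mask(cls, mask, all_gene_ids) -> "GeneSubset":
        mask = np.asarray(mask, dtype=bool)
        return cls(tuple(g for g, keep in zip(all_gene_ids, mask) if keep))


def fisher_scores(dataset: ExpressionDataset) -> FisherScores:
    """Fisher score of every gene (vectorized over genes)."""
    X = dataset.values
    labels = dataset.label_array()
    classes = dataset.class_set
    n_classes, n_genes = len(classes), dataset.n_genes
    class_means = np.empty((n_classes, n_genes))
    class_vars = np.empty((n_classes, n_genes))
    sizes = np.empty(n_classes)
    for k, cls in enumerate(classes):
        rows = X[labels == cls]
        sizes[k] = rows.shape[0]
        class_means[k] = rows.mean(axis=0)
        class_vars[k] = rows.var(axis=0)  # population variance
    overall = X.mean(axis=0)
    numer = (sizes[:, None] * (class_means - overall) ** 2).sum(axis=0)
    denom = (sizes[:, None] * class_vars).sum(axis=0)
    scores = np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = denom > 0
        scores[ok] = numer[ok] / denom[ok]
    # zero within-class scatter: constant gene -> 0, perfect separator -> cap
    scores[(~ok) & (numer > 0)] = SCORE_CAP
    np.minimum(scores, SCORE_CAP, out=scores)
    return FisherScores(
        gene_ids=dataset.gene_ids,
        scores=scores,
        class_means=class_means,
        class_variances=class_vars,
        overall_means=overall,
        classes=classes,
    )


def filter_genes(scores: FisherScores, mode: str, value) -> GeneSubset:
    """Keep high-scoring genes; original gene order is preserved.

    ``mode="absolute-threshold"`` keeps genes with score >= value (lambda);
    ``mode="top-m"`` keeps the value highest-scoring genes, ties broken in
    favor of earlier gene ids.
    """
    n = len(scores.gene_ids)
    if mode == "absolute-threshold":
        lam = float(value)
        if lam < 0:
            raise ValueError("lambda threshold must be non-negative")
        keep = scores.scores >= lam
        if not keep.any():
            raise ValueError(
                f"no gene has Fisher score >= {lam}; lower the threshold"
            )
    elif mode == "top-m":
        m = int(value)
        if not 1 <= m <= n:
            raise ValueError(f"top-m value must lie in [1, {n}]")
        # stable sort on -score: ties resolve to earlier gene positions
        order = np.argsort(-scores.scores, kind="stable")[:m]
        keep = np.zeros(n, dtype=bool)
        keep[order] = True
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return GeneSubset(tuple(g for g, k in zip(scores.gene_ids, keep) if k))


def normalize_scores(scores: FisherScores) -> dict:
    """Min-max scale scores to [0, 1] (all-equal degenerates to 0.5).

    The scaled scores act as per-gene selection probabilities during swarm
    initialization and as the preference order of the repair operator.
    """
    s = scores.scores
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        scaled = np.full_like(s, 0.5)
    else:
        scaled = (s - lo) / (hi - lo)
    return dict(zip(scores.gene_ids, scaled.tolist()))


def scores_table(scores: FisherScores, kept: GeneSubset) -> pd.DataFrame:
    """TSV-ready table: gene_id, fisher_score, normalized_score, kept_flag."""
    normalized = normalize_scores(scores)
    kept_set = set(kept.gene_ids)
    return pd.DataFrame(
        {
            "gene_id": scores.gene_ids,
            "fisher_score": scores.scores,
            "normalized_score": [normalized[g] for g in scores.gene_ids],
            "kept_flag": [int(g in kept_set) for g in scores.gene_ids],
        }
    )
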