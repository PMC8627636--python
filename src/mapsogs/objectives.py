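"""The five minimization objectives of the gene-subset fitness vector.

For a candidate subset GS the swarm minimizes

    F(GS) = (f1, f2, f3, f4, f5)

    f1 = classification error of a classifier trained on GS (cross-validated)
    f2 = sum of edge centralities over selected gene pairs  (redundancy)
    f3 = 1 / NC(GS), NC = sum of node centralities of selected genes
    f4 = 1 / specificity (true-negative rate)
    f5 = |GS|, the number of selected genes

f3 and f4 are reciprocals of quantities that can vanish, so both are guarded
with a small epsilon, turning a zero into a large but finite penalty that
preserves dominance comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import config_context as sklearn_config
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import ExpressionDataset
from .filtering import GeneSubset
from .graph import CentralityTables

__all__ = [
    "ConfusionCounts",
    "FitnessVector",
    "confusion_counts",
    "classification_error",
    "specificity",
    "evaluate_subset_cv",
    "fitness_vector",
    "make_classifier",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts per class.

    For a binary problem the counts of the designated positive class are the
    usual TP/FP/TN/FN. ``total`` is the number of evaluated predictions.
    """

    classes: tuple
    tp: dict
    fp: dict
    tn: dict
    fn: dict
    total: int

    def binary(self, positive_class) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) treating ``positive_class`` as positive."""
        c = positive_class
        return self.tp[c], self.fp[c], self.tn[c], self.fn[c]

    @property
    def misclassified(self) -> int:
        # each misclassified sample is exactly one class's false negative
        return sum(self.fn.values())


def confusion_counts(true_labels, predicted_labels, classes=None) -> ConfusionCounts:
    """Exact one-vs-rest confusion counts (binary counts fall out per class)."""
    true = np.asarray(true_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label sequences differ in length")
    if classes is None:
        classes = tuple(dict.fromkeys(true.tolist()))
    tp, fp, tn, fn = {}, {}, {}, {}
    for c in classes:
        pos_true = true == c
        pos_pred = pred == c
        tp[c] = int(np.sum(pos_true & pos_pred))
        fp[c] = int(np.sum(~pos_true & pos_pred))
        tn[c] = int(np.sum(~pos_true & ~pos_pred))
        fn[c] = int(np.sum(pos_true & ~pos_pred))
    return ConfusionCounts(tuple(classes), tp, fp, tn, fn, int(true.size))


def classification_error(counts: ConfusionCounts) -> float:
    """Fraction of evaluated samples that were misclassified.

    Binary: (FP + FN) / (TP + FP + TN + FN); with more classes it is simply
    misclassified / total.
    """
    if counts.total == 0:
        raise ValueError("no evaluated predictions")
    return counts.misclassified / counts.total


def specificity(counts: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP); macro-averaged one-vs-rest.

    A class with no negatives (TN + FP = 0) contributes 1: there were no
    negative cases to mislabel.
    """
    values = []
    for c in counts.classes:
        tn, fp = counts.tn[c], counts.fp[c]
        values.append(1.0 if tn + fp == 0 else tn / (tn + fp))
    if len(counts.classes) == 2:
        # macro average == per-class value symmetry does not hold in general;
        # for the binary case use the designated positive (second) class's TNR
        return values[-1]
    return float(np.mean(values))


def make_classifier(spec: str, seed: int = 0):
    """Instantiate the evaluator classifier from a spec string.

    ``"svm"`` is a linear-kernel SVM with C=1 (the default evaluator),
    ``"dt"`` a CART decision tree, ``"knn"`` / ``"knn:k=5"`` k-nearest
    neighbours.
    """
    name, _, args = spec.partition(":")
    name = name.strip().lower()
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "knn":
        k = 5
        for part in filter(None, (p.strip() for p in args.split(","))):
            key, _, value = part.partition("=")
            if key.strip() == "k":
                k = int(value)
            else:
                raise ValueError(f"unknown knn argument {part!r}")
        return KNeighborsClassifier(n_neighbors=k)
    raise ValueError(f"unknown classifier spec {spec!r}")


def evaluate_subset_cv(
    dataset: ExpressionDataset,
    subset: GeneSubset,
    classifier_spec: str = "svm",
    folds: int = 5,
    seed: int = 0,
) -> ConfusionCounts:
    """Stratified k-fold CV of a classifier on the subset's columns.

    Out-of-fold predictions are pooled into one set of confusion counts, so
    every sample is evaluated exactly once. If ``folds`` exceeds the
    smallest class size it is reduced with a warning.
    """
    if len(subset) == 0:
        raise ValueError("cannot evaluate an empty gene subset")
    smallest = min(dataset.class_counts().values())
    if folds > smallest:
        warnings.warn(
            f"reducing cv folds from {folds} to smallest class size {smallest}",
            stacklevel=2,
        )
        folds = smallest
    X = dataset.values[:, subset.mask(dataset.gene_ids)]
    y = dataset.label_array()
    classes = dataset.class_set
    code = {c: i for i, c in enumerate(classes)}
    y_int = np.array([code[c] for c in y])
    pred = np.empty_like(y_int)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with sklearn_config(assume_finite=True):
        for train_idx, test_idx in splitter.split(X, y_int):
            clf = make_classifier(classifier_spec, seed)
            clf.fit(X[train_idx], y_int[train_idx])
            pred[test_idx] = clf.predict(X[test_idx])
    decode = np.asarray(classes, dtype=object)
    return confusion_counts(y, decode[pred], classes=classes)


@dataclass(frozen=True)
class FitnessVector:
    """The 5-component minimization objective vector."""

    f1: float  # classification error, in [0, 1]
    f2: float  # summed edge centrality of selected pairs, >= 0
    f3: float  # 1 / total node centrality, > 0
    f4: float  # 1 / specificity, >= 1 (epsilon-guarded)
    f5: int    # subset size

    def __post_init__(self):
        vec = self.as_array()
        if not np.all(np.isfinite(vec)):
            raise ValueError("fitness components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4, float(self.f5)])

    def __len__(self) -> int:
        return 5


def fitness_vector(
    mask: np.ndarray,
    centralities: CentralityTables,
    counts: ConfusionCounts,
    epsilon: float = 1e-6,
) -> FitnessVector:
    """Assemble F(GS) from a selection mask, centrality tables and CV counts."""
    mask = np.asarray(mask, dtype=bool)
    selected = np.flatnonzero(mask)
    if selected.size == 0:
        raise ValueError("empty mask must be repaired before evaluation")
    f1 = classification_error(counts)
    f2 = 0.0
    for a in range(selected.size):
        i = selected[a]
        for j in selected[a + 1 :]:
            f2 += centralities.edge_value(int(i), int(j))
    nc = float(centralities.node[selected].sum())
    f3 = 1.0 / max(nc, epsilon)
    f4 = 1.0 / max(specificity(counts), epsilon)
    return FitnessVector(f1, f2, f3, f4, int(selected.size))
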