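"""Published benchmark results on seven microarray datasets.

Reported per-dataset results for MaPSOGS and seven competing gene-selection
methods (Geometric PSO, basic PSO, RMA, RPSW, EPSO, Hybrid BPSO-BBHA,
PSOC4.5) on the AMLGSE2191, Colon, DLBCL, Leukaemia, Prostate, MLL and SRBCT
microarray datasets: number of selected genes, and LOOCV accuracy (%) under
SVM, decision-tree and KNN classifiers. These are external inputs to the
aggregate-statistics machinery (column means, rank tables, Friedman test) —
the competitor methods themselves are not implemented here. The printed
summary rows of the source tables are kept alongside for cross-checking;
note the published tables round some averages half-up and truncate others,
so reproduced aggregates can differ from the printed ones by one unit in
the last digit.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DATASETS",
    "METHODS",
    "DATASET_SHAPES",
    "gene_count_table",
    "accuracy_table",
    "printed_average",
    "PRINTED_AVERAGE_RANKS",
]

DATASETS = (
    "AMLGSE2191",
    "Colon",
    "DLBCL",
    "Leukaemia",
    "Prostate",
    "MLL",
    "SRBCT",
)

METHODS = (
    "MaPSOGS",
    "Geometric PSO",
    "PSO",
    "RMA",
    "RPSW",
    "EPSO",
    "Hybrid BPSO-BBHA",
    "PSOC4.5",
)

# (n_genes, n_classes, n_samples) of each dataset
DATASET_SHAPES = {
    "AMLGSE2191": (12616, 2, 54),
    "Colon": (7464, 2, 36),
    "DLBCL": (7070, 2, 77),
    "Leukaemia": (5147, 2, 72),
    "Prostate": (12533, 2, 102),
    "MLL": (12533, 3, 72),
    "SRBCT": (2308, 4, 83),
}

# Number of genes selected by each method, per dataset.
_GENE_COUNTS = {
    "AMLGSE2191": (10, 32, 98, 12, 46, 28, 37, 34),
    "Colon": (3, 19, 81, 2, 37, 23, 16, 12),
    "DLBCL": (4, 21, 88, 4, 28, 16, 12, 8),
    "Leukaemia": (6, 18, 85, 5, 24, 21, 28, 24),
    "Prostate": (4, 18, 99, 5, 16, 14, 10, 11),
    "MLL": (3, 9, 94, 4, 18, 19, 8, 12),
    "SRBCT": (6, 12, 78, 6, 16, 31, 18, 10),
}

# LOOCV accuracy (%) per classifier, dataset and method.
_ACCURACY = {
    "svm": {
        "AMLGSE2191": (100.00, 89.01, 82.29, 96.29, 90.48, 91.63, 94.26, 96.88),
        "Colon": (99.52, 89.93, 86.63, 100.00, 91.38, 91.01, 92.25, 95.27),
        "DLBCL": (98.84, 86.08, 83.54, 95.15, 94.24, 91.75, 92.06, 92.65),
        "Leukaemia": (98.71, 86.13, 82.39, 96.81, 91.90, 90.96, 89.92, 93.46),
        "Prostate": (98.38, 85.96, 84.55, 97.41, 90.51, 89.14, 87.92, 91.81),
        "MLL": (96.38, 81.26, 81.67, 91.23, 86.53, 85.98, 86.75, 91.63),
        "SRBCT": (98.91, 84.56, 83.28, 95.37, 91.50, 90.11, 91.70, 93.03),
    },
    "dt": {
        "AMLGSE2191": (97.08, 86.65, 80.90, 95.11, 91.18, 90.01, 91.63, 94.05),
        "Colon": (96.52, 87.05, 84.09, 94.89, 91.55, 89.14, 90.95, 92.64),
        "DLBCL": (94.57, 85.62, 81.33, 92.63, 91.07, 90.22, 89.96, 90.91),
        "Leukaemia": (95.42, 83.39, 82.12, 92.89, 89.69, 88.43, 88.53, 91.57),
        "Prostate": (96.71, 81.93, 83.05, 95.09, 90.28, 86.14, 87.19, 91.18),
        "MLL": (93.44, 80.98, 79.24, 90.93, 85.87, 89.88, 85.28, 90.22),
        "SRBCT": (95.85, 81.66, 80.88, 92.16, 90.02, 90.75, 89.97, 91.76),
    },
    "knn": {
        "AMLGSE2191": (95.36, 87.08, 81.16, 95.11, 90.79, 91.22, 91.05, 93.39),
        "Colon": (96.18, 86.76, 84.88, 94.10, 90.55, 88.21, 90.36, 91.45),
        "DLBCL": (93.89, 86.96, 82.83, 91.49, 91.18, 89.64, 88.07, 90.39),
        "Leukaemia": (93.81, 84.14, 82.66, 91.95, 88.71, 87.19, 89.06, 91.88),
        "Prostate": (94.25, 80.83, 82.69, 93.77, 90.26, 85.55, 86.37, 90.04),
        "MLL": (93.74, 81.49, 80.90, 91.55, 83.72, 88.78, 86.44, 90.61),
        "SRBCT": (94.90, 81.96, 81.13, 92.53, 90.11, 90.01, 88.83, 91.39),
    },
}

# Summary rows as printed in the source tables (for cross-checks only).
_PRINTED_MEANS = {
    "genes": (5.14, 18.42, 89.00, 5.42, 26.42, 21.71, 18.42, 15.85),
    "svm": (98.68, 86.13, 83.48, 96.04, 90.93, 90.08, 90.69, 93.53),
    "dt": (95.65, 83.89, 81.66, 93.38, 89.95, 89.22, 89.07, 91.76),
    "knn": (94.59, 84.18, 82.32, 92.93, 89.33, 88.66, 88.60, 91.31),
}

# Published average ranks per classifier (rank 1 = most accurate method).
PRINTED_AVERAGE_RANKS = {
    "svm": dict(zip(METHODS, (1.14, 7.14, 7.85, 2.14, 4.57, 5.57, 4.71, 2.85))),
    "dt": dict(zip(METHODS, (1.00, 7.28, 7.71, 2.00, 4.28, 5.28, 5.28, 3.14))),
    "knn": dict(zip(METHODS, (1.00, 7.14, 7.85, 2.14, 4.42, 5.14, 5.14, 3.14))),
}


def gene_count_table() -> pd.DataFrame:
    """Selected-gene counts: datasets as rows, methods as columns."""
    return pd.DataFrame.from_dict(
        _GENE_COUNTS, orient="index", columns=list(METHODS), dtype=float
    ).loc[list(DATASETS)]


def accuracy_table(classifier: str) -> pd.DataFrame:
    """Accuracy (%) table for ``classifier`` in {"svm", "dt", "knn"}."""
    try:
        data = _ACCURACY[classifier.lower()]
    except KeyError:
        raise ValueError(f"no published table for classifier {classifier!r}") from None
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(METHODS)
    ).loc[list(DATASETS)]


def printed_average(kind: str, method: str) -> float:
    """Printed column average ('genes', 'svm', 'dt' or 'knn') for a method."""
    return _PRINTED_MEANS[kind][METHODS.index(method)]
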