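"""Expression dataset container, delimited-table I/O and stratified splitting.

The canonical in-memory layout is samples x genes: one row per sample, one
column per gene, plus a vector of categorical class labels (one per sample).
Microarray tables frequently ship transposed (genes as rows); the loader
accepts either orientation and always returns the canonical one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "RunConfig",
    "load_expression_table",
    "write_expression_table",
    "split_stratified",
]


class ValidationError(ValueError):
    """Raised when a table or dataset violates the container invariants."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A labeled samples x genes expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values; must be finite.
    gene_ids : tuple of str
        Unique gene identifiers, one per column.
    labels : tuple
        Class label per sample (opaque identifiers). Class order is the order
        of first appearance, which fixes confusion-matrix layout downstream.
    """

    values: np.ndarray
    gene_ids: tuple
    labels: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values contain missing or non-finite entries")
        if len(self.gene_ids) != values.shape[1]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {values.shape[1]} columns"
            )
        if len(self.labels) != values.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set = set()
            dupes = []
            for g in self.gene_ids:
                if g in seen:
                    dupes.append(g)
                seen.add(g)
            raise ValidationError(f"duplicate gene ids: {sorted(set(dupes))[:5]}")
        if len(self.class_counts()) < 2:
            raise ValidationError("dataset must contain at least 2 distinct classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def class_set(self) -> tuple:
        """Distinct classes in order of first appearance."""
        seen = dict.fromkeys(self.labels)
        return tuple(seen)

    def class_counts(self) -> dict:
        counts: dict = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset_samples(self, indices) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            self.values[idx], self.gene_ids, tuple(self.labels[i] for i in idx)
        )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None


@dataclass
class RunConfig:
    """Parameters of the full selection pipeline.

    filter_mode / lambda_threshold / top_m control the Fisher-score filter
    (lambda is the absolute score threshold; top_m keeps the m best genes).
    theta is the edge-weight threshold on the normalized similarity graph,
    omega the minimum number of selected genes per cluster enforced by the
    repair operator. The swarm parameters follow the usual PSO notation:
    inertia w (kept within [0.5, 0.9]), acceleration constants c1/c2 and the
    velocity clamp v_max.
    """

    filter_mode: str = "top-m"          # "absolute-threshold" | "top-m"
    lambda_threshold: float = 0.0
    top_m: int = 300
    theta: float = 0.6
    omega: int = 1
    swarm_size: int = 30
    max_iterations: int = 100
    inertia_w: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    archive_capacity: int = 50
    cv_folds: int = 5
    classifier_spec: str = "svm"
    seed: int = 0
    epsilon: float = 1e-6
    node_centrality_measure: str = "eigenvector"   # "eigenvector" | "strength"
    edge_centrality_measure: str = "direct-weight"  # "direct-weight" | "betweenness"
    use_repair: bool = True

    def __post_init__(self):
        if self.filter_mode not in ("absolute-threshold", "top-m"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.lambda_threshold < 0:
            raise ValueError("lambda_threshold must be non-negative")
        if self.top_m < 1:
            raise ValueError("top_m must be a positive integer")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.omega < 0:
            raise ValueError("omega must be a non-negative integer")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not 0.5 <= self.inertia_w <= 0.9:
            raise ValueError("inertia_w must lie in [0.5, 0.9]")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.archive_capacity < 1:
            raise ValueError("archive_capacity must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be a small positive real")

    @classmethod
    def from_key_values(cls, text: str, **overrides) -> "RunConfig":
        """Build a config from flat ``key=value`` lines; kwargs override."""
        params: dict = {}
        for lineno, raw in enumerate(io.StringIO(text), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            params[key] = value
        params.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name: f.type for f in fields(cls)}
        casts = {
            "filter_mode": str, "classifier_spec": str,
            "node_centrality_measure": str, "edge_centrality_measure": str,
            "lambda_threshold": float, "theta": float, "inertia_w": float,
            "c1": float, "c2": float, "v_max": float, "epsilon": float,
            "top_m": int, "omega": int, "swarm_size": int, "max_iterations": int,
            "archive_capacity": int, "cv_folds": int, "seed": int,
            "use_repair": lambda s: str(s).lower() in ("1", "true", "yes"),
        }
        kwargs = {}
        for key, value in params.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts.get(key, str)(value) if isinstance(value, str) else value
        return cls(**kwargs)


def _sniff_sep(path) -> str:
    with open(path, "r", newline="") as handle:
        header = handle.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def load_expression_table(
    path,
    label_column: str = "class",
    orientation: str = "samples-as-rows",
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    ``orientation="genes-as-rows"`` expects gene identifiers in the first
    column and one column per sample, with a final row (indexed by
    ``label_column``) carrying the class labels; the table is transposed into
    the canonical samples x genes layout.
    """
    if orientation not in ("samples-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = sep or _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, header=0, index_col=None, dtype=str)
    if orientation == "genes-as-rows":
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
        frame.columns.name = None
    if label_column not in frame.columns:
        raise ValidationError(f"label column {label_column!r} not found in {path}")
    labels = tuple(frame[label_column].astype(str))
    expr = frame.drop(columns=[label_column])
    gene_ids = tuple(str(c) for c in expr.columns)
    raw = expr.to_numpy()
    empty = pd.isna(expr).to_numpy() | (expr == "").to_numpy()
    if empty.any():
        r, c = np.argwhere(empty)[0]
        raise ValidationError(
            f"empty cell at data row {r + 1}, column {gene_ids[c]!r}"
        )
    try:
        values = raw.astype(float)
    except ValueError:
        for r in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                try:
                    float(raw[r, c])
                except ValueError:
                    raise ValidationError(
                        f"non-numeric cell {raw[r, c]!r} at data row {r + 1}, "
                        f"column {gene_ids[c]!r}"
                    ) from None
        raise
    return ExpressionDataset(values, gene_ids, labels)


def write_expression_table(
    dataset: ExpressionDataset, path, label_column: str = "class", sep: str = ","
) -> None:
    """Write a dataset as delimited text readable by :func:`load_expression_table`.

    Values are printed with ``repr``-level precision so a load/write round
    trip is lossless for float64.
    """
    frame = pd.DataFrame(dataset.values, columns=list(dataset.gene_ids))
    if label_column in frame.columns:
        raise ValidationError(
            f"gene id {label_column!r} collides with the label column name"
        )
    frame[label_column] = list(dataset.labels)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def split_stratified(
    dataset: ExpressionDataset, test_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Class-stratified disjoint train/test split.

    Per class, round(class_size * test_fraction) samples go to the test side
    (at least one sample of every class is kept on each side). Same seed,
    same split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = dataset.label_array()
    small = [c for c, n in dataset.class_counts().items() if n < 2]
    if small:
        raise ValidationError(
            f"stratified split needs >= 2 samples per class; too small: {small}"
        )
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in dataset.class_set:
        members = np.flatnonzero(labels == cls)
        n_test = int(round(len(members) * test_fraction))
        n_test = min(max(n_test, 1), len(members) - 1)
        if len(members) - n_test < 1:
            raise ValidationError(f"class {cls!r} would be emptied in train")
        perm = rng.permutation(members)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    train_idx.sort()
    test_idx.sort()
    return dataset.subset_samples(train_idx), dataset.subset_samples(test_idx)
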