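"""Synthetic labeled expression data with planted structure.

The generator emulates the shape of small-sample microarray studies: tens of
samples, hundreds-to-thousands of genes, a handful of co-expressed gene
modules and a small set of class-discriminative genes. Gene modules are built
as equicorrelated blocks sharing one latent factor, so the pairwise
within-block Pearson correlation has the closed-form target rho and a graph
clustering step has a well-defined ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_samples, n_genes, n_classes : int
        Matrix shape and number of balanced classes.
    block_sizes : tuple of int, optional
        Sizes of the planted correlated gene blocks; genes beyond the blocks
        are independent noise genes. ``n_blocks`` is ``len(block_sizes)``.
        The default (None) partitions all genes into four near-equal blocks
        (fewer when there are fewer genes than blocks).
    rho : float in [0, 1)
        Target pairwise Pearson correlation inside each block.
    n_relevant : int
        Number of class-informative genes. They are placed at the head of the
        blocks, round-robin across blocks, so informative genes are spread
        over clusters (any surplus beyond the blocks goes to noise genes).
    delta : float
        Class-mean shift in units of noise_sd: class k is shifted by
        ``k * delta * noise_sd`` on each relevant gene.
    noise_sd : float
        Standard deviation of the per-gene noise component.
    """

    n_samples: int = 60
    n_genes: int = 100
    n_classes: int = 2
    block_sizes: tuple | None = None
    rho: float = 0.8
    n_relevant: int = 5
    delta: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.block_sizes is None:
            n_blocks = min(4, self.n_genes)
            base, extra = divmod(self.n_genes, n_blocks)
            sizes = tuple(base + (1 if b < extra else 0) for b in range(n_blocks))
            object.__setattr__(self, "block_sizes", sizes)
        else:
            object.__setattr__(
                self, "block_sizes", tuple(int(b) for b in self.block_sizes)
            )
        if self.n_samples < 4 or self.n_genes < 1:
            raise ValueError("need n_samples >= 4 and n_genes >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes must sum to at most n_genes")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.n_relevant <= self.n_genes:
            raise ValueError("n_relevant must lie in [0, n_genes]")
        if self.delta < 0 or self.noise_sd <= 0:
            raise ValueError("delta must be >= 0 and noise_sd > 0")

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated dataset.

    ``block_assignment`` maps every gene id to its block index, or ``"free"``
    for unblocked noise genes.
    """

    relevant_gene_ids: frozenset
    block_assignment: dict = field(compare=False)

    def block_labels(self, gene_ids) -> list:
        return [self.block_assignment[g] for g in gene_ids]


def _relevant_positions(spec: SyntheticSpec) -> list[int]:
    """Column indices of the relevant genes: round-robin over block heads."""
    starts = np.concatenate([[0], np.cumsum(spec.block_sizes)])
    positions: list[int] = []
    depth = 0
    while len(positions) < spec.n_relevant:
        placed = False
        for b, size in enumerate(spec.block_sizes):
            if depth < size and len(positions) < spec.n_relevant:
                positions.append(int(starts[b]) + depth)
                placed = True
        if not placed:  # blocks exhausted -> spill into free genes
            base = int(starts[-1])
            while len(positions) < spec.n_relevant:
                positions.append(base)
                base += 1
            break
        depth += 1
    return positions


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset according to ``spec``. Deterministic in ``spec.seed``.

    Within a block, gene g = sqrt(rho) * latent_block + sqrt(1 - rho) * eps_g
    (both standard normal, scaled by noise_sd), which gives every within-block
    pair correlation rho in expectation. Relevant genes additionally receive
    the class-dependent mean shift. Labels are balanced to within one sample.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_genes
    labels_int = np.arange(n) % spec.n_classes
    rng.shuffle(labels_int)

    values = np.empty((n, p))
    block_of = np.full(p, -1, dtype=int)
    col = 0
    for b, size in enumerate(spec.block_sizes):
        latent = rng.standard_normal(n)
        eps = rng.standard_normal((n, size))
        values[:, col : col + size] = spec.noise_sd * (
            np.sqrt(spec.rho) * latent[:, None] + np.sqrt(1.0 - spec.rho) * eps
        )
        block_of[col : col + size] = b
        col += size
    if col < p:
        values[:, col:] = spec.noise_sd * rng.standard_normal((n, p - col))

    relevant = _relevant_positions(spec)
    shift = spec.delta * spec.noise_sd
    for j in relevant:
        values[:, j] += labels_int * shift

    gene_ids = tuple(f"G{j + 1}" for j in range(p))
    labels = tuple(f"class{k}" for k in labels_int)
    dataset = ExpressionDataset(values, gene_ids, labels)
    truth = GroundTruth(
        relevant_gene_ids=frozenset(gene_ids[j] for j in relevant),
        block_assignment={
            g: (int(block_of[j]) if block_of[j] >= 0 else "free")
            for j, g in enumerate(gene_ids)
        },
    )
    return dataset, truth
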