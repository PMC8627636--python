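"""Many-objective binary PSO with a Pareto archive and cluster repair.

Particles are binary selection masks over the filtered genes with a real
velocity per gene. Velocities follow the canonical PSO update

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),

clamped to [-v_max, v_max]; bits are re-drawn through the sigmoid transfer
rule (bit = 1 with probability 1/(1+exp(-v))), the standard binarization of
continuous PSO. Fitness vectors are compared by Pareto dominance; mutually
nondominated solutions accumulate in a bounded external archive pruned by
crowding distance, which also supplies the global guide via binary
tournament. Before evaluation every particle passes through the repair
operator, which enforces that each Louvain cluster contributes at least
omega selected genes by swapping the globally weakest (lowest-Fisher)
selected genes for the strongest unselected genes of uncovered clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import GeneClustering, louvain
from .data import ExpressionDataset, RunConfig
from .filtering import (
    FisherScores,
    GeneSubset,
    filter_genes,
    fisher_scores,
    normalize_scores,
)
from .graph import CentralityTables, WeightedGeneGraph, build_gene_graph
from .objectives import FitnessVector, evaluate_subset_cv, fitness_vector

__all__ = [
    "Particle",
    "ParetoArchive",
    "dominates",
    "crowding_distances",
    "initialize_swarm",
    "update_particle",
    "repair",
    "select_gbest",
    "final_solution",
    "run_mapsogs",
    "SelectionResult",
]

logger = logging.getLogger(__name__)


def dominates(a, b) -> bool:
    """Pareto dominance for minimization: a <= b everywhere, < somewhere."""
    av = a.as_array() if isinstance(a, FitnessVector) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, FitnessVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("fitness vectors differ in length")
    return bool(np.all(av <= bv) and np.any(av < bv))


@dataclass
class Particle:
    """One swarm member: mask, velocity and personal best."""

    mask: np.ndarray
    velocity: np.ndarray
    fitness: FitnessVector | None = None
    best_mask: np.ndarray | None = None
    best_fitness: FitnessVector | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.mask.shape != self.velocity.shape:
            raise ValueError("mask and velocity must have equal length")


def crowding_distances(vectors: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of each row; boundary points get inf."""
    vectors = np.asarray(vectors, dtype=float)
    n, m = vectors.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(vectors[:, j], kind="stable")
        col = vectors[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span == 0:
            continue
        dist[order[1:-1]] += (col[2:] - col[:-2]) / span
    return dist


class ParetoArchive:
    """Bounded store of mutually nondominated (mask, fitness) pairs."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("archive capacity must be positive")
        self.capacity = capacity
        self.members: list[tuple[np.ndarray, FitnessVector]] = []

    def __len__(self) -> int:
        return len(self.members)

    def fitness_matrix(self) -> np.ndarray:
        return np.array([f.as_array() for _, f in self.members])

    def update(self, mask: np.ndarray, fitness: FitnessVector) -> bool:
        """Insert a candidate; returns True if it entered the archive.

        Dominated candidates are rejected, members dominated by the
        candidate are evicted, and capacity overflow drops the most crowded
        member (smallest crowding distance, lowest index on ties).
        """
        mask = np.asarray(mask, dtype=bool)
        for m, f in self.members:
            if dominates(f, fitness):
                return False
            if np.array_equal(m, mask) and np.array_equal(
                f.as_array(), fitness.as_array()
            ):
                return False  # exact duplicate
        self.members = [
            (m, f) for m, f in self.members if not dominates(fitness, f)
        ]
        self.members.append((mask.copy(), fitness))
        if len(self.members) > self.capacity:
            dist = crowding_distances(self.fitness_matrix())
            drop = int(np.argmin(dist))
            del self.members[drop]
        return True

    def assert_nondominated(self) -> None:
        for i, (_, fi) in enumerate(self.members):
            for j, (_, fj) in enumerate(self.members):
                if i != j and dominates(fi, fj):
                    raise AssertionError("archive contains dominated members")


def select_gbest(archive: ParetoArchive, rng: np.random.Generator) -> np.ndarray:
    """Global guide by binary tournament on crowding distance (less crowded wins)."""
    if len(archive) == 0:
        raise ValueError("archive is empty")
    if len(archive) == 1:
        return archive.members[0][0]
    dist = crowding_distances(archive.fitness_matrix())
    i, j = rng.integers(0, len(archive), size=2)
    winner = i if dist[i] >= dist[j] else j
    return archive.members[int(winner)][0]


def initialize_swarm(
    n_particles: int,
    n_genes: int,
    selection_probs: np.ndarray,
    seed: int | np.random.Generator,
) -> list[Particle]:
    """Score-biased random swarm: gene g is selected with probability
    clip(normalized_fisher(g), 0.05, 0.95); velocities start at 0 and empty
    masks are re-drawn."""
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.clip(np.asarray(selection_probs, dtype=float), 0.05, 0.95)
    if probs.shape != (n_genes,):
        raise ValueError("one selection probability per gene required")
    swarm = []
    for _ in range(n_particles):
        mask = rng.random(n_genes) < probs
        while not mask.any():
            mask = rng.random(n_genes) < probs
        swarm.append(Particle(mask=mask, velocity=np.zeros(n_genes)))
    return swarm


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_particle(
    particle: Particle,
    gbest_mask: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator,
    selection_probs: np.ndarray | None = None,
) -> Particle:
    """Velocity update, clamp, and sigmoid-transfer re-draw of the mask.

    Fresh r1, r2 ~ U[0,1] are drawn per dimension. An all-zero outcome gets
    the gene with the highest selection probability re-enabled so the mask
    stays evaluable.
    """
    x = particle.mask.astype(float)
    pbest = (particle.best_mask if particle.best_mask is not None else particle.mask)
    g = np.asarray(gbest_mask, dtype=float)
    if g.shape != x.shape:
        raise ValueError("gbest mask length mismatch")
    r1 = rng.random(x.shape)
    r2 = rng.random(x.shape)
    v = (
        config.inertia_w * particle.velocity
        + config.c1 * r1 * (pbest.astype(float) - x)
        + config.c2 * r2 * (g - x)
    )
    np.clip(v, -config.v_max, config.v_max, out=v)
    new_mask = rng.random(x.shape) < _sigmoid(v)
    if not new_mask.any():
        if selection_probs is None:
            new_mask[int(np.argmax(v))] = True
        else:
            new_mask[int(np.argmax(selection_probs))] = True
    particle.velocity = v
    particle.mask = new_mask
    return particle


def repair(
    mask: np.ndarray,
    clustering: GeneClustering,
    scores: FisherScores | np.ndarray,
    omega: int,
) -> np.ndarray:
    """Enforce that every cluster contributes >= min(omega, cluster size) genes.

    Deficient clusters are processed in ascending cluster index. Each missing
    slot is filled by the cluster's highest-Fisher unselected gene; in
    exchange the globally lowest-Fisher selected gene whose own cluster stays
    covered is dropped, keeping the subset size constant. When no such donor
    exists the gene is added without removal (the mask grows; logged).
    omega = 0 leaves every mask unchanged.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if omega == 0:
        return mask
    score_arr = scores.scores if isinstance(scores, FisherScores) else np.asarray(scores, float)
    assignment = clustering.assignment
    if len(assignment) != mask.size or len(score_arr) != mask.size:
        raise ValueError("clustering and scores must cover all mask positions")

    n_clusters = clustering.n_clusters
    cluster_sizes = np.bincount(assignment, minlength=n_clusters)
    required = np.minimum(omega, cluster_sizes)

    def selected_per_cluster() -> np.ndarray:
        return np.bincount(assignment[mask], minlength=n_clusters)

    for c in range(n_clusters):
        counts = selected_per_cluster()
        while counts[c] < required[c]:
            members = np.flatnonzero((assignment == c) & ~mask)
            if members.size == 0:  # cannot happen: required <= cluster size
                break
            incoming = members[np.argmax(score_arr[members])]
            # donor: globally lowest-Fisher selected gene whose removal keeps
            # its own cluster at or above its requirement
            donors = np.flatnonzero(mask)
            removable = [
                d for d in donors if counts[assignment[d]] > required[assignment[d]]
            ]
            mask[incoming] = True
            if removable:
                removable = np.array(removable)
                outgoing = removable[np.argmin(score_arr[removable])]
                mask[outgoing] = False
            else:
                logger.debug("repair grew mask: no removable donor for cluster %d", c)
            counts = selected_per_cluster()
    return mask


def final_solution(archive: ParetoArchive) -> np.ndarray:
    """Pick the single reported solution from the archive.

    Minimum classification error f1; ties broken by smaller subset size f5,
    then smaller 1/specificity f4, then the lexicographically smallest mask.
    """
    if len(archive) == 0:
        raise ValueError("archive is empty")

    def key(member):
        mask, f = member
        return (f.f1, f.f5, f.f4, tuple(int(b) for b in mask))

    return min(archive.members, key=key)[0]


@dataclass
class SelectionResult:
    """Everything produced by one end-to-end selection run."""

    subset: GeneSubset                 # final selected genes (original ids)
    filtered_genes: GeneSubset         # genes surviving the Fisher filter
    archive: ParetoArchive
    clustering: GeneClustering
    graph: WeightedGeneGraph
    centralities: CentralityTables
    scores: FisherScores
    trace: list = field(default_factory=list)  # (iteration, best f1, archive size)
    iterations_run: int = 0

    def trace_best_f1(self) -> list[float]:
        return [row[1] for row in self.trace]


def run_mapsogs(dataset: ExpressionDataset, config: RunConfig) -> SelectionResult:
    """Full pipeline: filter -> graph -> cluster -> swarm search -> solution.

    Deterministic given (dataset, config): every random draw flows from
    config.seed. The swarm loop repairs each particle, evaluates its fitness
    (cached by mask), updates personal bests and the archive, then moves the
    swarm; it stops at max_iterations or when an iteration leaves every mask
    unchanged. The trace records the archive's best f1 per iteration.
    """
    scores = fisher_scores(dataset)
    if config.filter_mode == "top-m":
        filtered = filter_genes(scores, "top-m", min(config.top_m, dataset.n_genes))
    else:
        filtered = filter_genes(scores, "absolute-threshold", config.lambda_threshold)

    graph, centralities = build_gene_graph(
        dataset,
        filtered,
        config.theta,
        node_measure=config.node_centrality_measure,
        edge_measure=config.edge_centrality_measure,
    )
    clustering = louvain(graph, seed=config.seed)

    gene_ids = filtered.gene_ids
    index = {g: i for i, g in enumerate(dataset.gene_ids)}
    filtered_scores = scores.scores[[index[g] for g in gene_ids]]
    norm_all = normalize_scores(scores)
    probs = np.array([norm_all[g] for g in gene_ids])

    rng = np.random.default_rng(config.seed)
    n = len(gene_ids)
    swarm = initialize_swarm(config.swarm_size, n, probs, rng)
    archive = ParetoArchive(config.archive_capacity)
    fitness_cache: dict[bytes, FitnessVector] = {}

    def evaluate(mask: np.ndarray) -> FitnessVector:
        key = mask.tobytes()
        cached = fitness_cache.get(key)
        if cached is not None:
            return cached
        counts = evaluate_subset_cv(
            dataset,
            GeneSubset.from_mask(mask, gene_ids),
            classifier_spec=config.classifier_spec,
            folds=config.cv_folds,
            seed=config.seed,
        )
        fit = fitness_vector(mask, centralities, counts, epsilon=config.epsilon)
        fitness_cache[key] = fit
        return fit

    trace: list[tuple[int, float, int]] = []
    iterations = 0
    for iteration in range(config.max_iterations):
        iterations = iteration + 1
        for particle in swarm:
            if config.use_repair:
                particle.mask = repair(
                    particle.mask, clustering, filtered_scores, config.omega
                )
            particle.fitness = evaluate(particle.mask)
            if particle.best_fitness is None or dominates(
                particle.fitness, particle.best_fitness
            ):
                particle.best_mask = particle.mask.copy()
                particle.best_fitness = particle.fitness
            elif not dominates(particle.best_fitness, particle.fitness):
                if rng.random() < 0.5:  # mutually nondominated: coin flip
                    particle.best_mask = particle.mask.copy()
                    particle.best_fitness = particle.fitness
            archive.update(particle.mask, particle.fitness)
        best_f1 = min(f.f1 for _, f in archive.members)
        trace.append((iteration, best_f1, len(archive)))

        moved = False
        for particle in swarm:
            old = particle.mask.copy()
            gbest = select_gbest(archive, rng)
            update_particle(particle, gbest, config, rng, selection_probs=probs)
            if not np.array_equal(old, particle.mask):
                moved = True
        if not moved:
            break

    best_mask = final_solution(archive)
    subset = GeneSubset.from_mask(best_mask, gene_ids)
    return SelectionResult(
        subset=subset,
        filtered_genes=filtered,
        archive=archive,
        clustering=clustering,
        graph=graph,
        centralities=centralities,
        scores=scores,
        trace=trace,
        iterations_run=iterations,
    )
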