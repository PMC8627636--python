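import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapsogs.clustering import GeneClustering
from mapsogs.data import RunConfig
from mapsogs.objectives import FitnessVector
from mapsogs.swarm import (
    ParetoArchive,
    Particle,
    crowding_distances,
    dominates,
    final_solution,
    initialize_swarm,
    repair,
    run_mapsogs,
    select_gbest,
    update_particle,
)
from mapsogs.synthetic import SyntheticSpec, generate_dataset

fitness_vectors = st.lists(
    st.floats(min_value=0, max_value=10, allow_nan=False), min_size=5, max_size=5
).map(np.array)


class TestDominates:
    def test_equal_vectors_do_not_dominate(self):
        v = np.array([1.0, 2, 3, 4, 5])
        assert not dominates(v, v)

    def test_strictly_smaller_dominates(self):
        assert dominates([0, 1, 2, 3, 4], [1, 2, 3, 4, 5])

    def test_single_component_improvement(self):
        a, b = [1, 2, 3, 4, 5], [1, 2, 3, 4, 6]
        assert dominates(a, b) and not dominates(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dominates([1, 2], [1, 2, 3])

    @given(a=fitness_vectors, b=fitness_vectors, c=fitness_vectors)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_axioms_on_random_vectors(self, a, b, c):
        """Irreflexivity, antisymmetry and transitivity of Pareto dominance."""
        assert not dominates(a, a)
        assert not (dominates(a, b) and dominates(b, a))
        if dominates(a, b) and dominates(b, c):
            assert dominates(a, c)


class TestInitializeSwarm:
    def test_same_seed_identical_masks(self):
        probs = np.full(30, 0.5)
        a = initialize_swarm(10, 30, probs, seed=4)
        b = initialize_swarm(10, 30, probs, seed=4)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.mask, pb.mask)

    def test_density_tracks_probabilities(self):
        probs = np.full(50, 0.5)
        swarm = initialize_swarm(1000, 50, probs, seed=0)
        density = np.mean([p.mask.mean() for p in swarm])
        assert 0.45 <= density <= 0.55

    def test_no_empty_masks_even_with_floor_probs(self):
        probs = np.zeros(10)  # floored to 0.05
        swarm = initialize_swarm(200, 10, probs, seed=1)
        assert all(p.mask.any() for p in swarm)
        assert all(np.all(p.velocity == 0) for p in swarm)


class TestUpdateParticle:
    def test_hand_computed_velocity(self):
        # w=0.5, v=1, c1=c2=2, r1=r2=0.5, (pbest-x)=1, (gbest-x)=0 -> v'=1.5
        config = RunConfig(inertia_w=0.5, c1=2.0, c2=2.0, v_max=4.0)

        class FixedRng:
            def random(self, shape=None):
                return np.full(shape, 0.5) if shape else 0.5

        particle = Particle(
            mask=np.array([False]), velocity=np.array([1.0]),
            best_mask=np.array([True]),
        )
        update_particle(particle, np.array([False]), config, FixedRng())
        assert particle.velocity[0] == pytest.approx(1.5)

    def test_zero_velocity_flip_probability_half(self):
        """x = pbest = gbest and v = 0: the transfer rule flips each bit on
        with probability sigmoid(0) = 0.5."""
        config = RunConfig(inertia_w=0.7)
        rng = np.random.default_rng(0)
        n, draws = 100, 100
        ones = 0
        for _ in range(draws):
            particle = Particle(
                mask=np.ones(n, bool), velocity=np.zeros(n),
                best_mask=np.ones(n, bool),
            )
            update_particle(particle, np.ones(n, bool), config, rng)
            ones += particle.mask.sum()
        assert abs(ones / (n * draws) - 0.5) < 0.02

    def test_velocity_clamped(self):
        config = RunConfig(inertia_w=0.9, c1=10.0, c2=10.0, v_max=2.5)
        rng = np.random.default_rng(3)
        particle = Particle(
            mask=np.zeros(20, bool), velocity=np.full(20, 2.5),
            best_mask=np.ones(20, bool),
        )
        for _ in range(10):
            update_particle(particle, np.ones(20, bool), config, rng)
            assert np.all(np.abs(particle.velocity) <= 2.5)

    def test_all_zero_mask_reenabled(self):
        config = RunConfig(inertia_w=0.5, v_max=50.0, c1=20.0, c2=20.0)

        class PushDownRng:  # drives velocities hard negative, draws high
            def random(self, shape=None):
                return np.full(shape, 0.999) if shape else 0.999

        particle = Particle(
            mask=np.ones(5, bool), velocity=np.full(5, -50.0),
            best_mask=np.zeros(5, bool),
        )
        probs = np.array([0.1, 0.9, 0.2, 0.3, 0.4])
        update_particle(
            particle, np.zeros(5, bool), config, PushDownRng(), selection_probs=probs
        )
        np.testing.assert_array_equal(
            particle.mask, [False, True, False, False, False]
        )


def _clustering(assignment):
    ids = tuple(f"G{i+1}" for i in range(len(assignment)))
    return GeneClustering(ids, np.asarray(assignment), 0.0)


class TestRepair:
    def test_worked_three_cluster_example(self):
        """Ten genes in three clusters, selection {G1,G3,G7,G10} covering
        only clusters 1-2: the lowest-Fisher selected gene (G7) is swapped
        for the highest-Fisher gene of the uncovered cluster (G9)."""
        clustering = _clustering([0, 0, 0, 1, 1, 1, 1, 2, 2, 1])
        scores = np.array([0.9, 0.3, 0.8, 0.2, 0.1, 0.15, 0.05, 0.5, 0.7, 0.6])
        mask = np.zeros(10, bool)
        mask[[0, 2, 6, 9]] = True  # G1, G3, G7, G10
        repaired = repair(mask, clustering, scores, omega=1)
        expected = np.zeros(10, bool)
        expected[[0, 2, 8, 9]] = True  # G1, G3, G9, G10
        np.testing.assert_array_equal(repaired, expected)

    def test_covered_clusters_unchanged(self):
        clustering = _clustering([0, 0, 1, 1, 2, 2])
        scores = np.arange(6, dtype=float)
        mask = np.array([1, 0, 1, 0, 1, 0], bool)
        np.testing.assert_array_equal(
            repair(mask, clustering, scores, omega=1), mask
        )

    def test_omega_zero_identity(self):
        clustering = _clustering([0, 1, 2])
        mask = np.array([1, 0, 0], bool)
        np.testing.assert_array_equal(
            repair(mask, clustering, scores=np.ones(3), omega=0), mask
        )

    def test_size_preserved_when_donors_exist(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = 12
            clustering = _clustering(rng.integers(0, 3, size=n))
            scores = rng.random(n)
            mask = rng.random(n) < 0.5
            mask[rng.integers(0, n)] = True  # never empty
            repaired = repair(mask, clustering, scores, omega=1)
            assignment = clustering.assignment
            sizes = np.bincount(assignment, minlength=3)
            covered = np.bincount(assignment[repaired], minlength=3)
            assert np.all(covered >= np.minimum(1, sizes))
            if mask.sum() >= len(np.unique(assignment)):
                assert repaired.sum() == mask.sum()

    def test_grows_when_no_donor_available(self):
        # two singleton clusters, one selected gene: nothing removable
        clustering = _clustering([0, 1])
        mask = np.array([1, 0], bool)
        repaired = repair(mask, clustering, np.array([0.5, 0.6]), omega=1)
        assert repaired.sum() == 2

    def test_cluster_coverage_never_decreases(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = 15
            assignment = rng.integers(0, 4, size=n)
            _, assignment = np.unique(assignment, return_inverse=True)
            clustering = _clustering(assignment)
            scores = rng.random(n)
            mask = rng.random(n) < 0.4
            mask[0] = True
            before = len(np.unique(assignment[mask]))
            repaired = repair(mask, clustering, scores, omega=2)
            after = len(np.unique(assignment[repaired]))
            assert after >= before


def _fv(*values):
    return FitnessVector(*values)


class TestParetoArchive:
    def test_dominated_candidate_rejected(self):
        archive = ParetoArchive(capacity=5)
        archive.update(np.array([True, False]), _fv(0.1, 0, 1, 1, 1))
        assert not archive.update(np.array([False, True]), _fv(0.2, 1, 2, 2, 2))
        assert len(archive) == 1

    def test_candidate_evicts_dominated_members(self):
        archive = ParetoArchive(capacity=5)
        archive.update(np.array([1, 0, 0], bool), _fv(0.3, 1, 1, 1, 2))
        archive.update(np.array([0, 1, 0], bool), _fv(0.4, 2, 2, 2, 3))
        assert archive.update(np.array([0, 0, 1], bool), _fv(0.2, 0.5, 0.5, 1, 1))
        assert len(archive) == 1

    def test_capacity_eviction_targets_smallest_crowding(self):
        """Overflowing member with minimal crowding distance is dropped,
        verified by recomputing all crowding distances by hand."""
        archive = ParetoArchive(capacity=4)
        # mutually nondominated ladder on (f1, f5)
        fits = [
            _fv(0.5, 0, 1, 1, 1),
            _fv(0.4, 0, 1, 1, 2),
            _fv(0.3, 0, 1, 1, 3),
            _fv(0.31, 0, 1, 1, 4),   # crowded near the previous one
            _fv(0.1, 0, 1, 1, 5),
        ]
        for i, f in enumerate(fits):
            mask = np.zeros(5, bool)
            mask[i] = True
            archive.update(mask, f)
        assert len(archive) == 4
        survivors = {tuple(f.as_array()) for _, f in archive.members}
        all_dist = crowding_distances(np.array([f.as_array() for f in fits]))
        evicted = int(np.argmin(all_dist))
        assert tuple(fits[evicted].as_array()) not in survivors
        archive.assert_nondominated()

    def test_pairwise_nondominated_after_random_updates(self):
        rng = np.random.default_rng(2)
        archive = ParetoArchive(capacity=10)
        for _ in range(200):
            vec = rng.integers(0, 4, size=5).astype(float)
            mask = rng.random(6) < 0.5
            mask[0] = True
            archive.update(mask, _fv(*vec))
            archive.assert_nondominated()
            assert len(archive) <= 10


class TestSelectGbest:
    def test_singleton_archive_returned(self):
        archive = ParetoArchive(3)
        mask = np.array([True, False])
        archive.update(mask, _fv(0.1, 0, 1, 1, 1))
        np.testing.assert_array_equal(
            select_gbest(archive, np.random.default_rng(0)), mask
        )

    def test_less_crowded_wins_tournament(self):
        archive = ParetoArchive(5)
        for i, f in enumerate(
            [_fv(0.5, 0, 1, 1, 1), _fv(0.45, 0, 1, 1, 2), _fv(0.1, 0, 1, 1, 9)]
        ):
            mask = np.zeros(3, bool)
            mask[i] = True
            archive.update(mask, f)

        class BothRng:
            def integers(self, low, high, size):
                return np.array([1, 2])  # middle (crowded) vs boundary (inf)

        winner = select_gbest(archive, BothRng())
        np.testing.assert_array_equal(winner, [False, False, True])

    def test_seeded_rng_reproducible_sequence(self):
        archive = ParetoArchive(5)
        for i in range(4):
            mask = np.zeros(4, bool)
            mask[i] = True
            archive.update(mask, _fv(0.5 - 0.1 * i, 0, 1, 1, i + 1))
        seq_a = [select_gbest(archive, np.random.default_rng(9)).tolist() for _ in range(1)]
        seq_b = [select_gbest(archive, np.random.default_rng(9)).tolist() for _ in range(1)]
        assert seq_a == seq_b

    def test_empty_archive_rejected(self):
        with pytest.raises(ValueError):
            select_gbest(ParetoArchive(2), np.random.default_rng(0))


class TestFinalSolution:
    def test_singleton_archive(self):
        archive = ParetoArchive(2)
        mask = np.array([True, False])
        archive.update(mask, _fv(0.2, 0, 1, 1, 1))
        np.testing.assert_array_equal(final_solution(archive), mask)

    def test_tie_break_rule_enumeration(self):
        archive = ParetoArchive(5)
        entries = [
            (np.array([1, 1, 1, 1, 1, 1, 1, 1], bool), _fv(0.1, 0, 1, 1, 8)),
            (np.array([1, 1, 1, 1, 1, 0, 0, 0], bool), _fv(0.1, 0, 1, 1, 5)),
            (np.array([1, 1, 0, 0, 0, 0, 0, 0], bool), _fv(0.2, 0, 1, 1, 2)),
        ]
        for mask, f in entries:
            archive.members.append((mask, f))  # bypass dominance filtering
        winner = final_solution(archive)
        np.testing.assert_array_equal(winner, entries[1][0])

    def test_result_is_archive_member(self):
        rng = np.random.default_rng(1)
        archive = ParetoArchive(8)
        for _ in range(30):
            mask = rng.random(6) < 0.5
            mask[0] = True
            archive.update(mask, _fv(*rng.integers(0, 5, size=5).astype(float)))
        winner = final_solution(archive)
        assert any(np.array_equal(winner, m) for m, _ in archive.members)


@pytest.fixture(scope="module")
def small_run():
    ds, truth = generate_dataset(
        SyntheticSpec(n_samples=40, n_genes=30, n_relevant=3, seed=2)
    )
    config = RunConfig(swarm_size=10, max_iterations=8, seed=2)
    return ds, truth, config, run_mapsogs(ds, config)


class TestRunMapsogs:
    def test_same_seed_identical_subset(self, small_run):
        ds, _, config, result = small_run
        again = run_mapsogs(ds, config)
        assert again.subset.gene_ids == result.subset.gene_ids
        np.testing.assert_array_equal(
            again.archive.fitness_matrix(), result.archive.fitness_matrix()
        )

    def test_final_subset_covers_every_cluster(self, small_run):
        _, _, config, result = small_run
        assignment = result.clustering.assignment
        mask = result.subset.mask(result.filtered_genes.gene_ids)
        sizes = np.bincount(assignment)
        covered = np.bincount(assignment[mask], minlength=len(sizes))
        assert np.all(covered >= np.minimum(config.omega, sizes))

    def test_trace_and_archive_sane(self, small_run):
        _, _, _, result = small_run
        assert 1 <= len(result.trace) <= 8
        best = result.trace_best_f1()
        assert all(b >= a - 1e-12 for a, b in zip(best[1:], best))  # non-increasing
        result.archive.assert_nondominated()

    def test_selects_informative_genes(self, small_run):
        _, truth, _, result = small_run
        assert set(result.subset.gene_ids) & truth.relevant_gene_ids
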