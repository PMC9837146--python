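import numpy as np
import pytest
from scipy import stats

from complevo import (
    Population,
    SimulationConfig,
    compute_selection_weights,
    init_population,
    run,
    step,
)
from complevo.dynamics import apply_parasite_conversion, mutate, reproduce


def _pop(alleles, deletions, m):
    return Population(np.asarray(alleles, dtype=np.uint8),
                      np.asarray(deletions), m=m)


class TestSelectionWeights:
    def test_fitness_proportional_groups(self, valley_landscape):
        pop = _pop([[1, 1], [0, 0]], [0, 0], m=1)
        w = compute_selection_weights(pop, valley_landscape, "none", beta_C=5)
        assert w.group_probs == pytest.approx([1 / 1.2, 0.2 / 1.2])

    def test_equal_fitness_is_uniform(self, flat_landscape):
        pop = _pop([[0, 1], [1, 0], [1, 1], [0, 0]], [0] * 4, m=2)
        w = compute_selection_weights(pop, flat_landscape, "full_trans", beta_C=5)
        assert w.group_probs == pytest.approx([0.5, 0.5])

    def test_zero_total_fitness_falls_back_to_uniform(self, valley_landscape):
        pop = _pop([[0, 1], [1, 0]], [1, 2], m=1)  # all parasites, f_g = 0
        w = compute_selection_weights(pop, valley_landscape, "full_cis", beta_C=5)
        assert w.degenerate
        assert w.group_probs == pytest.approx([0.5, 0.5])

    def test_member_probs_normalized(self, valley_landscape):
        pop = _pop([[1, 1], [1, 1], [0, 0], [0, 0]], [0, 1, 0, 0], m=2)
        w = compute_selection_weights(pop, valley_landscape, "full_trans", beta_C=5)
        assert w.member_probs.sum(axis=1) == pytest.approx([1.0, 1.0])
        assert w.member_probs[0] == pytest.approx([1 / 6, 5 / 6])


class TestReproduce:
    def test_monomorphic_population_unchanged(self, valley_landscape):
        cfg = SimulationConfig(landscape=valley_landscape, S=40, m=2, alpha=0.0,
                               alpha_C=0.0, initial_genotype="11")
        pop = init_population(cfg)
        w = compute_selection_weights(pop, valley_landscape, "full_trans", 5)
        nxt = reproduce(pop, w, "random", np.random.default_rng(0))
        assert np.array_equal(nxt.alleles, pop.alleles)
        assert nxt.generation == 1

    def test_kin_groups_descend_from_single_parent_group(self, flat_landscape):
        # give every parental group a distinctive genotype and check each
        # offspring group is uniform in it
        alleles = np.repeat(np.array([[0, 0], [0, 1], [1, 0], [1, 1]],
                                     dtype=np.uint8), 3, axis=0)
        pop = Population(alleles, np.zeros(12, dtype=int), m=3)
        w = compute_selection_weights(pop, flat_landscape, "full_trans", 5)
        nxt = reproduce(pop, w, "kin", np.random.default_rng(1))
        per_group = nxt.alleles.reshape(4, 3, 2)
        for grp in per_group:
            assert (grp == grp[0]).all()

    def test_population_size_conserved(self, valley_landscape):
        cfg = SimulationConfig(landscape=valley_landscape, S=60, m=3,
                               initial_genotype="00", run_seed=2)
        pop = init_population(cfg)
        rng = np.random.default_rng(2)
        for grouping in ("random", "kin"):
            w = compute_selection_weights(pop, valley_landscape, "full_trans", 5)
            pop = reproduce(pop, w, grouping, rng)
            assert pop.S == 60 and pop.G == 20

    def test_neutral_fixation_probability_matches_initial_frequency(self, flat_landscape):
        # Wright-Fisher check: a neutral allele at initial frequency 0.2
        # fixes in ~20% of replicates
        s, reps = 50, 400
        fixed = 0
        rng_master = np.random.default_rng(123)
        for _ in range(reps):
            alleles = np.zeros((s, 2), dtype=np.uint8)
            alleles[:10, 0] = 1
            pop = Population(alleles, np.zeros(s, dtype=int), m=1)
            rng = np.random.default_rng(rng_master.integers(2**31))
            while 0 < pop.alleles[:, 0].sum() < s:
                w = compute_selection_weights(pop, flat_landscape, "none", 1)
                pop = reproduce(pop, w, "random", rng)
            fixed += int(pop.alleles[0, 0] == 1)
        # binomial 99.9% interval around p=0.2 with n=400
        assert abs(fixed / reps - 0.2) < 3.3 * np.sqrt(0.2 * 0.8 / reps)


class TestParasiteConversion:
    def test_zero_rate_is_identity(self):
        pop = _pop([[0, 1]] * 4, [0] * 4, m=2)
        out = apply_parasite_conversion(pop, 0.0, np.random.default_rng(0))
        assert not out.is_parasite.any()

    def test_certain_conversion_uniform_deletion_sizes(self):
        n, s = 5, 10_000
        pop = Population(np.zeros((s, n), dtype=np.uint8),
                         np.zeros(s, dtype=int), m=1)
        apply_parasite_conversion(pop, 1.0, np.random.default_rng(42))
        assert pop.is_parasite.all()
        counts = np.bincount(pop.deletion_count, minlength=n + 1)[1:]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_existing_parasites_never_reconverted(self):
        pop = _pop([[0, 1]] * 6, [2, 0, 1, 0, 0, 0], m=1)
        before = pop.deletion_count.copy()
        apply_parasite_conversion(pop, 1.0, np.random.default_rng(7))
        assert (pop.deletion_count[[0, 2]] == before[[0, 2]]).all()
        assert pop.is_parasite.all()


class TestMutate:
    def test_zero_rate_identity(self):
        pop = _pop([[0, 1], [1, 0]], [0, 0], m=1)
        before = pop.alleles.copy()
        mutate(pop, 0.0, np.random.default_rng(0))
        assert np.array_equal(pop.alleles, before)

    def test_rate_one_complements_helpers(self):
        pop = _pop([[0, 1], [1, 0]], [0, 0], m=1)
        mutate(pop, 1.0, np.random.default_rng(0))
        assert pop.alleles.tolist() == [[1, 0], [0, 1]]

    def test_deleted_positions_untouched(self):
        pop = _pop([[0, 1], [1, 0]], [1, 2], m=1)
        mutate(pop, 1.0, np.random.default_rng(0))
        # first individual: locus 1 deleted (kept), locus 2 flipped
        assert pop.alleles.tolist() == [[0, 0], [1, 0]]

    def test_expected_flip_count(self):
        # S*N*alpha expected flips per application (binomial sampling check)
        s, n, alpha, gens = 10_000, 2, 0.001, 100
        rng = np.random.default_rng(5)
        pop = Population(np.zeros((s, n), dtype=np.uint8), np.zeros(s, dtype=int), m=1)
        flips = 0
        for _ in range(gens):
            before = pop.alleles.copy()
            mutate(pop, alpha, rng)
            flips += int((pop.alleles != before).sum())
        expected = s * n * alpha * gens
        se = np.sqrt(expected * (1 - alpha))
        assert abs(flips - expected) < 3 * se


class TestStepAndRun:
    def test_absorbing_state_at_optimum(self, valley_landscape):
        cfg = SimulationConfig(landscape=valley_landscape, S=20, m=2, alpha=0.0,
                               alpha_C=0.0, initial_genotype="11",
                               parasites_enabled=False)
        pop = init_population(cfg)
        rng = np.random.default_rng(0)
        for _ in range(5):
            pop, rec = step(pop, cfg, rng)
            assert rec.mean_fitness == 1.0
            assert pop.S == 20

    def test_local_peak_without_variation_is_static(self, valley_landscape):
        cfg = SimulationConfig(landscape=valley_landscape, S=20, m=1, rule="none",
                               alpha=0.0, alpha_C=0.0, initial_genotype="00",
                               parasites_enabled=False, max_generations=10)
        result = run(cfg)
        assert not result.reached_threshold
        assert np.allclose(result.trajectory["mean_fitness"], 0.2)

    def test_threshold_at_generation_zero(self, valley_landscape):
        cfg = SimulationConfig(landscape=valley_landscape, S=10, m=1, rule="none",
                               alpha=0.0, initial_genotype="11",
                               parasites_enabled=False)
        result = run(cfg)
        assert result.reached_threshold
        assert result.generations_to_threshold == 0
        assert len(result.records) == 1

    def test_identical_seeds_bitwise_identical_trajectories(self, valley_landscape):
        cfg = SimulationConfig(landscape=valley_landscape, S=200, m=2,
                               initial_genotype="00", run_seed=9,
                               max_generations=50, fitness_threshold=2.0)
        a, b = run(cfg), run(cfg)
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.final_population.alleles, b.final_population.alleles)

    def test_flat_landscape_neutrality(self, flat_landscape):
        cfg = SimulationConfig(landscape=flat_landscape, S=100, m=2,
                               parasites_enabled=False, initial_genotype="00",
                               run_seed=3, max_generations=30, fitness_threshold=2.0)
        result = run(cfg)
        assert (result.trajectory["mean_fitness"] == 1.0).all()

    def test_m1_rules_equivalent(self, valley_landscape):
        # with singleton groups every complementation rule reduces to the
        # basic model's fitness-proportional selection
        base = dict(landscape=valley_landscape, S=300, m=1, initial_genotype="00",
                    run_seed=17, max_generations=60, fitness_threshold=2.0,
                    parasites_enabled=False)
        ref = run(SimulationConfig(rule="none", **base)).trajectory
        for rule in ("full_trans", "average_trans", "full_cis", "average_cis"):
            traj = run(SimulationConfig(rule=rule, **base)).trajectory
            assert traj["mean_fitness"].equals(ref["mean_fitness"])

    def test_conservation_across_regimes(self, valley_landscape):
        for grouping in ("random", "kin"):
            cfg = SimulationConfig(landscape=valley_landscape, S=60, m=2,
                                   grouping=grouping, initial_genotype="00",
                                   run_seed=1, max_generations=20,
                                   fitness_threshold=2.0)
            result = run(cfg)
            assert result.final_population.S == 60
            assert all(len(r.to_row()) > 0 for r in result.records)

    def test_neutral_allele_frequency_random_walk_is_unbiased(self, flat_landscape):
        # over replicates, the mean frequency change of a neutral allele is ~0
        reps, s, gens = 300, 60, 5
        deltas = []
        for r in range(reps):
            alleles = np.zeros((s, 2), dtype=np.uint8)
            alleles[: s // 2, 0] = 1
            pop = Population(alleles, np.zeros(s, dtype=int), m=2)
            rng = np.random.default_rng(1000 + r)
            cfg = SimulationConfig(landscape=flat_landscape, S=s, m=2,
                                   alpha=0.0, parasites_enabled=False,
                                   initial_genotype="00")
            for _ in range(gens):
                pop, _ = step(pop, cfg, rng)
            deltas.append(pop.alleles[:, 0].mean() - 0.5)
        assert abs(np.mean(deltas)) < 3 * np.std(deltas) / np.sqrt(reps)
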