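"""Lattice kernels, backward coalescent and GSM mutation."""

import numpy as np
import pytest

from riverdrift.sim import (
    Genealogy,
    LatticeConfig,
    MutationConfig,
    SampleDesign,
    drop_mutations,
    forward_kernel,
    kernel_matrix,
    simulate_dataset,
    simulate_genealogy,
)


class TestKernel:
    def test_panmixia_is_uniform(self):
        cfg = LatticeConfig(emigration=1.0, geometric_g=1.0, max_distance=160)
        k = forward_kernel(cfg, 80)
        assert np.allclose(k, 1.0 / 160)

    def test_zero_emigration_is_identity(self):
        cfg = LatticeConfig(emigration=0.0)
        mat = kernel_matrix(cfg)
        assert np.allclose(mat, np.eye(160))

    def test_geometric_ratio_at_interior_node(self):
        cfg = LatticeConfig(emigration=0.25, geometric_g=0.9, max_distance=40)
        k = forward_kernel(cfg, 80)
        assert k.sum() == pytest.approx(1.0)
        assert k[81] / k[80] == pytest.approx(0.9)  # P(d=2)/P(d=1) = g
        assert k[77] == pytest.approx(k[81])  # up/downstream symmetry

    def test_rows_sum_to_one_everywhere(self):
        for cfg in (
            LatticeConfig(emigration=0.5, geometric_g=0.95),
            LatticeConfig(emigration=0.15, geometric_g=0.85,
                          barrier_node=125, barrier_age=10, downstream_leak=0.2),
        ):
            for epoch in ("pre-barrier",) + (("barrier",) if cfg.barrier_node else ()):
                mat = kernel_matrix(cfg, epoch)
                assert np.allclose(mat.sum(axis=1), 1.0)

    def test_complete_barrier_blocks_upstream_mass(self):
        cfg = LatticeConfig(emigration=0.25, geometric_g=0.9,
                            barrier_node=125, barrier_age=10)
        k = forward_kernel(cfg, 126, epoch="barrier")
        assert k[:125].sum() == 0.0  # nodes <= 125 unreachable
        k_below = forward_kernel(cfg, 125, epoch="barrier")
        assert k_below[125:].sum() == 0.0

    def test_leak_scales_downstream_crossings(self):
        base = LatticeConfig(emigration=0.25, geometric_g=0.9,
                             barrier_node=125, barrier_age=10, downstream_leak=0.0)
        leaky = LatticeConfig(emigration=0.25, geometric_g=0.9,
                              barrier_node=125, barrier_age=10, downstream_leak=0.2)
        open_k = kernel_matrix(base, "pre-barrier")[126]
        leak_k = kernel_matrix(leaky, "barrier")[126]
        assert np.allclose(leak_k[:125], 0.2 * open_k[:125])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LatticeConfig(emigration=1.5)
        with pytest.raises(ValueError):
            LatticeConfig(max_distance=200)
        with pytest.raises(ValueError):
            SampleDesign(window_nodes=4)


class TestCoalescent:
    def test_single_node_pairwise_time_geometric_mean(self):
        """Two lineages in one closed deme of 10 diploids: E[T2] = 2N = 20."""
        cfg = LatticeConfig(n_nodes=2, density=10, emigration=0.0, max_distance=1)
        design = SampleDesign(nodes=(1,), per_node=1, window_nodes=1)
        times = []
        for s in range(8000):
            tree = simulate_genealogy(cfg, design, seed=s,
                                      start_nodes=np.array([1, 1]))
            times.append(tree.tmrca)
        assert np.mean(times) == pytest.approx(20.0, rel=0.05)

    def test_small_panmictic_lattice_matches_wright_fisher(self):
        """10 nodes x 2 diploids, uniform kernel: E[T2] = 2N = 40."""
        cfg = LatticeConfig(n_nodes=10, density=2, emigration=1.0,
                            geometric_g=1.0, max_distance=10)
        design = SampleDesign(nodes=(5,), per_node=1, window_nodes=1)
        times = []
        for s in range(8000):
            tree = simulate_genealogy(cfg, design, seed=s,
                                      start_nodes=np.array([3, 8]))
            times.append(tree.tmrca)
        assert np.mean(times) == pytest.approx(40.0, rel=0.05)

    def test_no_cross_barrier_coalescence_during_barrier(self):
        cfg = LatticeConfig(n_nodes=20, density=3, emigration=0.5, geometric_g=0.9,
                            max_distance=5, barrier_node=10, barrier_age=5000)
        design = SampleDesign(nodes=(10,), per_node=1, window_nodes=1)
        for s in range(20):
            tree = simulate_genealogy(cfg, design, seed=s,
                                      start_nodes=np.array([5, 15]))
            assert tree.tmrca > 5000

    def test_tree_structure_invariants(self):
        cfg = LatticeConfig(density=3, emigration=0.5, geometric_g=0.95)
        design = SampleDesign()
        tree = simulate_genealogy(cfg, design, seed=1)
        n = tree.n_leaves
        assert n == 2 * design.n_individuals
        assert np.all(tree.time[:n] == 0.0)  # ultrametric leaves
        bl = tree.branch_lengths()
        assert np.all(bl > 0)  # merges strictly increase time
        assert tree.parent[tree.root] == -1
        # every non-root node's parent was created later (higher id)
        assert np.all(tree.parent[:-1] > np.arange(len(tree.parent) - 1))

    def test_generation_cap_raises(self):
        cfg = LatticeConfig(n_nodes=2, density=500, emigration=0.0, max_distance=1)
        design = SampleDesign(nodes=(1,), per_node=1, window_nodes=1)
        with pytest.raises(RuntimeError, match="common ancestor"):
            simulate_genealogy(cfg, design, seed=0, max_generations=5,
                               start_nodes=np.array([1, 1]))


def _two_leaf_tree(length: float) -> Genealogy:
    parent = np.array([2, 2, -1])
    time = np.array([0.0, 0.0, length])
    nodes = np.array([1, 1, 1])
    return Genealogy(parent, time, nodes, 2, np.array([1, 1]))


class TestMutation:
    def test_zero_rate_keeps_root_state(self):
        tree = _two_leaf_tree(1000.0)
        mut = MutationConfig(mu=0.0)
        states = drop_mutations(tree, mut, seed=0)
        assert np.all(states == mut.root_state)

    def test_poisson_mutation_rate_via_smm_displacement(self):
        """Branch of 5e4 generations at mu = 3e-4 carries ~Poisson(15)
        mutations; under SMM each is a +/-1 step, so the leaf displacement
        has E[disp^2] equal to the mutation count on its root path."""
        tree = _two_leaf_tree(50_000.0)  # two independent branches of 5e4
        mut = MutationConfig(mu=3e-4, step_variance=0.0, n_states=100_000,
                             root_state=50_000)
        sq = []
        for s in range(200):
            states = drop_mutations(tree, mut, seed=s)
            sq.extend(((states - 50_000.0) ** 2).tolist())
        mean_sq = np.mean(sq)
        se = np.std(sq) / np.sqrt(len(sq))
        assert abs(mean_sq - 15.0) < 3 * se + 0.5

    def test_smm_limit_steps_of_one(self):
        tree = _two_leaf_tree(2000.0)
        mut = MutationConfig(mu=5e-3, step_variance=0.0, n_states=1000, root_state=500)
        assert mut.p_gsm == 0.0
        states = drop_mutations(tree, mut, seed=3)
        assert np.all(states >= 1)

    def test_states_stay_in_range(self):
        tree = _two_leaf_tree(10_000.0)
        mut = MutationConfig(mu=5e-3, n_states=60, root_state=30)
        for s in range(20):
            states = drop_mutations(tree, mut, seed=s)
            assert np.all((1 <= states) & (states <= 60))

    def test_gsm_parameter_solves_variance(self):
        mut = MutationConfig()
        p = mut.p_gsm
        assert p / (1 - p) ** 2 == pytest.approx(0.36)
        assert p == pytest.approx(0.2195, abs=0.001)


class TestDataset:
    def test_shapes_sides_and_determinism(self):
        from riverdrift.experiment import scenario_lattice

        cfg = scenario_lattice("ibd", 3, barrier_age=10)
        m1 = simulate_dataset(cfg, SampleDesign(), MutationConfig(), 8, seed=42)
        m2 = simulate_dataset(cfg, SampleDesign(), MutationConfig(), 8, seed=42)
        assert np.array_equal(m1.genotypes, m2.genotypes)  # byte-identical
        assert m1.n_individuals == 135 and m1.n_loci == 8
        sides = m1.individuals.groupby("side").size()
        assert sides["above"] == 45 and sides["below"] == 90
        pos = m1.individuals["position_m"]
        assert pos.min() == pytest.approx((70 - 1) * 200.0)

    def test_simulated_he_in_observed_range(self):
        from riverdrift.experiment import scenario_lattice
        from riverdrift.genotypes import AlleleMatrix
        from riverdrift.stats.diversity import heterozygosity

        cfg = scenario_lattice("ibd", 10)
        hes = []
        for s in range(3):
            m = simulate_dataset(cfg, SampleDesign(), MutationConfig(), 8, seed=s)
            meta = m.individuals.copy()
            meta["pool"] = "all"
            _, _, he = heterozygosity(AlleleMatrix(meta, m.genotypes), "all")
            hes.append(he)
        assert 0.3 <= np.mean(hes) <= 0.7

    def test_loci_are_independent(self):
        """Genotype states at different loci are uncorrelated across replicates."""
        from riverdrift.experiment import scenario_lattice

        cfg = scenario_lattice("ibd", 3)
        design = SampleDesign(nodes=(80,), per_node=6, window_nodes=5)
        sums = []
        for s in range(60):
            m = simulate_dataset(cfg, design, MutationConfig(), 2, seed=s)
            sums.append(m.genotypes.sum(axis=(0, 2)))  # per-locus totals
        sums = np.array(sums, dtype=float)
        r = np.corrcoef(sums[:, 0], sums[:, 1])[0, 1]
        assert abs(r) < 0.35  # ~N(0, 1/sqrt(60)) under independence
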