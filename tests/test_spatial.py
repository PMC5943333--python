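"""Ritland kinship, autocorrelogram and IBD regression."""

import numpy as np
import pandas as pd
import pytest

from riverdrift.genotypes import AlleleMatrix, FixtureConfig, PoolFixture, make_empirical_fixture, simple_metadata
from riverdrift.stats.spatial import autocorrelogram, ibd_regression, ritland_kinship

from conftest import matrix_from_pools


def _with_positions(matrix: AlleleMatrix, positions) -> AlleleMatrix:
    meta = matrix.individuals.copy()
    meta["position_m"] = np.asarray(positions, dtype=float)
    return AlleleMatrix(meta, matrix.genotypes, list(matrix.locus_names))


class TestRitlandKinship:
    def test_identical_homozygotes_at_even_biallelic_locus(self):
        # reference p = 0.5 for both alleles; identical (1,1) pairs: F = 1
        m = matrix_from_pools({"p": [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]]})
        kin = ritland_kinship(m)
        assert kin[0, 1] == pytest.approx(1.0)
        assert kin[2, 3] == pytest.approx(1.0)
        assert kin[0, 2] == pytest.approx(-1.0)  # opposite homozygotes

    def test_mean_kinship_near_zero_with_whole_sample_reference(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, {"p": 40}, n_loci=6, max_allele=5)
        kin = ritland_kinship(m)
        vals = kin[np.triu_indices(40, 1)]
        assert abs(np.nanmean(vals)) < 0.05  # estimator centred on the sample

    def test_duplicated_individual_scores_highest(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, {"p": 20}, n_loci=8, max_allele=6)
        genos = np.concatenate([m.genotypes, m.genotypes[:1]], axis=0)
        meta = simple_metadata(21)
        dup = AlleleMatrix(meta, genos)
        kin = ritland_kinship(dup)
        assert kin[0, 20] > np.nanmean(kin)


class TestAutocorrelogram:
    def test_single_class_mean_equals_global_mean(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, {"p": 15}, n_loci=4)
        kin = ritland_kinship(m)
        pos = np.linspace(0, 900, 15)  # all pairs inside one 2000-m class
        ac = autocorrelogram(kin, pos, class_width=2000, permutations=50, seed=0)
        global_mean = np.nanmean(kin[np.triu_indices(15, 1)])
        assert ac.mean_kinship[1] == pytest.approx(global_mean)

    def test_pair_counts_and_weighted_mean_invariant(self, rng):
        from conftest import random_matrix

        n = 24
        m = random_matrix(rng, {"p": n}, n_loci=5)
        kin = ritland_kinship(m)
        pos = np.repeat(np.arange(6) * 1500.0, 4)
        ac = autocorrelogram(kin, pos, class_width=2000, permutations=50, seed=0)
        assert ac.pair_counts.sum() == n * (n - 1) // 2
        weighted = np.nansum(ac.mean_kinship * ac.pair_counts) / ac.pair_counts.sum()
        assert weighted == pytest.approx(np.nanmean(kin[np.triu_indices(n, 1)]))

    def test_null_flag_rate_near_five_percent(self, rng):
        flagged = total = 0
        for _ in range(40):
            cfg = FixtureConfig(
                [PoolFixture("p", 30, [0.5] * 4, [4] * 4)], seed=int(rng.integers(2**31))
            )
            m = make_empirical_fixture(cfg)
            kin = ritland_kinship(m)
            pos = np.repeat(np.arange(5) * 2000.0, 6)
            ac = autocorrelogram(kin, pos, class_width=2000, permutations=199,
                                 seed=int(rng.integers(2**31)))
            with_pairs = ac.pair_counts > 0
            flagged += int(ac.significant[with_pairs].sum())
            total += int(with_pairs.sum())
        rate = flagged / total
        assert rate < 0.15  # ~5% expected; binomial slack on ~160 classes


class TestIbdRegression:
    def _sim_matrix(self, seed):
        import riverdrift as rd
        from riverdrift.experiment import scenario_lattice

        cfg = scenario_lattice("ibd", 10)
        return rd.simulate_dataset(cfg, rd.SampleDesign(), rd.MutationConfig(), 8, seed)

    def test_equal_distances_error(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, {"s1": 5, "s2": 5, "s3": 5})
        meta = m.individuals.copy()
        meta["site"] = meta["pool"]
        meta["position_m"] = 0.0
        m = AlleleMatrix(meta, m.genotypes)
        with pytest.raises(ValueError, match="distances"):
            ibd_regression(m, permutations=10, seed=0)

    def test_null_mantel_calibrated(self, rng):
        hits = 0
        n_datasets = 100
        for _ in range(n_datasets):
            cfg = FixtureConfig(
                [
                    PoolFixture("s%d" % i, 10, [0.5] * 4, [4] * 4, site=f"s{i}",
                                position_m=2000.0 * i)
                    for i in range(6)
                ],
                seed=int(rng.integers(2**31)),
            )
            m = make_empirical_fixture(cfg)
            fit = ibd_regression(m, permutations=199, seed=int(rng.integers(2**31)))
            if fit.mantel_p < 0.05:
                hits += 1
        assert hits <= 13  # Binomial(100, 0.05) upper 99.9% bound

    def test_mantel_p_reproducible_under_seed(self):
        m = self._sim_matrix(3)
        p1 = ibd_regression(m, permutations=2000, seed=7).mantel_p
        p2 = ibd_regression(m, permutations=2000, seed=7).mantel_p
        assert p1 == p2

    def test_ibd_simulation_gives_positive_slopes(self):
        slopes = [ibd_regression(self._sim_matrix(s), permutations=20, seed=s).slope
                  for s in range(8)]
        assert np.mean(np.asarray(slopes) > 0) >= 0.75

    def test_slope_order_of_magnitude_matches_rousset(self):
        """Mean slope within a factor of 3 of 1/(4 D sigma^2) per metre."""
        import riverdrift as rd
        from riverdrift.experiment import scenario_lattice
        from riverdrift.sim import kernel_matrix

        cfg = scenario_lattice("ibd", 10)
        kern = kernel_matrix(cfg)[80]  # interior node
        d_nodes = np.arange(cfg.n_nodes) - 80
        sigma2 = float((kern * (d_nodes * cfg.spacing_m) ** 2).sum())
        dens_per_m = cfg.density / cfg.spacing_m
        predicted = 1.0 / (4 * dens_per_m * sigma2)
        slopes = [
            ibd_regression(self._sim_matrix(100 + s), permutations=20, seed=s).slope
            for s in range(10)
        ]
        mean_slope = np.mean(slopes)
        assert predicted / 3 < mean_slope < predicted * 3


class TestKinshipUnderIbd:
    def test_colocated_pairs_most_related(self):
        """Simulated limited dispersal: class-0 kinship exceeds the global mean."""
        import riverdrift as rd
        from riverdrift.experiment import scenario_lattice

        cfg = scenario_lattice("ibd", 10)
        wins = 0
        n_reps = 12
        for s in range(n_reps):
            m = rd.simulate_dataset(cfg, rd.SampleDesign(), rd.MutationConfig(), 8, 500 + s)
            kin = ritland_kinship(m)
            pos = m.individuals["position_m"].to_numpy()
            ac = autocorrelogram(kin, pos, class_width=2000, permutations=30, seed=s)
            global_mean = np.nanmean(kin[np.triu_indices(m.n_individuals, 1)])
            if ac.mean_kinship[0] > global_mean:
                wins += 1
        assert wins >= 0.8 * n_reps
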