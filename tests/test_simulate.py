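import numpy as np
import pytest

from sgllmm.kinship import KinshipEigen, compute_rrm, eigendecompose, standardize_genotypes
from sgllmm.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_grid,
    simulate_phenotype,
    simulate_population_effect,
)


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_samples=40, n_groups=5, seed=9)
        g1, _ = simulate_genotypes(cfg)
        g2, _ = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_no_structure_limit(self):
        # fst = 0, no LD: between-population allele-frequency differences are
        # pure sampling noise
        cfg = SimulationConfig(
            n_samples=1130, n_groups=500, snps_per_group=10, fst=0.0, ld_rho=0.0, seed=5
        )
        g, _ = simulate_genotypes(cfg)
        half = cfg.n_samples // 2
        f1 = g.dosages[:half].mean(axis=0) / 2
        f2 = g.dosages[half:].mean(axis=0) / 2
        assert np.mean(np.abs(f1 - f2)) < 0.02

    def test_binomial_moments_without_ld(self):
        # with one panmictic population and independent haplotypes,
        # Var(dosage) = 2 p (1 - p)
        cfg = SimulationConfig(n_samples=1130, n_groups=100, ld_rho=0.0, fst=0.0, seed=6)
        g, _ = simulate_genotypes(cfg)
        p_hat = g.dosages.mean(axis=0) / 2
        var_expected = 2 * p_hat * (1 - p_hat)
        var_obs = g.dosages.var(axis=0)
        assert np.mean(np.abs(var_obs - var_expected)) < 0.02

    def test_ld_induces_neighbor_correlation(self):
        cfg = SimulationConfig(n_samples=400, n_groups=30, ld_rho=0.7, seed=8)
        g, groups = simulate_genotypes(cfg)
        corrs = []
        for gi in range(10):
            idx = groups.members[gi]
            c = np.corrcoef(g.dosages[:, idx].T)
            corrs.append(np.mean(np.diag(c, k=1)))
        assert np.mean(corrs) > 0.3  # adjacent SNPs in a gene are correlated

    def test_groups_are_contiguous_blocks(self):
        cfg = SimulationConfig(
            n_samples=20, n_groups=4, snps_per_group=3, causal_per_active=2, seed=1
        )
        _, groups = simulate_genotypes(cfg)
        np.testing.assert_array_equal(groups.assignments, np.repeat(np.arange(4), 3))

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            SimulationConfig(fst=1.0)


class TestSimulatePopulationEffect:
    def test_identity_kinship_gives_standardized_normal(self):
        ke = KinshipEigen(K=np.eye(50), U=np.eye(50), S=np.ones(50))
        y = simulate_population_effect(ke, seed=3)
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std(ddof=1) == pytest.approx(1.0)

    def test_deterministic(self):
        ke = KinshipEigen(K=np.eye(10), U=np.eye(10), S=np.ones(10))
        np.testing.assert_array_equal(
            simulate_population_effect(ke, seed=4), simulate_population_effect(ke, seed=4)
        )

    def test_covariance_tracks_kinship(self, rng):
        # across replicate draws the empirical covariance approximates K
        # (per-draw standardization only rescales mildly at this dimension)
        Z, _ = standardize_genotypes(rng.choice([0.0, 1.0, 2.0], size=(200, 300)))
        ke = eigendecompose(compute_rrm(Z))
        draws = np.stack([simulate_population_effect(ke, seed=s) for s in range(500)])
        emp = draws.T @ draws / 500
        assert np.mean(np.abs(emp - ke.K)) < 0.2
        # structure, not just scale: correlation between matrices is high
        c = np.corrcoef(emp.ravel(), ke.K.ravel())[0, 1]
        assert c > 0.8


class TestSimulatePhenotype:
    cfg = SimulationConfig(n_samples=80, n_groups=10, seed=2)

    def make(self, **overrides):
        from dataclasses import replace

        cfg = replace(self.cfg, **overrides)
        g, groups = simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        y_pop = rng.standard_normal(cfg.n_samples)
        return cfg, g, groups, y_pop

    def test_defaults_place_15_causal_in_3_groups(self):
        cfg, g, groups, y_pop = self.make()
        ds = simulate_phenotype(cfg, g, groups, y_pop, seed=7)
        assert ds.causal_mask.sum() == 15
        causal_groups = np.unique(groups.assignments[ds.causal_mask])
        assert len(causal_groups) == 3
        np.testing.assert_array_equal(causal_groups, ds.active_groups)

    def test_sigma_sig_one_is_pure_signal(self):
        cfg, g, groups, y_pop = self.make(sigma_sig=1.0)
        ds = simulate_phenotype(cfg, g, groups, y_pop, seed=7)
        np.testing.assert_allclose(ds.phenotype.values, ds.y_sig)

    def test_all_noise_boundary(self):
        cfg, g, groups, y_pop = self.make(sigma_sig=0.0, sigma_pop=0.0)
        ds = simulate_phenotype(cfg, g, groups, y_pop, seed=7)
        np.testing.assert_allclose(ds.phenotype.values, ds.phi)
        assert ds.phi.std(ddof=1) == pytest.approx(1.0)

    def test_variance_bookkeeping_of_mixer(self):
        # Var(y) ~ s^2 + (1-s)^2 [p^2 + (1-p)^2] for standardized components
        cfg = SimulationConfig(n_samples=2000, n_groups=50, sigma_sig=0.4,
                               sigma_pop=0.7, seed=13)
        ds = simulate_dataset(cfg)
        s, p = 0.4, 0.7
        expected = s**2 + (1 - s) ** 2 * (p**2 + (1 - p) ** 2)
        assert ds.phenotype.values.var(ddof=1) == pytest.approx(expected, rel=0.1)

    def test_raw_components_mode_skips_standardization(self):
        cfg, g, groups, y_pop = self.make(sigma_sig=1.0, raw_components=True)
        ds = simulate_phenotype(cfg, g, groups, y_pop, seed=7)
        X = g.dosages[:, ds.causal_mask]
        np.testing.assert_allclose(ds.phenotype.values, X @ ds.beta_true[ds.causal_mask])

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            SimulationConfig(snps_per_group=3, causal_per_active=5)


class TestSimulateGrid:
    base = SimulationConfig(n_samples=50, n_groups=6, seed=77)

    def test_full_grid_counts_and_manifests(self):
        datasets = list(simulate_grid(self.base, [0.2, 0.5], [0.5, 0.9], reps=2))
        assert len(datasets) == 2 * 2 * 2
        manifests = [(d.manifest["sigma_sig"], d.manifest["sigma_pop"], d.manifest["rep"])
                     for d in datasets]
        assert len(set(manifests)) == 8

    def test_explicit_combination_subset(self):
        combos = [(0.2, 0.5), (0.5, 0.9), (0.3, 0.7)]
        datasets = list(simulate_grid(self.base, reps=2, combinations=combos))
        assert len(datasets) == 6

    def test_rerun_reproduces_phenotypes(self):
        d1 = list(simulate_grid(self.base, [0.3], [0.7], reps=2))
        d2 = list(simulate_grid(self.base, [0.3], [0.7], reps=2))
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.phenotype.values, b.phenotype.values)
            assert a.config.seed == b.config.seed

    def test_distinct_cells_get_distinct_seeds(self):
        datasets = list(simulate_grid(self.base, [0.1, 0.2, 0.3], [0.5], reps=3))
        seeds = {d.config.seed for d in datasets}
        assert len(seeds) == 9


def test_causal_mask_confined_to_active_groups():
    for seed in range(5):
        cfg = SimulationConfig(n_samples=30, n_groups=8, seed=seed)
        ds = simulate_dataset(cfg)
        groups_of_causal = set(ds.groups.assignments[ds.causal_mask])
        assert groups_of_causal <= set(ds.active_groups.tolist())
        assert ds.causal_mask.sum() == cfg.k_causal
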