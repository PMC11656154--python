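"""Latent-Gaussian genotypes, phenotypes, exact regressions, resampling."""

import numpy as np
import pytest
from scipy import stats

import sumstatsim as ss
from sumstatsim.individual import (
    build_membership,
    indicator_correlation_from_latent,
    regression_sumstats,
    resample_inddata,
    resample_sumstats,
    simulate_genotypes,
    simulate_phenotypes,
    solve_latent_correlation,
)
from sumstatsim.ld import make_ld_pattern, tile_pattern
from sumstatsim.sampling import SampleDesign, build_sample_design


class TestLatentCorrelation:
    def test_zero_maps_to_zero(self):
        assert solve_latent_correlation(0.3, 0.6, 0.0) == 0.0

    def test_median_threshold_closed_form(self):
        # at f1 = f2 = 0.5 the indicator correlation is 2 arcsin(rho)/pi,
        # so target 0.5 inverts to sin(pi/4)
        got = solve_latent_correlation(0.5, 0.5, 0.5)
        assert got == pytest.approx(np.sin(np.pi * 0.5 / 2), abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_forward_verified_by_orthant_probability(self, seed):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.uniform(0.15, 0.85, size=2)
        lo = -0.5 * np.sqrt(min(f1 * f2 / ((1 - f1) * (1 - f2)),
                                (1 - f1) * (1 - f2) / (f1 * f2)))
        hi = 0.5 * np.sqrt(min(f1 * (1 - f2) / (f2 * (1 - f1)),
                               f2 * (1 - f1) / (f1 * (1 - f2))))
        target = rng.uniform(lo, hi)
        latent = solve_latent_correlation(f1, f2, target)
        h1, h2 = stats.norm.ppf([f1, f2])
        p11 = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, latent], [latent, 1]]
        ).cdf([h1, h2])
        back = (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
        assert back == pytest.approx(target, abs=1e-5)

    def test_infeasible_target_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="infeasible"):
            solve_latent_correlation(0.1, 0.9, 0.95)

    def test_forward_map_round_trip(self):
        af = np.array([0.3, 0.5, 0.7])
        latent = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        R = indicator_correlation_from_latent(latent, af)
        for i in range(3):
            for j in range(i + 1, 3):
                assert solve_latent_correlation(af[i], af[j], R[i, j]) == pytest.approx(
                    latent[i, j], abs=1e-5
                )


class TestGenotypes:
    def test_values_in_dosage_range(self, feasible_block_layout):
        G = simulate_genotypes(feasible_block_layout, 200, np.random.default_rng(0))
        assert set(np.unique(G)).issubset({0, 1, 2})

    def test_hardy_weinberg_marginals(self):
        layout = tile_pattern(make_ld_pattern("identity", np.full(1, 0.5)), 4)
        G = simulate_genotypes(layout, 20_000, np.random.default_rng(1))
        for j in range(4):
            counts = np.bincount(G[:, j], minlength=3) / 20_000
            for g, want in enumerate([0.25, 0.5, 0.25]):
                se = np.sqrt(want * (1 - want) / 20_000)
                assert abs(counts[g] - want) < 3 * se

    def test_target_ld_recovered(self, feasible_block_layout):
        G = simulate_genotypes(feasible_block_layout, 20_000, np.random.default_rng(2))
        emp = np.corrcoef(G, rowvar=False)
        want = feasible_block_layout.materialize()
        off = ~np.eye(6, dtype=bool)
        assert np.abs(emp - want)[off].max() < 0.02

    def test_tiles_independent(self):
        pat = make_ld_pattern(("ar1", 3, 0.8), np.full(3, 0.5))
        layout = tile_pattern(pat, 6)
        G = simulate_genotypes(layout, 20_000, np.random.default_rng(3))
        emp = np.corrcoef(G, rowvar=False)
        assert np.abs(emp[:3, 3:]).max() < 0.03


class TestPhenotypes:
    def test_pure_environment_unit_variance(self):
        layout = tile_pattern(make_ld_pattern("identity", np.full(1, 0.5)), 2)
        G = simulate_genotypes(layout, 50_000, np.random.default_rng(4))
        Y = simulate_phenotypes(
            G, layout, np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2),
            np.random.default_rng(5),
        )
        se = np.sqrt(2 / 50_000)  # var of a variance estimate
        assert np.all(np.abs(Y.var(axis=0, ddof=1) - 1.0) < 3 * se)

    def test_sem_coefficients_recovered_by_regression(self, three_trait_dag):
        # disjoint causal sets: shared causal variants would correlate the
        # traits' direct genetic components and bias the trait-on-trait
        # regression away from the structural coefficients
        J = 99
        pi = np.zeros((J, 3))
        for k in range(3):
            pi[k * 33 : (k + 1) * 33, k] = 1.0
        sim = ss.simulate(three_trait_dag, [0.3, 0.3, 0.3], 1000, J, pi, seed=6)
        data = resample_inddata(
            sim, design=build_sample_design(100_000.0, 3), seed=7
        )
        Y = data.phenotypes
        X = np.column_stack([Y[:, 0], Y[:, 1], np.ones(len(Y))])
        coef, *_ = np.linalg.lstsq(X, Y[:, 2], rcond=None)
        resid = Y[:, 2] - X @ coef
        cov = np.linalg.inv(X.T @ X) * resid.var(ddof=3)
        se = np.sqrt(np.diag(cov))[:2]
        assert abs(coef[0] - (-0.2)) < 3 * se[0]
        assert abs(coef[1] - 0.1) < 3 * se[1]

    def test_realized_heritability_at_large_n(self):
        sim = ss.simulate(np.zeros((1, 1)), [0.4], 1000, 50, 1.0, seed=8)
        data = resample_inddata(sim, design=build_sample_design(50_000.0, 1), seed=9)
        from sumstatsim.individual import standardize_genotypes

        gen = standardize_genotypes(data.genotypes, sim.layout) @ sim.effects.gamma_std
        h2_emp = gen.var(axis=0)[0] / data.phenotypes.var(axis=0)[0]
        h2_model = sim.effects.realized_h2[0] / (1 - 0.4 + sim.effects.realized_h2[0])
        assert h2_emp == pytest.approx(h2_model, rel=0.10)


class TestMembership:
    def test_two_trait_overlap_counts(self):
        design = SampleDesign(np.array([[8000, 2000], [2000, 10_000]]))
        n_union, members = build_membership(design)
        assert n_union == 16_000
        assert len(members[0]) == 8000 and len(members[1]) == 10_000
        assert len(np.intersect1d(members[0], members[1])) == 2000

    def test_three_trait_pairwise_counts(self):
        n = np.array([[100, 20, 30], [20, 200, 40], [30, 40, 300]])
        design = SampleDesign(n)
        _, members = build_membership(design)
        for a in range(3):
            assert len(members[a]) == n[a, a]
            for b in range(a + 1, 3):
                assert len(np.intersect1d(members[a], members[b])) == n[a, b]

    def test_infeasible_overlap_rejected(self):
        n = np.array([[10, 8, 8], [8, 100, 0], [8, 0, 100]])
        with pytest.raises(ValueError, match="overlap"):
            build_membership(SampleDesign(n))


class TestRegressionSumstats:
    def test_hand_computed_slope_and_se(self):
        g = np.array([[0], [1], [2], [1]])
        y = np.array([[0.1], [0.2], [0.5], [0.2]])
        beta, se = regression_sumstats(g, y, [np.arange(4)])
        assert beta[0, 0] == pytest.approx(0.2)
        assert se[0, 0] == pytest.approx(0.05)

    def test_matches_generic_least_squares(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = rng.integers(10, 40)
            g = rng.integers(0, 3, size=(n, 3)).astype(float)
            y = rng.normal(size=(n, 1))
            beta, se = regression_sumstats(g, y, [np.arange(n)])
            for j in range(3):
                if np.ptp(g[:, j]) == 0:
                    continue
                fit = stats.linregress(g[:, j], y[:, 0])
                assert beta[j, 0] == pytest.approx(fit.slope, abs=1e-10)
                assert se[j, 0] == pytest.approx(fit.stderr, abs=1e-10)

    def test_monomorphic_variant_reported_missing(self):
        g = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 1.0]])
        y = np.random.default_rng(11).normal(size=(4, 1))
        with pytest.warns(UserWarning, match="monomorphic"):
            beta, se = regression_sumstats(g, y, [np.arange(4)])
        assert np.isnan(beta[0, 0]) and not np.isnan(beta[1, 0])


class TestResampling:
    def test_same_effects_fresh_noise(self):
        sim = ss.simulate(np.zeros((1, 1)), [0.3], 5000, 20, 0.5, seed=12)
        a = resample_sumstats(sim, seed=1)
        b = resample_sumstats(sim, seed=2)
        assert not np.array_equal(a.beta_hat, b.beta_hat)
        np.testing.assert_array_equal(a.se_true, b.se_true)

    def test_doubling_n_scales_true_se(self):
        sim = ss.simulate(np.zeros((1, 1)), [0.3], 5000, 20, 0.5, seed=13)
        doubled = resample_sumstats(
            sim, design=build_sample_design(10_000.0, 1), seed=3
        )
        np.testing.assert_allclose(
            doubled.se_true, sim.sumstats.se_true / np.sqrt(2), atol=1e-15
        )

    def test_new_layout_recomputes_marginals(self):
        sim = ss.simulate(np.zeros((1, 1)), [0.3], 5000, 4, 1.0, seed=14)
        block = np.array(
            [
                [1.0, 0.4, 0.1, 0.0],
                [0.4, 1.0, 0.4, 0.1],
                [0.1, 0.4, 1.0, 0.4],
                [0.0, 0.1, 0.4, 1.0],
            ]
        )
        new_layout = tile_pattern(make_ld_pattern([block], np.full(4, 0.4)), 4)
        reps = np.array(
            [
                resample_sumstats(sim, new_layout=new_layout, seed=s).beta_hat[:, 0]
                for s in range(3000)
            ]
        )
        want = (block @ sim.effects.beta_joint_std[:, 0]) / np.sqrt(
            new_layout.variant_var
        )
        se = reps.std(axis=0, ddof=1) / np.sqrt(3000)
        assert np.all(np.abs(reps.mean(axis=0) - want) < 3 * se)

    def test_mode_genotypes_only_then_phenotypes_only(self):
        sim = ss.simulate(np.zeros((2, 2)), [0.3, 0.2], 500, 10, 0.5, seed=15)
        geno = resample_inddata(sim, genotypes_only=True, n_samples=600, seed=16)
        assert geno.genotypes.shape == (600, 10) and geno.phenotypes is None
        both = resample_inddata(
            sim, phenotypes_only=True, genotypes=geno.genotypes, seed=17
        )
        assert both.phenotypes.shape == (600, 2)
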