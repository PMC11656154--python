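"""Causal selection, scale-family effect distributions, propagation."""

import numpy as np
import pandas as pd
import pytest

from sumstatsim.effects import (
    EmptyCausalSetError,
    apply_h2_exact,
    compute_joint_effects,
    compute_marginal_effects,
    fixed_effects,
    make_effect_distribution,
    mixture_normal,
    point_normal,
    sample_direct_effects,
    select_causal,
    simulate_effects,
)
from sumstatsim.ld import make_ld_pattern, tile_pattern
from sumstatsim.sem import total_effects


def identity_layout(J, f=0.5):
    return tile_pattern(make_ld_pattern("identity", np.array([f])), J)


class TestSelectCausal:
    def test_zero_probability_selects_nothing(self):
        rng = np.random.default_rng(0)
        assert not select_causal(0.0, 50, 2, rng).any()

    def test_deterministic_half_genome(self):
        J = 100
        pi = np.zeros((J, 1))
        pi[: J // 2] = 1.0
        ind = select_causal(pi, J, 1, np.random.default_rng(0))
        assert ind[: J // 2, 0].all() and not ind[J // 2 :, 0].any()

    def test_causal_count_binomial(self):
        # 200 independent draws of Binomial(10000, 0.1)
        counts = [
            select_causal(0.1, 10_000, 1, np.random.default_rng(s)).sum()
            for s in range(200)
        ]
        se = np.sqrt(10_000 * 0.1 * 0.9 / 200)
        assert abs(np.mean(counts) - 1000) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            select_causal(1.5, 10, 1, np.random.default_rng(0))


class TestDistributions:
    def test_single_component_mixture_equals_point_normal_moments(self):
        rng = np.random.default_rng(1)
        mix = mixture_normal([1.0], [1.0])
        n, target = 10, 0.8
        draws = np.array(
            [mix(n, target, None, rng) for _ in range(10_000)]
        )
        ss = (draws**2).sum(axis=1)
        assert abs(ss.mean() - target) < 3 * ss.std(ddof=1) / 100

    def test_fixed_values_rescaled_exactly(self):
        handle = fixed_effects([1.0, 2.0, 2.0])
        out = handle(3, 0.9, None, np.random.default_rng(0))
        np.testing.assert_allclose(out, np.sqrt(0.1) * np.array([1.0, 2.0, 2.0]))
        assert (out**2).sum() == pytest.approx(0.9)

    def test_two_component_variance_ratio(self):
        # second component has 10x the variance of the first
        rng = np.random.default_rng(2)
        mix = mixture_normal([0.9, 0.1], [1.0, 10.0])
        draws = np.concatenate([mix(100, 1.0, None, rng) for _ in range(500)])
        a2 = np.sort(draws**2)
        # top decile of squared draws dominated by component 2
        ratio = a2[-len(a2) // 10 :].mean() / a2[: -len(a2) // 10].mean()
        assert ratio > 5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            mixture_normal([0.5, 0.6], [1.0, 1.0])
        with pytest.raises(ValueError):
            fixed_effects([0.0, 0.0])
        with pytest.raises(ValueError):
            make_effect_distribution("no_such_family")


class TestSampleDirectEffects:
    def test_single_causal_variant_moment(self):
        layout = identity_layout(1)
        ind = np.ones((1, 1), dtype=bool)
        sq = [
            sample_direct_effects(
                ind, [0.4], point_normal(), layout, np.random.default_rng(s)
            )[0, 0]
            ** 2
            for s in range(20_000)
        ]
        # E[gamma^2] = 0.4; var of chi2_1 scaled
        assert abs(np.mean(sq) - 0.4) < 3 * np.std(sq, ddof=1) / np.sqrt(20_000)

    def test_zero_variance_trait_all_zero(self):
        layout = identity_layout(20)
        ind = select_causal(0.5, 20, 2, np.random.default_rng(0))
        gamma = sample_direct_effects(
            ind, [0.0, 0.3], point_normal(), layout, np.random.default_rng(1)
        )
        assert not gamma[:, 0].any()
        assert gamma[ind[:, 1], 1].all()

    def test_empty_causal_set_with_positive_variance_errors(self):
        layout = identity_layout(5)
        ind = np.zeros((5, 1), dtype=bool)
        with pytest.raises(EmptyCausalSetError):
            sample_direct_effects(
                ind, [0.3], point_normal(), layout, np.random.default_rng(0)
            )

    def test_annotation_weighted_custom_handle(self):
        # LDAK-style: E[h_j^2] proportional to (f(1-f))^0.75 (a0 + a1 A1 + a2 A2)
        J = 40
        rng0 = np.random.default_rng(7)
        af = rng0.uniform(0.1, 0.9, size=J)
        layout = tile_pattern(make_ld_pattern("identity", af), J)
        snp_info = pd.DataFrame(
            {"A1": rng0.binomial(1, 0.5, J), "A2": rng0.binomial(1, 0.3, J)}
        )
        alpha = (0.9, 0.1, 0.13)

        def ldak_handle(n, total_variance, variant_info, rng):
            f = variant_info["AF"].to_numpy()
            w = (f * (1 - f)) ** 0.75 * (
                alpha[0]
                + alpha[1] * variant_info["A1"].to_numpy()
                + alpha[2] * variant_info["A2"].to_numpy()
            )
            per_var = total_variance * w / w.sum()
            return rng.normal(0.0, np.sqrt(per_var))

        ind = np.ones((J, 1), dtype=bool)
        reps = np.array(
            [
                sample_direct_effects(
                    ind, [0.5], ldak_handle, layout,
                    np.random.default_rng(s), snp_info=snp_info,
                )[:, 0]
                for s in range(4000)
            ]
        )
        mean_sq = (reps**2).mean(axis=0)
        f = af
        w = (f * (1 - f)) ** 0.75 * (
            alpha[0] + alpha[1] * snp_info["A1"] + alpha[2] * snp_info["A2"]
        ).to_numpy()
        expected = 0.5 * w / w.sum()
        se = (reps**2).std(axis=0, ddof=1) / np.sqrt(4000)
        z = (mean_sq - expected) / se
        # per-variant deviations jointly consistent with Monte-Carlo noise
        assert (z**2).sum() < J + 3 * np.sqrt(2 * J)
        # and the realized weights are proportional to the annotation model
        slope = (mean_sq @ expected) / (expected @ expected)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert (reps**2).sum(axis=1).mean() == pytest.approx(0.5, rel=0.05)


class TestH2Exact:
    def test_no_ld_algebraic_scaling(self):
        layout = identity_layout(2)
        gamma = np.array([[0.1], [0.3]])
        out = apply_h2_exact(gamma, layout, [0.5])
        np.testing.assert_allclose(out, gamma * np.sqrt(5.0))
        assert (out**2).sum() == pytest.approx(0.5, abs=1e-12)

    def test_quadratic_form_exact_under_ld(self, feasible_block_layout):
        rng = np.random.default_rng(3)
        gamma = rng.normal(size=(6, 2)) * 0.1
        out = apply_h2_exact(gamma, feasible_block_layout, [0.3, 0.05])
        R = feasible_block_layout.materialize()
        for k, target in enumerate([0.3, 0.05]):
            assert out[:, k] @ R @ out[:, k] == pytest.approx(target, abs=1e-10)

    def test_zero_target_forces_zero_column(self):
        layout = identity_layout(3)
        out = apply_h2_exact(np.ones((3, 1)), layout, [0.0])
        assert not out.any()

    def test_zero_column_positive_target_errors(self):
        layout = identity_layout(3)
        with pytest.raises(ValueError):
            apply_h2_exact(np.zeros((3, 1)), layout, [0.2])


class TestPropagation:
    def test_no_dag_joint_equals_direct(self):
        gamma = np.random.default_rng(0).normal(size=(7, 3))
        np.testing.assert_array_equal(
            compute_joint_effects(gamma, np.zeros((3, 3))), gamma
        )

    def test_worked_three_trait_propagation(self, three_trait_dag):
        Dtot = total_effects(three_trait_dag)
        joint = compute_joint_effects(np.array([[1.0, 0.0, 0.0]]), Dtot)
        np.testing.assert_allclose(joint, [[1.0, 0.8, -0.12]], atol=1e-12)

    def test_linearity(self, three_trait_dag):
        Dtot = total_effects(three_trait_dag)
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 5, 3))
        np.testing.assert_allclose(
            compute_joint_effects(a + b, Dtot),
            compute_joint_effects(a, Dtot) + compute_joint_effects(b, Dtot),
        )

    def test_marginal_identity_ld(self):
        layout = identity_layout(4)
        beta = np.random.default_rng(2).normal(size=(4, 2))
        np.testing.assert_array_equal(compute_marginal_effects(beta, layout), beta)

    def test_marginal_hand_product(self):
        block = np.array([[1.0, 0.5], [0.5, 1.0]])
        layout = tile_pattern(make_ld_pattern([block], np.full(2, 0.5)), 2)
        out = compute_marginal_effects(np.array([[0.1], [0.0]]), layout)
        np.testing.assert_allclose(out, [[0.1], [0.05]])

    def test_marginal_matches_dense_product(self, ar1_layout):
        rng = np.random.default_rng(4)
        beta = rng.normal(size=(12, 2))
        np.testing.assert_allclose(
            compute_marginal_effects(beta, ar1_layout),
            ar1_layout.materialize() @ beta,
        )


class TestRealizedVariance:
    def test_expected_direct_variance_recovered(self):
        # pi*J = 100 causal on average; mean realized variance ~ target
        J = 1000
        layout = identity_layout(J, f=0.3)
        reals = [
            simulate_effects(
                layout, np.zeros((1, 1)), np.array([0.3]), 0.1,
                np.random.default_rng(s),
            ).realized_vg_direct[0]
            for s in range(300)
        ]
        se = np.std(reals, ddof=1) / np.sqrt(300)
        assert abs(np.mean(reals) - 0.3) < 3 * se

    def test_realized_total_h2_close_with_many_causals(self, three_trait_dag):
        J = 2000
        layout = identity_layout(J, f=0.4)
        Dtot = total_effects(three_trait_dag)
        from sumstatsim.sem import direct_genetic_variance

        h2 = np.array([0.3, 0.3, 0.3])
        vg = direct_genetic_variance(three_trait_dag, h2)
        eff = simulate_effects(
            layout, Dtot, vg, 0.5, np.random.default_rng(11)
        )
        np.testing.assert_allclose(eff.realized_h2, h2, rtol=0.10)

    def test_permutation_equivariance(self, three_trait_dag):
        # relabeling traits permutes the effect columns consistently
        layout = identity_layout(50, f=0.4)
        from sumstatsim.sem import direct_genetic_variance

        h2 = np.array([0.3, 0.4, 0.2])
        perm = np.array([2, 0, 1])
        Dp = three_trait_dag[np.ix_(perm, perm)]
        vg = direct_genetic_variance(three_trait_dag, h2)
        gamma = np.random.default_rng(8).normal(size=(50, 3)) * np.sqrt(vg / 25)
        joint = compute_joint_effects(gamma, total_effects(three_trait_dag))
        joint_p = compute_joint_effects(gamma[:, perm], total_effects(Dp))
        np.testing.assert_allclose(joint_p, joint[:, perm], atol=1e-12)
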