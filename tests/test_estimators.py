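"""Horvitz-Thompson estimation and variance machinery."""

import numpy as np
import pytest

import mht
from conftest import (
    estimate_all,
    masked,
    pps_fixture,
    theoretical_variance,
    two_stage_3x3,
)


class TestOnePassMoments:
    def test_small_cases(self):
        assert mht.onepass_mean_ssd(np.array([5.0, 5.0, 5.0])) == (5.0, 0.0)
        mean, ssd = mht.onepass_mean_ssd(np.array([1.0, 2.0, 3.0]))
        assert (mean, ssd) == (2.0, 2.0)
        with pytest.raises(ValueError, match="empty"):
            mht.onepass_mean_ssd(np.array([]))

    def test_matches_two_pass_with_large_offset(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=10_000) + 1e4  # offset punishes the naive formula
        _, ssd = mht.onepass_mean_ssd(y)
        two_pass = float(np.sum((y - y.mean()) ** 2))
        assert ssd == pytest.approx(two_pass, rel=1e-12)
        naive = float(np.sum(y * y) - len(y) * y.mean() ** 2)
        assert abs(naive - two_pass) > abs(ssd - two_pass)  # stability payoff


class TestTotals:
    def test_census_recovers_true_total(self):
        tree = two_stage_3x3()
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor", "srswor"], [3, 3])
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(2).normal(size=9)
        I = np.ones(tree.n_nodes, dtype=np.int64)
        _, yhat = mht.ht_total_general(y, I, plan.P, tree.C, tree.D, spec.S)
        assert yhat == pytest.approx(y.sum(), rel=1e-14)
        _, yhat_s = mht.ht_total_srswor(y, I, tree.C, tree.D, spec.S)
        assert yhat_s == pytest.approx(y.sum(), rel=1e-14)

    def test_single_stage_classic_expansion(self):
        tree = mht.random_tree(1, 6, 6, seed=0)
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor"], [3])
        plan = mht.build_plan(tree, spec)
        y = np.arange(1.0, 7.0)
        I = np.zeros(7, dtype=np.int64)
        I[[0, 1, 3, 5]] = 1  # root + leaves 1, 3, 5
        yy = masked(y, I, tree)
        _, yhat = mht.ht_total_general(yy, I, plan.P, tree.C, tree.D, spec.S)
        sample_sum = y[0] + y[2] + y[4]
        assert yhat == pytest.approx(6 / 3 * sample_sum, rel=1e-14)

    def test_constant_y_expands_to_cN(self):
        # equal cluster sizes make every leaf weight N/n, so the
        # expansion of a constant is exact on every draw
        tree = mht.random_tree(3, 3, 3, seed=6)
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor"] * 3, [2, 2, 2])
        plan = mht.build_plan(tree, spec)
        y = np.full(tree.n_leaves, 3.25)
        I = mht.draw_multistage_sample(tree, plan, np.random.default_rng(1))
        yy = masked(y, I, tree)
        _, yhat = mht.ht_total_srswor(yy, I, tree.C, tree.D, spec.S)
        assert yhat == pytest.approx(3.25 * tree.n_leaves, rel=1e-12)

    def test_unsampled_leaf_values_never_read(self):
        tree, spec, plan, y = pps_fixture()
        I = mht.draw_multistage_sample(tree, plan, np.random.default_rng(4))
        leaf = tree.level_slice(tree.L)
        base = estimate_all(tree, spec, plan, y, I)
        poisoned = y.copy()
        poisoned[I[leaf] == 0] = 1e30
        assert estimate_all(tree, spec, plan, poisoned, I) == base

    def test_sampled_leaf_missing_y_rejected(self):
        tree, spec, plan, y = pps_fixture()
        I = mht.draw_multistage_sample(tree, plan, np.random.default_rng(4))
        leaf = tree.level_slice(tree.L)
        yy = masked(y, I, tree)
        yy[np.flatnonzero(I[leaf] == 1)[0]] = np.nan
        with pytest.raises(ValueError, match="no y value"):
            mht.ht_total_general(yy, I, plan.P, tree.C, tree.D, spec.S)


class TestTheoreticalVariance:
    def test_census_variance_is_zero(self):
        tree = two_stage_3x3()
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor", "srswor"], [3, 3])
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(3).normal(size=9)
        TY, V = theoretical_variance(tree, plan, y)
        assert V == pytest.approx(0.0, abs=1e-12)
        _, V_s = mht.variance_srswor(TY, tree.C, tree.D, spec.S)
        assert V_s == pytest.approx(0.0, abs=1e-12)

    def test_single_stage_textbook_srswor_variance(self):
        tree = mht.random_tree(1, 8, 8, seed=0)
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor"], [3])
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(5).gamma(2, 1, 8)
        TY, V = theoretical_variance(tree, plan, y)
        N, n = 8, 3
        S2 = np.var(y, ddof=1)
        assert V == pytest.approx(N**2 * (1 - n / N) * S2 / n, rel=1e-12)
        _, V_s = mht.variance_srswor(TY, tree.C, tree.D, spec.S)
        assert V_s == pytest.approx(V, rel=1e-12)

    def test_syg_vanishes_for_totals_proportional_to_pi(self):
        """If child totals are proportional to their probabilities the
        expansion estimate is constant, so the node variance is zero."""
        tree, spec, plan, _ = pps_fixture(sizes=(2, 3, 4))
        TY = np.zeros(tree.n_nodes)
        TY[1:4] = plan.P[1:4] * 11.0  # PSU totals proportional to pi
        Vstar = mht.node_variances_syg(TY, plan.P, plan.store, tree.C, tree.D)
        assert Vstar[0] == pytest.approx(0.0, abs=1e-12)

    def test_explicit_threestage_equals_recurrence(self):
        tree = mht.random_tree(3, 3, 4, seed=17)
        spec, _, plan = mht.build_selfweighted_plan(tree, [2, 2, 2])
        y = np.random.default_rng(23).gamma(2, 1, tree.n_leaves)
        TY, V = theoretical_variance(tree, plan, y)
        V_exp = mht.explicit_threestage_variance(
            TY, plan.P, plan.store, tree.C, tree.D, spec.S
        )
        assert V_exp == pytest.approx(V, abs=1e-12 * max(1, abs(V)))

    def test_explicit_threestage_requires_three_stages(self):
        tree, spec, plan, y = pps_fixture()
        TY = mht.node_totals(y, tree.C, tree.D)
        with pytest.raises(ValueError, match="exactly 3 stages"):
            mht.explicit_threestage_variance(
                TY, plan.P, plan.store, tree.C, tree.D, spec.S
            )

    def test_explicit_threestage_census_final_stage(self):
        """With a census at stage 3 the within-cluster terms vanish."""
        tree = mht.random_tree(3, 3, 3, seed=2)
        x = np.ones(tree.n_leaves)
        spec = mht.StageDesignSpec.per_stage(
            tree, ["ppswor", "ppswor", "srswor"], [2, 2, 3], x=x
        )
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(2).gamma(2, 1, tree.n_leaves)
        TY, V = theoretical_variance(tree, plan, y)
        V_exp = mht.explicit_threestage_variance(
            TY, plan.P, plan.store, tree.C, tree.D, spec.S
        )
        assert V_exp == pytest.approx(V, abs=1e-12 * max(1, abs(V)))


class TestVarianceEstimates:
    def test_census_estimates_are_zero(self):
        tree = two_stage_3x3()
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor", "srswor"], [3, 3])
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(3).normal(size=9)
        I = np.ones(tree.n_nodes, dtype=np.int64)
        _, v_syg, v_app = estimate_all(tree, spec, plan, y, I)
        assert v_syg == pytest.approx(0.0, abs=1e-12)
        assert v_app == pytest.approx(0.0, abs=1e-12)
        _, v_s = mht.variance_estimate_srswor(y, I, tree.C, tree.D, spec.S)
        assert v_s == pytest.approx(0.0, abs=1e-12)

    def test_syg_estimate_closed_form_single_stage(self):
        """One SRSWOR stage: the SYG estimate reduces to N^2(1-f)s^2/n."""
        tree = mht.random_tree(1, 8, 8, seed=0)
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor"], [4])
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(9).gamma(2, 1, 8)
        I = mht.draw_multistage_sample(tree, plan, np.random.default_rng(2))
        yy = masked(y, I, tree)
        _, v_syg, _ = estimate_all(tree, spec, plan, y, I)
        s2 = np.var(yy[I[1:] == 1], ddof=1)
        N, n = 8, 4
        assert v_syg == pytest.approx(N**2 * (1 - n / N) * s2 / n, rel=1e-12)

    def test_approx_reduces_to_srswor_form(self):
        """Under equal within-block probabilities the approximate node
        term collapses to the SRSWOR estimator term exactly."""
        rng = np.random.default_rng(12)
        for trial in range(5):
            N = int(rng.integers(4, 10))
            n = int(rng.integers(2, N))
            tree = mht.random_tree(1, N, N, seed=trial)
            spec = mht.StageDesignSpec.per_stage(tree, ["srswor"], [n])
            plan = mht.build_plan(tree, spec)
            y = rng.gamma(2, 1, N)
            I = mht.draw_multistage_sample(tree, plan, np.random.default_rng(trial))
            yy = masked(y, I, tree)
            HTE, _ = mht.ht_total_general(yy, I, plan.P, tree.C, tree.D, spec.S)
            va = mht.node_variance_estimates_approx(
                HTE, plan.P, I, tree.C, tree.D, spec.S
            )
            s2 = np.var(yy[I[1:] == 1], ddof=1)
            assert va[0] == pytest.approx(N**2 * (1 - n / N) * s2 / n, rel=1e-10)

    def test_srswor_estimate_path_equals_general(self):
        tree = mht.random_tree(2, 3, 5, seed=31)
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor", "srswor"], [2, 2])
        plan = mht.build_plan(tree, spec)
        y = np.random.default_rng(8).gamma(2, 1, tree.n_leaves)
        I = mht.draw_multistage_sample(tree, plan, np.random.default_rng(3))
        yy = masked(y, I, tree)
        _, v_syg, _ = estimate_all(tree, spec, plan, y, I)
        _, v_s = mht.variance_estimate_srswor(yy, I, tree.C, tree.D, spec.S)
        assert v_s == pytest.approx(v_syg, rel=1e-10)

    def test_non_census_single_draw_block_rejected(self):
        tree = two_stage_3x3()
        spec = mht.StageDesignSpec.per_stage(tree, ["srswor", "srswor"], [2, 2])
        plan = mht.build_plan(tree, spec)
        bad_S = spec.S.copy()
        bad_S[1:4] = 1  # one SSU per sampled PSU
        y = np.random.default_rng(0).normal(size=9)
        I = np.zeros(tree.n_nodes, dtype=np.int64)
        I[[0, 1, 2, 4, 7]] = 1
        yy = masked(y, I, tree)
        with pytest.raises(ValueError, match="sample size 1"):
            mht.variance_estimate_srswor(yy, I, tree.C, tree.D, bad_S)
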