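import numpy as np
import pytest

import mht


def balanced_tree(L: int, k: int) -> mht.Tree:
    """Perfect k-ary hierarchy on L levels."""
    return mht.random_tree(L, k, k, seed=0)


def two_stage_3x3() -> mht.Tree:
    """Root -> 3 PSUs -> 3 SSUs each (the workhorse small fixture)."""
    return balanced_tree(2, 3)


@pytest.fixture
def tree_3x3() -> mht.Tree:
    return two_stage_3x3()


@pytest.fixture
def selfweighted_l3():
    """A 3-stage self-weighted plan (PPS / PPS / SRSWOR, m = 2 each)
    on a random hierarchy with 3-4 children per internal node."""
    tree = mht.random_tree(3, 3, 4, seed=7)
    spec, sw, plan = mht.build_selfweighted_plan(tree, [2, 2, 2])
    y = np.random.default_rng(11).gamma(2.0, 1.0, tree.n_leaves)
    return tree, spec, sw, plan, y


def pps_fixture(sizes=(2, 3, 4), n1: int = 2, n2: int = 2, seed: int = 3):
    """Two-stage fixture: 3 PSUs chosen by PPSWOR with the given size
    totals, then SRSWOR of n2 of the 3 SSUs inside each PSU."""
    tree = two_stage_3x3()
    x = np.repeat(np.asarray(sizes, dtype=float) / 3.0, 3)
    spec = mht.StageDesignSpec.per_stage(tree, ["ppswor", "srswor"], [n1, n2], x=x)
    plan = mht.build_plan(tree, spec)
    y = np.random.default_rng(seed).gamma(2.0, 1.0, tree.n_leaves)
    return tree, spec, plan, y


def masked(y: np.ndarray, I: np.ndarray, tree: mht.Tree) -> np.ndarray:
    """Leaf values with NaN on unsampled elementary units."""
    leaf = tree.level_slice(tree.L)
    return np.where(I[leaf] == 1, y, np.nan)


def estimate_all(tree, spec, plan, y, I):
    """Convenience: (Yhat, Vhat_syg, Vhat_approx) via the general path."""
    C, D, S = tree.C, tree.D, spec.S
    yy = masked(y, I, tree)
    HTE, yhat = mht.ht_total_general(yy, I, plan.P, C, D, S)
    vs = mht.node_variance_estimates_syg(HTE, plan.P, plan.store, I, C, D, S)
    _, v_syg = mht.variance_estimate_general(vs, plan.P, I, C, D)
    va = mht.node_variance_estimates_approx(HTE, plan.P, I, C, D, S)
    _, v_app = mht.variance_estimate_general(va, plan.P, I, C, D)
    return yhat, v_syg, v_app


def theoretical_variance(tree, plan, y):
    TY = mht.node_totals(y, tree.C, tree.D)
    Vs = mht.node_variances_syg(TY, plan.P, plan.store, tree.C, tree.D)
    _, V = mht.variance_general(Vs, plan.P, tree.C, tree.D)
    return TY, V
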