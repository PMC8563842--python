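"""Stage designs and inclusion-probability calculus.

A multistage design attaches, to every internal node of the unit tree,
a fixed-size without-replacement design on that node's children: either
SRSWOR (simple random sampling) or PPSWOR (probability proportional to
size).  This module computes

* per-node totals of a leaf variable (sizes, or the study variable),
* first-order inclusion probabilities ``P`` (pi per node, within its
  parent's block),
* overall inclusion probabilities ``Pstar`` via the selection equation
  ``pi*_child = pi_child * pi*_parent``,
* joint (second-order) inclusion probabilities, packed block-diagonally
  into two flat arrays ``(F, PP)``,
* self-weighted plans: per-stage constant sample sizes ``m_l`` with PPS
  probabilities proportional to descendant-leaf counts, which give every
  elementary unit the same overall probability ``n/N`` with
  ``n = prod(m_l)``.

The PPSWOR scheme used throughout is the exact conditional (rejective)
fixed-size design: all ``C(N, n)`` child subsets are enumerated with
probability proportional to the product of per-unit odds, and the odds
are calibrated by a damped fixed-point iteration so that the realized
first-order probabilities hit the PPS targets.  This yields exact joint
probabilities, all strictly positive, as the Sen-Yates-Grundy variance
machinery requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .tree import Tree, child_starts

__all__ = [
    "SRSWOR",
    "PPSWOR",
    "StageDesignSpec",
    "RejectiveBlock",
    "JointProbabilityStore",
    "SelfWeightedPlan",
    "DesignPlan",
    "node_totals",
    "srswor_first_order",
    "srswor_joint",
    "pps_first_order",
    "overall_probs",
    "sym_pair_index",
    "calibrate_rejective_block",
    "build_joint_store",
    "get_joint_prob",
    "build_plan",
    "build_selfweighted_plan",
]

SRSWOR = "srswor"
PPSWOR = "ppswor"

#: Default cap on the number of enumerated subsets per PPSWOR block.
ENUMERATION_CAP = 10**6


# ---------------------------------------------------------------------------
# Specification containers
# ---------------------------------------------------------------------------


@dataclass
class StageDesignSpec:
    """Per-node design kinds and sample sizes.

    ``kinds[l]`` is the design applied within every level-``l`` parent
    (stage ``l+1`` of the survey); ``S[v]`` is the number of children
    sampled inside internal node ``v`` (0 at leaves).  ``x`` is the
    leaf-level size variable, required iff any stage is PPSWOR.
    """

    kinds: list[str]
    S: np.ndarray
    x: np.ndarray | None = None

    def validate(self, tree: Tree) -> None:
        if len(self.kinds) != tree.L:
            raise ValueError(f"need one design kind per stage (expected {tree.L})")
        for k in self.kinds:
            if k not in (SRSWOR, PPSWOR):
                raise ValueError(f"unknown design kind {k!r}")
        if len(self.S) != tree.n_nodes:
            raise ValueError("S must have one entry per node")
        C = tree.C
        for lev in range(tree.L):
            seg = tree.level_slice(lev)
            n_blk = self.S[seg]
            N_blk = C[seg]
            bad = ~(((n_blk > 1) & (n_blk <= N_blk)) | (n_blk == N_blk))
            if np.any(bad):
                pos = int(np.flatnonzero(bad)[0]) + 1
                raise ValueError(
                    f"infeasible sample size at level {lev}, position {pos}: "
                    f"need 1 < n <= N (or census n = N), got "
                    f"n={int(n_blk[bad][0])}, N={int(N_blk[bad][0])}"
                )
        if any(k == PPSWOR for k in self.kinds) and self.x is None:
            raise ValueError("PPSWOR stages require a leaf size variable x")

    @classmethod
    def per_stage(
        cls,
        tree: Tree,
        kinds: list[str],
        n: list[int],
        x: np.ndarray | None = None,
    ) -> "StageDesignSpec":
        """Constant sample size per stage; ``n[l]`` children sampled in
        every level-``l`` parent."""
        S = np.zeros(tree.n_nodes, dtype=np.int64)
        for lev in range(tree.L):
            S[tree.level_slice(lev)] = n[lev]
        spec = cls(kinds=list(kinds), S=S, x=x)
        spec.validate(tree)
        return spec


@dataclass
class RejectiveBlock:
    """Exact enumerated fixed-size design on one child block."""

    subsets: np.ndarray  # (n_subsets, n) 0-based within-block indices
    probs: np.ndarray  # subset probabilities, sum to 1
    pi: np.ndarray  # realized first-order probabilities
    pijk: np.ndarray  # packed strict upper triangle of joint probabilities
    forced: np.ndarray  # within-block indices with pi = 1 (certainty units)


@dataclass
class JointProbabilityStore:
    """Block-diagonal joint inclusion probabilities as two flat arrays.

    ``F[k]`` is the offset into ``PP`` of the packed strict upper
    triangle for the children block of internal node ``k`` (internal
    nodes are exactly the sorted positions ``0..n_internal-1``);
    ``F[-1] = len(PP)``.  Pairs within a block are stored in
    lexicographic ``(j < k)`` order.
    """

    F: np.ndarray
    PP: np.ndarray

    def block(self, k: int) -> np.ndarray:
        return self.PP[int(self.F[k]) : int(self.F[k + 1])]


@dataclass
class SelfWeightedPlan:
    """Summary of a self-weighted multistage plan."""

    m: list[int]  # per-stage constant sample sizes
    n: int  # final sample size, prod(m)
    N: int  # number of elementary units
    pi_star: float  # common overall leaf probability n / N


@dataclass
class DesignPlan:
    """A design spec with all probabilities resolved against a tree."""

    spec: StageDesignSpec
    P: np.ndarray  # first-order pi per node (root = 1)
    Pstar: np.ndarray  # overall pi* per node (root = 1)
    blocks: dict[int, RejectiveBlock] = field(default_factory=dict)
    store: JointProbabilityStore | None = None
    TX: np.ndarray | None = None  # per-node size totals (PPSWOR stages)


# ---------------------------------------------------------------------------
# Totals and first-order probabilities
# ---------------------------------------------------------------------------


def node_totals(leaf_values: np.ndarray, C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Per-node totals of a leaf-level variable, bottom-up.

    Leaf entries equal the leaf values; each internal node holds the sum
    over its children; the root holds the grand total.
    """
    L = int(D.shape[0] - 1)
    n1 = int(D[-1, 1])
    n_leaves = int(D[L, 1] - D[L, 0])
    leaf_values = np.asarray(leaf_values, dtype=np.float64)
    if len(leaf_values) != n_leaves:
        raise ValueError(
            f"need one value per elementary unit ({n_leaves}), got {len(leaf_values)}"
        )
    if np.any(np.isnan(leaf_values)):
        pos = int(np.flatnonzero(np.isnan(leaf_values))[0]) + 1
        raise ValueError(f"missing leaf value at leaf position {pos}")
    TX = np.zeros(n1, dtype=np.float64)
    TX[int(D[L, 0]) :] = leaf_values
    cs = child_starts(C, D)
    for lev in range(L - 1, -1, -1):
        start, stop = int(D[lev, 0]), int(D[lev, 1])
        nxt = TX[int(D[lev + 1, 0]) : int(D[lev + 1, 1])]
        offs = cs[start:stop] - int(D[lev + 1, 0])
        TX[start:stop] = np.add.reduceat(nxt, offs)
    return TX


def srswor_first_order(N: int, n: int) -> np.ndarray:
    """First-order probabilities of an SRSWOR block: ``pi = n/N`` each."""
    if n > N:
        raise ValueError(f"sample size {n} exceeds block size {N}")
    return np.full(N, n / N, dtype=np.float64)


def srswor_joint(N: int, n: int) -> float:
    """Joint probability of any pair under SRSWOR: ``n(n-1)/(N(N-1))``."""
    if n > N:
        raise ValueError(f"sample size {n} exceeds block size {N}")
    return n * (n - 1) / (N * (N - 1))


def pps_first_order(sizes: np.ndarray, n: int) -> np.ndarray:
    """PPS target probabilities ``pi_j = n x_j / sum(x)``.

    Certainty selections (``pi > 1``) are rejected: splitting off units
    that must always be selected is out of scope here.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if np.any(sizes <= 0):
        raise ValueError("PPS sizes must be strictly positive")
    pi = n * sizes / sizes.sum()
    if np.any(pi > 1.0 + 1e-12):
        j = int(np.argmax(pi)) + 1
        raise ValueError(
            f"PPS probability exceeds 1 for block unit {j} (pi={pi[j - 1]:.6g}); "
            "certainty-selection handling is out of scope — reduce n or use "
            "a different size variable"
        )
    return np.minimum(pi, 1.0)


def overall_probs(P: np.ndarray, C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Overall inclusion probabilities by the selection equation.

    Single top-down pass: root gets 1, every child gets its own
    first-order probability times its parent's overall probability.
    """
    L = int(D.shape[0] - 1)
    Pstar = np.ones(int(D[-1, 1]), dtype=np.float64)
    cs = child_starts(C, D)
    for lev in range(L):
        for v in range(int(D[lev, 0]), int(D[lev, 1])):
            blk = slice(int(cs[v]), int(cs[v] + C[v]))
            Pstar[blk] = P[blk] * Pstar[v]
    return Pstar


# ---------------------------------------------------------------------------
# Joint probabilities: packed symmetric storage
# ---------------------------------------------------------------------------


def sym_pair_index(i: int, j: int, N: int) -> int:
    """1-based packed index of the unordered pair {i, j} in the strict
    upper triangle of an N x N symmetric matrix, pairs (j < k) stored in
    lexicographic order.

    Diagonal elements are first-order probabilities and are held in
    ``P``, not ``PP``; requesting ``i == j`` is an error.
    """
    if i == j:
        raise ValueError("diagonal entries are first-order probabilities, not stored")
    if not (1 <= i <= N and 1 <= j <= N):
        raise ValueError(f"pair ({i}, {j}) out of range for block size {N}")
    if i > j:
        i, j = j, i
    return (i - 1) * N - i * (i + 1) // 2 + j


def calibrate_rejective_block(
    target_pi: np.ndarray,
    n: int,
    cap: int = ENUMERATION_CAP,
    tol: float = 1e-13,
    max_iter: int = 200,
    damping: float = 1.0,
) -> RejectiveBlock:
    """Exact conditional (rejective) fixed-size design hitting target
    first-order probabilities.

    All ``C(N, n)`` subsets receive probability proportional to the
    product of per-unit working odds ``w_j``; the log-odds are adjusted
    by a step-limited Newton iteration (the Jacobian of the realized
    probabilities with respect to log-odds is the exact indicator
    covariance, available from the enumeration) until the realized
    inclusion probabilities match ``target_pi`` to ``tol``.  Units with
    ``pi = 1`` are forced into every subset.  Joint probabilities are
    read off the enumerated distribution, hence exact and positive.
    """
    target_pi = np.asarray(target_pi, dtype=np.float64)
    N = len(target_pi)
    if abs(target_pi.sum() - n) > 1e-8:
        raise ValueError("target probabilities must sum to the sample size")
    forced = np.flatnonzero(target_pi >= 1.0 - 1e-12)
    free = np.flatnonzero(target_pi < 1.0 - 1e-12)
    n_free = n - len(forced)
    if n_free < 0:
        raise ValueError("more certainty units than the sample size")
    n_subsets = comb(len(free), n_free)
    if n_subsets > cap:
        raise ValueError(
            f"PPSWOR block requires enumerating {n_subsets} subsets, above the "
            f"cap {cap}; use the approximate (first-order-only) estimator path"
        )
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(len(free)), n_free)),
        dtype=np.int64,
        count=n_subsets * n_free,
    ).reshape(n_subsets, n_free)
    membership = np.zeros((n_subsets, len(free)), dtype=np.float64)
    np.put_along_axis(membership, combos, 1.0, axis=1)

    t = target_pi[free]
    logw = np.log(t / (1.0 - t))  # working log-odds, initialized at targets
    probs = np.full(n_subsets, 1.0 / n_subsets)
    for _ in range(max_iter if t.size else 0):
        logp = membership @ logw
        logp -= logp.max()
        probs = np.exp(logp)
        probs /= probs.sum()
        pi = membership.T @ probs
        if np.max(np.abs(pi - t)) < tol:
            break
        # Newton step on log-odds; the Jacobian is the exact indicator
        # covariance (singular by the fixed-size constraint: pin the
        # last free unit).  Steps are clipped to keep the iteration
        # inside the region where the linearization is trustworthy.
        cov = membership.T @ (membership * probs[:, None]) - np.outer(pi, pi)
        try:
            step = np.linalg.solve(cov[:-1, :-1], (t - pi)[:-1])
        except np.linalg.LinAlgError:
            step = (t - pi)[:-1] / np.maximum((pi * (1.0 - pi))[:-1], 1e-12)
        logw[:-1] += np.clip(step, -2.0 * damping, 2.0 * damping)
    else:
        raise RuntimeError(
            "rejective-design calibration did not converge; "
            "check the target probabilities"
        )

    # assemble full-block subsets (forced units always present) and pi
    full_subsets = np.empty((n_subsets, n), dtype=np.int64)
    full_subsets[:, : len(forced)] = forced
    full_subsets[:, len(forced) :] = free[combos]
    full_subsets.sort(axis=1)
    pi_full = np.empty(N, dtype=np.float64)
    pi_full[forced] = 1.0
    pi_full[free] = membership.T @ probs

    # joint probabilities from the enumerated distribution
    Z = np.zeros((n_subsets, N), dtype=np.float64)
    np.put_along_axis(Z, full_subsets, 1.0, axis=1)
    joint = Z.T @ (Z * probs[:, None])
    iu, ju = np.triu_indices(N, k=1)
    pijk = joint[iu, ju]
    return RejectiveBlock(
        subsets=full_subsets,
        probs=probs,
        pi=pi_full,
        pijk=pijk,
        forced=forced,
    )


def build_joint_store(
    spec: StageDesignSpec,
    tree: Tree,
    P: np.ndarray,
    blocks: dict[int, RejectiveBlock] | None = None,
) -> JointProbabilityStore:
    """Pack per-block joint probabilities into the flat (F, PP) arrays.

    Blocks are laid out level-major in sorted node order (which is also
    the order of internal node positions).  SRSWOR blocks use the closed
    form ``n(n-1)/(N(N-1))``; PPSWOR blocks use the exact rejective
    enumeration.
    """
    n_internal = tree.n_internal
    C = tree.C
    F = np.zeros(n_internal + 1, dtype=np.int64)
    tri = C[:n_internal] * (C[:n_internal] - 1) // 2
    F[1:] = np.cumsum(tri)
    PP = np.zeros(int(F[-1]), dtype=np.float64)
    for lev in range(tree.L):
        kind = spec.kinds[lev]
        for v in range(int(tree.D[lev, 0]), int(tree.D[lev, 1])):
            Nb, nb = int(C[v]), int(spec.S[v])
            blk = slice(int(F[v]), int(F[v + 1]))
            if kind == SRSWOR or Nb == nb:  # census blocks: all pairs certain
                PP[blk] = srswor_joint(Nb, nb)
            else:
                if blocks is None or v not in blocks:
                    raise ValueError(
                        f"PPSWOR block at node position {v + 1} has no calibrated "
                        "design; build the plan first"
                    )
                PP[blk] = blocks[v].pijk
    if np.any(PP < -1e-15):
        k = int(np.flatnonzero(PP < -1e-15)[0])
        raise ValueError(f"negative joint probability at packed position {k + 1}")
    # pi_jk = 0 can be forced by the first-order probabilities themselves
    # (a certainty unit with n = 2 leaves the remaining pair incompatible);
    # it is stored as-is and rejected only by the SYG estimator, which
    # requires positive pair probabilities among sampled pairs.
    PP[PP < 0] = 0.0
    return JointProbabilityStore(F=F, PP=PP)


def get_joint_prob(store: JointProbabilityStore, k: int, i: int, j: int) -> float:
    """Joint inclusion probability of within-block children ``i != j``
    (1-based) of the internal node at sorted position ``k`` (0-based).

    Symmetric in ``i`` and ``j``; block size is inferred from the packed
    triangle length.
    """
    blk = store.block(k)
    # triangle length N(N-1)/2 -> N
    N = int(round((1 + np.sqrt(1 + 8 * len(blk))) / 2))
    if not (1 <= i <= N and 1 <= j <= N):
        raise ValueError(f"pair ({i}, {j}) outside block of size {N}")
    return float(blk[sym_pair_index(i, j, N) - 1])


# ---------------------------------------------------------------------------
# Plan construction
# ---------------------------------------------------------------------------


def build_plan(
    tree: Tree,
    spec: StageDesignSpec,
    cap: int = ENUMERATION_CAP,
    with_joint: bool = True,
) -> DesignPlan:
    """Resolve a design spec against a tree: first-order and overall
    probabilities, calibrated PPSWOR blocks, and (optionally) the packed
    joint-probability store."""
    spec.validate(tree)
    C, D = tree.C, tree.D
    cs = child_starts(C, D)
    P = np.ones(tree.n_nodes, dtype=np.float64)
    TX = None
    if any(k == PPSWOR for k in spec.kinds):
        TX = node_totals(spec.x, C, D)
    blocks: dict[int, RejectiveBlock] = {}
    for lev in range(tree.L):
        kind = spec.kinds[lev]
        for v in range(int(D[lev, 0]), int(D[lev, 1])):
            blk = slice(int(cs[v]), int(cs[v] + C[v]))
            Nb, nb = int(C[v]), int(spec.S[v])
            if kind == SRSWOR:
                P[blk] = srswor_first_order(Nb, nb)
            else:
                # a PPS census is only consistent when all targets are 1
                # (equal sizes); unequal sizes raise the certainty error
                target = pps_first_order(TX[blk], nb)
                P[blk] = target
                if nb < Nb:
                    blocks[v] = calibrate_rejective_block(target, nb, cap=cap)
    Pstar = overall_probs(P, C, D)
    store = build_joint_store(spec, tree, P, blocks) if with_joint else None
    return DesignPlan(spec=spec, P=P, Pstar=Pstar, blocks=blocks, store=store, TX=TX)


def build_selfweighted_plan(
    tree: Tree,
    m: list[int],
    x: np.ndarray | None = None,
    cap: int = ENUMERATION_CAP,
) -> tuple[StageDesignSpec, SelfWeightedPlan, DesignPlan]:
    """Self-weighted plan: constant per-stage sizes ``m_l`` with
    size-proportional probabilities.

    Stages ``1..L-1`` are PPSWOR with probabilities proportional to the
    number of underlying elementary units; the final stage is SRSWOR
    (size-proportional selection of elementary units of size 1 reduces
    to equal probabilities).  Every leaf then has overall probability
    ``n/N`` with ``n = prod(m_l)``, so all observations share one
    sampling weight.

    ``x`` overrides the unit-size measure (defaults to one per leaf);
    the self-weighting identity is guaranteed for the default.
    """
    if len(m) != tree.L:
        raise ValueError(f"need one per-stage size (expected {tree.L})")
    if x is None:
        x = np.ones(tree.n_leaves, dtype=np.float64)
    kinds = [PPSWOR] * (tree.L - 1) + [SRSWOR]
    S = np.zeros(tree.n_nodes, dtype=np.int64)
    bad: list[str] = []
    for lev in range(tree.L):
        seg = tree.level_slice(lev)
        S[seg] = m[lev]
        short = np.flatnonzero(tree.C[seg] < m[lev])
        bad.extend(
            f"level {lev} position {int(p) + 1} (children {int(tree.C[seg][p])} "
            f"< m={m[lev]})"
            for p in short
        )
    if bad:
        raise ValueError("infeasible per-stage sizes at: " + "; ".join(bad))
    spec = StageDesignSpec(kinds=kinds, S=S, x=np.asarray(x, dtype=np.float64))
    plan = build_plan(tree, spec, cap=cap)
    N = tree.n_leaves
    n = int(np.prod(m))
    sw = SelfWeightedPlan(m=list(m), n=n, N=N, pi_star=n / N)
    return spec, sw, plan
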