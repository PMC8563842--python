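"""Drawing multistage samples without replacement.

A multistage sample is drawn stage by stage under invariance (the same
block design applies whatever was drawn earlier) and independence
(blocks are drawn independently).  The result is a per-node 0/1
indicator: the root is always selected; within each selected parent's
child block, exactly the block's sample size of children are selected;
descendants of unselected parents are never visited and consume no
randomness, so cost is proportional to the sample, not the population.

Blocks are visited in level-major sorted-node order from a single
seeded stream, which makes any draw bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .designs import SRSWOR, DesignPlan, RejectiveBlock
from .tree import Tree, child_starts

__all__ = ["draw_srswor", "draw_ppswor", "draw_multistage_sample"]


def draw_srswor(N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement draw of ``n`` of ``N`` block positions.

    Returns sorted 0-based within-block indices; every one of the
    ``C(N, n)`` subsets is equally likely.
    """
    if n > N:
        raise ValueError(f"sample size {n} exceeds block size {N}")
    if n == N:
        return np.arange(N)
    return np.sort(rng.choice(N, size=n, replace=False))


def draw_ppswor(block: RejectiveBlock, rng: np.random.Generator) -> np.ndarray:
    """Draw one subset from a calibrated rejective PPSWOR block.

    The subset is drawn from the exact enumerated design distribution,
    so realized inclusion frequencies converge to the PPS targets.
    """
    if not isinstance(block, RejectiveBlock):
        raise ValueError("PPSWOR block is not calibrated; build the plan first")
    idx = rng.choice(len(block.probs), p=block.probs)
    return block.subsets[idx]


def draw_multistage_sample(
    tree: Tree, plan: DesignPlan, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw a multistage sample, returning the per-node 0/1 indicator.

    Blocks of unselected parents are skipped entirely; within each
    selected parent, its own stage design (SRSWOR or the calibrated
    rejective PPSWOR) selects the children.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    C, D, S = tree.C, tree.D, plan.spec.S
    cs = child_starts(C, D)
    I = np.zeros(tree.n_nodes, dtype=np.int64)
    I[0] = 1
    for lev in range(tree.L):
        kind = plan.spec.kinds[lev]
        for v in range(int(D[lev, 0]), int(D[lev, 1])):
            if I[v] == 0:
                continue
            Nb, nb = int(C[v]), int(S[v])
            if nb == Nb:
                chosen = np.arange(Nb)
            elif kind == SRSWOR:
                chosen = draw_srswor(Nb, nb, rng)
            else:
                chosen = draw_ppswor(plan.blocks[v], rng)
            I[int(cs[v]) + chosen] = 1
    return I
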