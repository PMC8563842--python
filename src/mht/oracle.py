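"""Independent correctness oracles.

Two deliberately naive cross-checks of the iterative machinery:

* :func:`enumerate_design` — exact enumeration of every attainable
  multistage sample with its probability (rational arithmetic for pure
  SRSWOR designs), from which exact expectations of any estimator and
  exact inclusion probabilities follow;
* :func:`recursive_reference` — a direct recursive implementation of
  the estimation recurrences on a nested child-list structure, the
  classic pointer-style formulation that the flat-array implementation
  replaces.

Both are intended for small fixtures only and make no attempt at
efficiency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from .designs import SRSWOR, DesignPlan
from .tree import Tree, child_starts

__all__ = ["EnumeratedDesign", "enumerate_design", "recursive_reference"]


@dataclass
class EnumeratedDesign:
    """Every attainable multistage sample with its probability."""

    samples: list[np.ndarray]  # per-node 0/1 indicators
    probs: list  # Fraction (pure SRSWOR) or float

    def total_probability(self):
        return sum(self.probs)

    def inclusion_probs(self) -> np.ndarray:
        """Exact overall inclusion probability per node."""
        n1 = len(self.samples[0])
        pi = np.zeros(n1, dtype=np.float64)
        for I, p in zip(self.samples, self.probs):
            pi += float(p) * I
        return pi

    def expectation(self, fn) -> float:
        """Exact expectation of a statistic of the sample indicator."""
        return float(sum(float(p) * fn(I) for I, p in zip(self.samples, self.probs)))

    def variance(self, fn) -> float:
        mean = self.expectation(fn)
        return float(
            sum(float(p) * (fn(I) - mean) ** 2 for I, p in zip(self.samples, self.probs))
        )


def _block_options(tree: Tree, plan: DesignPlan, v: int, lev: int):
    """All (subset, probability) choices for the children block of node v."""
    Nb, nb = int(tree.C[v]), int(plan.spec.S[v])
    if Nb == nb:
        return [(tuple(range(Nb)), Fraction(1))]
    if plan.spec.kinds[lev] == SRSWOR:
        p = Fraction(1, comb(Nb, nb))
        return [(s, p) for s in itertools.combinations(range(Nb), nb)]
    block = plan.blocks[v]
    return [
        (tuple(int(x) for x in block.subsets[k]), float(block.probs[k]))
        for k in range(len(block.probs))
    ]


def enumerate_design(
    tree: Tree, plan: DesignPlan, cap: int = 10**6
) -> EnumeratedDesign:
    """Enumerate every attainable multistage sample with its probability.

    Stage draws are independent within and across blocks and blocks of
    unselected parents are never drawn, so a sample's probability is the
    product of its selected blocks' subset probabilities.
    """
    cs = child_starts(tree.C, tree.D)
    samples: list[np.ndarray] = []
    probs: list = []

    def rec(lev: int, parents: list[int], I: np.ndarray, p) -> None:
        if lev == tree.L:
            samples.append(I.copy())
            probs.append(p)
            if len(samples) > cap:
                raise ValueError(f"enumeration exceeds the cap of {cap} samples")
            return
        options = [_block_options(tree, plan, v, lev) for v in parents]
        for combo in itertools.product(*options):
            I2 = I.copy()
            p2 = p
            nxt: list[int] = []
            for v, (subset, bp) in zip(parents, combo):
                chosen = [int(cs[v]) + c for c in subset]
                I2[chosen] = 1
                nxt.extend(chosen)
                p2 = p2 * bp
            rec(lev + 1, nxt, I2, p2)

    I0 = np.zeros(tree.n_nodes, dtype=np.int64)
    I0[0] = 1
    rec(0, [0], I0, Fraction(1))
    return EnumeratedDesign(samples=samples, probs=probs)


# ---------------------------------------------------------------------------
# Recursive reference estimators
# ---------------------------------------------------------------------------


def _children(tree: Tree) -> np.ndarray:
    return child_starts(tree.C, tree.D)


def recursive_reference(
    y: np.ndarray,
    tree: Tree,
    plan: DesignPlan,
    I: np.ndarray,
    TY: np.ndarray | None = None,
) -> dict:
    """Direct recursive evaluation of the estimation recurrences.

    Returns a dict with the total estimate ``Yhat``, the Sen-Yates-Grundy
    and approximate variance estimates ``Vhat_syg`` / ``Vhat_approx``
    and, when the true per-node totals ``TY`` are supplied, the
    theoretical variance ``V``.
    """
    cs = _children(tree)
    C, S, P = tree.C, plan.spec.S, plan.P
    leaf0 = int(tree.D[tree.L, 0])
    y = np.asarray(y, dtype=np.float64)

    def kids(v: int) -> range:
        return range(int(cs[v]), int(cs[v] + C[v]))

    def yhat(v: int) -> float:
        if v >= leaf0:
            return float(y[v - leaf0])
        return sum(yhat(j) / P[j] for j in kids(v) if I[j] == 1)

    def syg_term(v: int, values: dict[int, float], sampled_only: bool, estimate: bool) -> float:
        js = [j for j in kids(v) if (not sampled_only) or I[j] == 1]
        Nb = int(C[v])
        acc = 0.0
        for a_i, j in enumerate(js):
            for k in js[a_i + 1 :]:
                a, b = j - int(cs[v]) + 1, k - int(cs[v]) + 1
                idx = (a - 1) * Nb - a * (a + 1) // 2 + b - 1
                pijk = float(plan.store.block(v)[idx])
                term = (P[j] * P[k] - pijk) * (
                    values[j] / P[j] - values[k] / P[k]
                ) ** 2
                acc += term / pijk if estimate else term
        return acc

    def var_theo(v: int) -> float:
        if v >= leaf0:
            return 0.0
        vals = {j: float(TY[j]) for j in kids(v)}
        return syg_term(v, vals, sampled_only=False, estimate=False) + sum(
            var_theo(j) / P[j] for j in kids(v)
        )

    def vhat_syg(v: int) -> float:
        if v >= leaf0:
            return 0.0
        vals = {j: yhat(j) for j in kids(v) if I[j] == 1}
        return syg_term(v, vals, sampled_only=True, estimate=True) + sum(
            vhat_syg(j) / P[j] for j in kids(v) if I[j] == 1
        )

    def approx_term(v: int) -> float:
        js = [j for j in kids(v) if I[j] == 1]
        nb = int(S[v])
        pis = np.array([P[j] for j in js])
        if np.allclose(pis, 1.0):
            return 0.0
        c = (1.0 - pis) * nb / (nb - 1)
        yh = np.array([yhat(j) for j in js])
        ystar = pis * float(np.sum(c * yh / pis)) / float(np.sum(c))
        return float(np.sum(c / pis**2 * (yh - ystar) ** 2))

    def vhat_approx(v: int) -> float:
        if v >= leaf0:
            return 0.0
        return approx_term(v) + sum(
            vhat_approx(j) / P[j] for j in kids(v) if I[j] == 1
        )

    out = {
        "Yhat": yhat(0),
        "Vhat_syg": vhat_syg(0),
        "Vhat_approx": vhat_approx(0),
    }
    if TY is not None:
        out["V"] = var_theo(0)
    return out
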