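"""Horvitz-Thompson estimation and variance for multistage samples.

All operations are single bottom-up (or top-down) passes over the
sorted node arrays and deliberately accept only ``(C, D, S, I, P,
store, y)``: children of an internal node are located from children
counts and level ranges alone, so the level/path arrays used to build
the tree are never needed here and may be released.

Notation (per internal node ``v`` with children block ``j = 1..N_v``):

* expansion (Horvitz-Thompson) total estimate, bottom-up:
  ``Yhat_v = sum_{j in sample} Yhat_j / pi_j``;
* theoretical variance by the recurrence
  ``V_v = V*_v + sum_{all j} V_j / pi_j`` with the fixed-size
  Sen-Yates-Grundy node term
  ``V*_v = sum_{j<k} (pi_j pi_k - pi_jk)(Y_j/pi_j - Y_k/pi_k)^2``;
* its estimator
  ``Vhat_v = Vhat*_v + sum_{sampled j} Vhat_j / pi_j`` with the SYG
  node term divided by ``pi_jk`` and summed over sampled pairs;
* an approximate node term needing first-order probabilities only,
  ``Vhat*_v = sum_j c_j/pi_j^2 (Yhat_j - Yhat*_j)^2`` with
  ``c_j = (1 - pi_j) n_v/(n_v - 1)`` and ``Yhat*_j`` the
  ``c``-weighted projection of the block estimates onto ``pi``; it is
  design-biased (typically downward) but exact under equal
  probabilities, where it reduces to the SRSWOR term
  ``N^2 (1 - f) s^2 / n``.

Sums of squared deviations use the numerically stable one-pass
updating formula of Youngs and Cramer.
"""

from __future__ import annotations

import numpy as np

from .designs import JointProbabilityStore
from .tree import child_starts

__all__ = [
    "onepass_mean_ssd",
    "ht_total_general",
    "ht_total_srswor",
    "node_variances_syg",
    "variance_general",
    "variance_srswor",
    "node_variance_estimates_syg",
    "node_variance_estimates_approx",
    "variance_estimate_general",
    "variance_estimate_srswor",
    "explicit_threestage_variance",
]


def onepass_mean_ssd(values: np.ndarray) -> tuple[float, float]:
    """Mean and sum of squared deviations in one pass (Youngs-Cramer).

    Running total ``T_j`` and update
    ``ss_j = ss_{j-1} + (j y_j - T_j)^2 / (j (j-1))`` avoid the
    catastrophic cancellation of the naive ``sum(y^2) - n ybar^2``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot compute moments of an empty block")
    T = values[0]
    ss = 0.0
    for j in range(1, len(values)):
        y = values[j]
        T += y
        ss += (( (j + 1) * y - T) ** 2) / ((j + 1) * j)
    return T / len(values), ss


def _blocks(C: np.ndarray, D: np.ndarray):
    """Yield (level, parent position, children slice) level by level,
    bottom level first — the single-pass iteration order shared by all
    estimators."""
    L = int(D.shape[0] - 1)
    cs = child_starts(C, D)
    for lev in range(L - 1, -1, -1):
        for v in range(int(D[lev, 0]), int(D[lev, 1])):
            yield lev, v, slice(int(cs[v]), int(cs[v] + C[v]))


# ---------------------------------------------------------------------------
# Total estimation
# ---------------------------------------------------------------------------


def ht_total_general(
    y: np.ndarray,
    I: np.ndarray,
    P: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Expansion (Horvitz-Thompson) estimate of the total, general case.

    ``y`` holds leaf values (NaN allowed — and never read — on
    unsampled leaves).  Returns the per-node estimate array (NaN at
    unsampled nodes) and the root value, the estimate of the population
    total.
    """
    L = int(D.shape[0] - 1)
    n1 = int(D[-1, 1])
    HTE = np.full(n1, np.nan)
    leaf0 = int(D[L, 0])
    leaf_I = I[leaf0:] == 1
    y = np.asarray(y, dtype=np.float64)
    if np.any(np.isnan(y[leaf_I])):
        pos = int(np.flatnonzero(leaf_I & np.isnan(y))[0]) + 1
        raise ValueError(f"sampled elementary unit at leaf position {pos} has no y value")
    HTE[leaf0:][leaf_I] = y[leaf_I]
    for _lev, v, blk in _blocks(C, D):
        if I[v] == 0:
            continue
        sel = I[blk] == 1
        p = P[blk][sel]
        if np.any(p <= 0):
            raise ValueError(
                f"sampled child of node position {v + 1} has non-positive "
                "inclusion probability"
            )
        HTE[v] = float(np.sum(HTE[blk][sel] / p))
    return HTE, float(HTE[0])


def ht_total_srswor(
    y: np.ndarray,
    I: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Expansion estimate when every stage is SRSWOR.

    The block weight is the constant ``N_v / n_v``, so probabilities
    need not be materialized.
    """
    L = int(D.shape[0] - 1)
    n1 = int(D[-1, 1])
    HTE = np.full(n1, np.nan)
    leaf0 = int(D[L, 0])
    leaf_I = I[leaf0:] == 1
    y = np.asarray(y, dtype=np.float64)
    if np.any(np.isnan(y[leaf_I])):
        pos = int(np.flatnonzero(leaf_I & np.isnan(y))[0]) + 1
        raise ValueError(f"sampled elementary unit at leaf position {pos} has no y value")
    HTE[leaf0:][leaf_I] = y[leaf_I]
    for _lev, v, blk in _blocks(C, D):
        if I[v] == 0:
            continue
        sel = I[blk] == 1
        HTE[v] = float(C[v] / S[v] * np.sum(HTE[blk][sel]))
    return HTE, float(HTE[0])


# ---------------------------------------------------------------------------
# Theoretical variance (population quantities known)
# ---------------------------------------------------------------------------


def node_variances_syg(
    TY: np.ndarray,
    P: np.ndarray,
    store: JointProbabilityStore,
    C: np.ndarray,
    D: np.ndarray,
) -> np.ndarray:
    """Sen-Yates-Grundy node variance for every internal node.

    ``V*_v = sum_{j<k} (pi_j pi_k - pi_jk)(Y_j/pi_j - Y_k/pi_k)^2``
    over the full child block, with ``Y`` the true child totals.
    """
    n_internal = int(D[-1 if D.shape[0] == 1 else D.shape[0] - 1, 0])
    Vstar = np.zeros(n_internal, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        pi = P[blk]
        e = TY[blk] / pi
        Nb = int(C[v])
        iu, ju = np.triu_indices(Nb, k=1)
        pijk = store.block(v)
        Vstar[v] = float(np.sum((pi[iu] * pi[ju] - pijk) * (e[iu] - e[ju]) ** 2))
    return Vstar


def variance_general(
    Vstar: np.ndarray,
    P: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Theoretical sampling variance by the bottom-up recurrence
    ``V_v = V*_v + sum_{all children j} V_j / pi_j`` (full-population
    pass); the root value is the variance of the total estimator."""
    n1 = int(D[-1, 1])
    V = np.zeros(n1, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        V[v] = float(Vstar[v] + np.sum(V[blk] / P[blk]))
    return V, float(V[0])


def variance_srswor(
    TY: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Theoretical variance when every stage is SRSWOR:
    ``V_v = N^2 (1 - n/N) S^2 / n + (N/n) sum_j V_j`` with ``S^2`` the
    population variance of the child totals."""
    n1 = int(D[-1, 1])
    V = np.zeros(n1, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        Nb, nb = int(C[v]), int(S[v])
        _, ss = onepass_mean_ssd(TY[blk])
        s2 = ss / (Nb - 1) if Nb > 1 else 0.0
        V[v] = Nb * Nb * (1 - nb / Nb) * s2 / nb + Nb / nb * float(np.sum(V[blk]))
    return V, float(V[0])


# ---------------------------------------------------------------------------
# Variance estimation (sample quantities only)
# ---------------------------------------------------------------------------


def node_variance_estimates_syg(
    HTE: np.ndarray,
    P: np.ndarray,
    store: JointProbabilityStore,
    I: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> np.ndarray:
    """Sen-Yates-Grundy node variance estimate per sampled internal node:
    ``Vhat*_v = sum_{sampled j<k} (pi_j pi_k - pi_jk)/pi_jk *
    (Yhat_j/pi_j - Yhat_k/pi_k)^2``; design-unbiased when all pair
    probabilities are positive."""
    n_internal = int(D[D.shape[0] - 1, 0])
    Vstar = np.zeros(n_internal, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        if I[v] == 0:
            continue
        sel = np.flatnonzero(I[blk] == 1)
        pi = P[blk][sel]
        e = HTE[blk][sel] / pi
        m = len(sel)
        iu, ju = np.triu_indices(m, k=1)
        Nb = int(C[v])
        pijk_blk = store.block(v)
        # packed 1-based pair index for within-block positions sel+1
        a = sel[iu] + 1
        b = sel[ju] + 1
        idx = (a - 1) * Nb - a * (a + 1) // 2 + b - 1
        pijk = pijk_blk[idx]
        if np.any(pijk <= 0):
            raise ValueError(
                f"zero joint probability among sampled pair in node position "
                f"{v + 1}; use the approximate (first-order-only) estimator"
            )
        Vstar[v] = float(
            np.sum((pi[iu] * pi[ju] - pijk) / pijk * (e[iu] - e[ju]) ** 2)
        )
    return Vstar


def node_variance_estimates_approx(
    HTE: np.ndarray,
    P: np.ndarray,
    I: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> np.ndarray:
    """Approximate node variance estimate needing only first-order
    probabilities (suited to high-entropy designs):

    ``Vhat*_v = sum_j c_j / pi_j^2 (Yhat_j - Yhat*_j)^2`` with
    ``c_j = (1 - pi_j) n/(n - 1)`` and
    ``Yhat*_j = pi_j (sum_m c_m Yhat_m / pi_m) / (sum_m c_m)``.

    Census blocks (all ``pi = 1``) contribute 0; a non-census block of
    sample size 1 is rejected.
    """
    n_internal = int(D[D.shape[0] - 1, 0])
    Vstar = np.zeros(n_internal, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        if I[v] == 0:
            continue
        sel = np.flatnonzero(I[blk] == 1)
        pi = P[blk][sel]
        nb = int(S[v])
        if nb == 1:
            if np.allclose(pi, 1.0):
                continue
            raise ValueError(
                f"block of node position {v + 1} has sample size 1; the "
                "approximate variance estimator needs at least 2 draws"
            )
        c = (1.0 - pi) * nb / (nb - 1)
        csum = float(np.sum(c))
        if csum == 0.0:  # census block
            continue
        yh = HTE[blk][sel]
        ystar = pi * float(np.sum(c * yh / pi)) / csum
        Vstar[v] = float(np.sum(c / pi**2 * (yh - ystar) ** 2))
    return Vstar


def variance_estimate_general(
    Vhat_star: np.ndarray,
    P: np.ndarray,
    I: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Sampling-variance estimate by the bottom-up recurrence over
    sampled nodes only:
    ``Vhat_v = Vhat*_v + sum_{sampled j} Vhat_j / pi_j``."""
    n1 = int(D[-1, 1])
    Vhat = np.zeros(n1, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        if I[v] == 0:
            continue
        sel = I[blk] == 1
        Vhat[v] = float(Vhat_star[v] + np.sum(Vhat[blk][sel] / P[blk][sel]))
    return Vhat, float(Vhat[0])


def variance_estimate_srswor(
    y: np.ndarray,
    I: np.ndarray,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Variance estimate when every stage is SRSWOR:
    ``Vhat_v = N^2 (1 - n/N) s^2 / n + (N/n) sum_{sampled j} Vhat_j``
    with ``s^2`` the sample variance of the sampled child estimates."""
    HTE, _ = ht_total_srswor(y, I, C, D, S)
    n1 = int(D[-1, 1])
    Vhat = np.zeros(n1, dtype=np.float64)
    for _lev, v, blk in _blocks(C, D):
        if I[v] == 0:
            continue
        sel = I[blk] == 1
        Nb, nb = int(C[v]), int(S[v])
        if nb == 1 and Nb > 1:
            raise ValueError(
                f"block of node position {v + 1} has sample size 1; "
                "variance estimation needs at least 2 draws (or a census)"
            )
        vals = HTE[blk][sel]
        if nb > 1:
            _, ss = onepass_mean_ssd(vals)
            s2 = ss / (nb - 1)
        else:
            s2 = 0.0
        Vhat[v] = Nb * Nb * (1 - nb / Nb) * s2 / nb + Nb / nb * float(np.sum(Vhat[blk][sel]))
    return Vhat, float(Vhat[0])


# ---------------------------------------------------------------------------
# Explicit three-stage variance (self-weighted PPS / PPS / SRSWOR)
# ---------------------------------------------------------------------------


def explicit_threestage_variance(
    TY: np.ndarray,
    P: np.ndarray,
    store: JointProbabilityStore,
    C: np.ndarray,
    D: np.ndarray,
    S: np.ndarray,
) -> float:
    """Closed-form theoretical variance of a three-stage design with
    PPS at stages 1-2 and SRSWOR at stage 3.

    Writes out what the general recurrence composes implicitly:

    ``V = SYG(level-1 block)
        + sum_i 1/pi_1i [ SYG(children of i)
        + sum_k 1/pi_2k N_3k^2 (1 - n_3k/N_3k) S_3k^2 / n_3k ]``

    and serves as an independent cross-check of the recurrence (the
    expression's growth with the number of stages is why the recurrent
    form is the workhorse).
    """
    L = int(D.shape[0] - 1)
    if L != 3:
        raise ValueError(f"explicit formula applies to exactly 3 stages, got L={L}")
    cs = child_starts(C, D)

    def syg(v: int) -> float:
        blk = slice(int(cs[v]), int(cs[v] + C[v]))
        pi = P[blk]
        e = TY[blk] / pi
        iu, ju = np.triu_indices(int(C[v]), k=1)
        pijk = store.block(v)
        return float(np.sum((pi[iu] * pi[ju] - pijk) * (e[iu] - e[ju]) ** 2))

    total = syg(0)  # s11: first-stage SYG over the level-1 block
    for i in range(int(D[1, 0]), int(D[1, 1])):
        inner = syg(i)  # s21: second-stage SYG within PSU i
        for k in range(int(cs[i]), int(cs[i] + C[i])):
            Nb, nb = int(C[k]), int(S[k])
            blk = slice(int(cs[k]), int(cs[k] + C[k]))
            _, ss = onepass_mean_ssd(TY[blk])
            s2 = ss / (Nb - 1) if Nb > 1 else 0.0
            inner += Nb * Nb * (1 - nb / Nb) * s2 / nb / P[k]  # s22 terms
        total += inner / P[i]  # s12 assembly
    return total
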