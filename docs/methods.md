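# Methods

## Setting and notation

A multistage without-replacement design selects units down a nesting
hierarchy of `L` stages. Level 0 is the root (the whole survey); the
units at level `ℓ < L` are populations of level-`ℓ+1` units; level `L`
holds the `N` elementary units carrying the study variable `y`. Within
each selected parent `u` a fixed-size design draws `n_u` of its `N_u`
children (`1 < n_u ≤ N_u`; a census `n_u = N_u` is allowed and
contributes no variance). Two standard assumptions make the recurrences
below valid: *invariance* (the block design attached to a parent does
not depend on which earlier draws selected it) and *independence*
(blocks are drawn independently).

Each child `j` of a parent has a first-order inclusion probability
`π_j` within its block (`Σ_j π_j = n_u`), pairs have joint
probabilities `π_jk` (`Σ_j Σ_k π_jk = n_u²` with `π_jj = π_j`), and the
*selection equation* gives the overall probability
`π*_j = π_j · π*_parent`, the quantity that defines the sampling weight
`w_j = 1/π*_j`.

## Estimation recurrences

All estimation is defined bottom-up, one quantity per node:

* **Total.** `Ŷ_v = y_v` at sampled leaves, else
  `Ŷ_v = Σ_{j ∈ s_v} Ŷ_j/π_j`; the root value estimates the population
  total and is design-unbiased.
* **Theoretical variance.** `V_v = V*_v + Σ_{all children j} V_j/π_j`
  with `V_v = 0` at leaves and the fixed-size Sen–Yates–Grundy node
  term `V*_v = Σ_{j<k} (π_jπ_k − π_jk)(Y_j/π_j − Y_k/π_k)²` over *all*
  child pairs with *true* child totals. The root value is `Var(Ŷ)`
  exactly.
* **SYG variance estimator.**
  `V̂_v = V̂*_v + Σ_{j ∈ s_v} V̂_j/π_j` with
  `V̂*_v = Σ_{j<k ∈ s_v} ((π_jπ_k − π_jk)/π_jk)(Ŷ_j/π_j − Ŷ_k/π_k)²`.
  It is design-unbiased **provided every pair probability is positive**
  (see the certainty-unit limitation below).
* **Approximate estimator.** When joint probabilities are unavailable
  or unmanageable, `V̂*_v = Σ_j (c_j/π_j²)(Ŷ_j − Ŷ*_j)²` with
  `c_j = (1−π_j) n_v/(n_v−1)` and `Ŷ*_j` the `c`-weighted projection of
  the block estimates onto `π`. It needs first-order probabilities
  only, is exact (reduces to `N²(1−f)s²/n`) under equal probabilities,
  and is biased — typically downward — otherwise. It is a reasonable
  companion for high-entropy designs.

When every stage is SRSWOR the recurrences specialize: the block weight
is `N_v/n_v` and both variances collapse to the textbook form
`N²(1−n/N)S²/n` plus the propagated child terms. The package carries
both paths and tests them against each other.

For exactly three stages with PPS at stages 1–2 and SRSWOR at stage 3,
the variance is also evaluated in closed form (the nested sum
`s11 + Σ 1/π [s21 + Σ 1/π s22]`); its agreement with the recurrence to
1e-12 is a strong end-to-end check, and its bulk is the practical
argument for the recurrent formulation.

## Flat-array tree and the memory contract

The hierarchy is held in four arrays: node levels `A`, path rows `B`
(the 1-based sibling positions of a node's ancestor chain, 0-padded to
width `L+1`), children counts `C` and per-level ranges `D`. Sorting
nodes lexicographically by `(A, B)` — a stable `lexsort`; duplicate
paths are rejected, so ties cannot arise — puts every node's children
in a contiguous block at the next level, blocks in parent order.
Children block offsets are then recoverable from `C` and `D` alone
(cumulative sums within each level), so every estimator takes exactly
`(C, D, S, I, P, store, y)` and never touches `A` or `B`; tests destroy
both after construction and verify nothing changes. Internally all
arrays are 0-based and `D` rows are half-open `(start, stop)` ranges;
file formats and error messages use 1-based positions.

The random-hierarchy generator draws children counts uniformly in
`[MIN, MAX]` with an explicit stack — the only place in the package
where tree recursion is even simulated. Defaults used throughout
testing follow the standard validation configuration: `L = 3` stages
with 3–4 children per internal node, self-weighted `m = (2, 2, 2)`,
and gamma(2, 1) leaf values (positive, right-skewed — the shape of
typical abundance or workload measures).

## Stage designs

**SRSWOR** blocks use the closed forms `π = n/N`,
`π_jk = n(n−1)/(N(N−1))`.

**PPSWOR** blocks use an exact conditional (rejective) fixed-size
design: all `C(N, n)` subsets receive probability proportional to the
product of per-unit working odds, and the log-odds are calibrated by a
step-limited Newton iteration so that realized inclusion probabilities
hit the PPS targets `π_j = n x_j / Σx`. The Newton direction uses the
exact indicator covariance `Π − ππᵀ` computed from the enumeration
(singular under the fixed-size constraint, so one unit's odds are
pinned); steps are clipped to ±2 in log-odds. A plain multiplicative
odds-ratio fixed point is attractive but oscillates with period 2 on
small blocks (e.g. 2-choose-1), which is why Newton is used; it
converges to 1e-13 in at most a handful of iterations on every block
the enumeration cap admits. Units whose target is exactly 1 are forced
into every subset. Joint probabilities are read off the enumerated
distribution, hence exact. The subset enumeration is capped (default
10⁶ subsets per block); blocks beyond the cap are directed to the
approximate, first-order-only estimator path. The Hanurav–Vijayan
procedure could be slotted in as an alternative PPSWOR scheme; its
internals are deliberately out of scope.

**Self-weighted plans** take per-stage constant sizes `m_ℓ` and use PPS
probabilities proportional to descendant-leaf counts at stages
`1..L−1` and SRSWOR at stage `L`. The stage probabilities telescope, so
every leaf gets `π* = Πm_ℓ / N` — one common weight for the whole
dataset, which is what makes the collected data usable with ordinary
statistical methods. Feasibility requires `m_ℓ` at most the smallest
children count at its stage *and* all PPS targets at most 1; a plan
violating either is rejected with the offending nodes listed (including
the subtle case `m = N_block` with unequal sizes, which is not a
census but an infeasible PPS).

Joint probabilities for all blocks are packed into two flat arrays: `F`
holds per-internal-node offsets into `PP`, which concatenates each
block's strict upper triangle in lexicographic pair order (the diagonal
lives in `P`). Internal nodes are exactly the sorted positions before
the leaf level, so `F` needs no separate index.

## Sampling and Monte Carlo

Samples are drawn level-major in sorted-node order from one seeded
generator, skipping the blocks of unselected parents entirely (cost
proportional to the sample, and unselected subtrees consume no
randomness). The replication harness derives one generator per
replication from `(seed, r)`, accumulates per-node selection counts and
the running moments of `Ŷ`, `V̂_SYG` and `V̂_approx` with the
Youngs–Cramer one-pass update, and stores nothing per replication, so
reports are bit-reproducible and the loop is embarrassingly parallel in
structure. Empirical selection frequencies are compared to `π*` as
binomial z-scores with a 4-SE flag threshold.

Sums of squared deviations everywhere use the Youngs–Cramer update
`ss += (j·y_j − T_j)²/(j(j−1))`. It matches the two-pass value to
relative 1e-12 for data offsets up to roughly 10⁴ standard deviations
(the naive `Σy² − nȳ²` fails several orders of magnitude earlier);
at extreme offsets (10⁷ SDs) one-pass accuracy degrades to ~1e-10,
which bounds the regime where the 1e-12 contracts apply.

## Validation strategy

Two independent oracles check the iterative machinery:

* an **exact enumerator** of every attainable multistage sample with
  its probability (rational arithmetic when all stages are SRSWOR,
  floating point with PPSWOR blocks), from which exact expectations of
  any estimator are computed — this proves design-unbiasedness of `Ŷ`
  and of the SYG estimator on small fixtures to 1e-10, not just
  approximately by simulation;
* a **recursive reference** implementation of the same recurrences on
  child lists, matching the flat-array path to 1e-12.

The Monte Carlo protocol runs 10⁵ replications on the three-stage
self-weighted fixture and checks selection frequencies, the mean
estimate and the mean SYG estimate at 4 standard errors. Replication
counts are a package choice balancing resolution against runtime; the
assertions are formulated in standard errors so they are valid at any
`R`.

What the synthetic fixtures do *not* exercise: real frames with
thousands of PSUs (block enumeration is exercised only up to the cap),
nonresponse and frame errors, stratification, and size measures only
weakly correlated with `y`. Passing tests demonstrate the estimators'
design properties under the stated designs, not robustness to those
practical complications.

## Known limitations

* **Certainty units break SYG unbiasedness.** If a PPS target equals 1
  (unit always selected) with block sample size 2, the two non-certain
  units can never appear together (`π_jk = 0` is forced by the
  first-order probabilities, for any fixed-size scheme), and the SYG
  estimator is then structurally biased — no estimator weighting by
  `1/π_jk` can recover the missing pair term. The package computes it
  anyway when the sampled pairs all have positive probability, and
  raises only when a *sampled* pair has `π_jk = 0`; users with
  certainty units should prefer the approximate estimator or redesign
  the stage. Targets strictly above 1 are rejected outright.
* Variable-size designs (Poisson-type, needing the Horvitz–Thompson
  rather than SYG variance form), stratification, ratio/regression
  estimators and domain estimation are out of scope.
* Blocks with sample size 1 admit no unbiased variance estimate and
  are rejected (censuses aside).
* The enumeration-based PPSWOR design is meant for desk-scale blocks;
  very large PPS blocks need a sequential scheme (e.g.
  Hanurav–Vijayan) plugged in alongside the approximate estimator.
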