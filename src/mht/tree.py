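"""Flat-array tree representation of nested sampling units.

Multistage sampling nests populations: the units sampled at stage ``l``
are themselves populations sampled at stage ``l+1``.  The nesting is a
tree whose root (level 0) is the whole survey, whose leaves (level L)
are the elementary units carrying the variable of interest, and whose
intermediate levels are the primary/secondary/... sampling units.

Instead of a pointer-based tree, everything here is a set of dense,
sorted arrays:

* ``A`` -- level of each node (0..L),
* ``B`` -- path matrix: row ``v`` holds the 1-based sibling positions of
  ``v``'s ancestor chain, right-padded with 0 to width ``L+1``,
* ``C`` -- number of children of each node (0 at the leaves),
* ``D`` -- per-level ``(start, stop)`` node ranges (0-based, half-open).

Nodes are sorted lexicographically by ``(A, B)``, which makes the
children of every node a contiguous block at the next level, with
blocks appearing in parent order.  Every statistical computation
downstream is a single pass over these blocks and needs only ``C`` and
``D``: the level and path arrays ``A``/``B`` are required solely to
build ``C`` and ``D`` and may be released afterwards.

All arrays are 0-based internally; file formats and error messages use
1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatasetArrays",
    "Tree",
    "dataset_to_tree",
    "tree_to_dataset",
    "build_reorder_index",
    "reorder_in_place",
    "build_level_access",
    "count_children",
    "child_starts",
    "generate_random_tree",
    "random_tree",
]


# ---------------------------------------------------------------------------
# Dataset representation (level-delimited label / parent-label arrays)
# ---------------------------------------------------------------------------


@dataclass
class DatasetArrays:
    """Level-delimited representation of the unit hierarchy.

    ``N`` concatenates the unit labels level by level (level 0 first);
    ``O`` holds, for each entry of ``N``, the label of its parent unit
    (sentinel 0 for the root); ``M`` is the fencepost array: the level-l
    segment of ``N``/``O`` is ``N[M[l]:M[l+1]]``.

    Labels are integers, unique within a level but not necessarily
    across levels.
    """

    M: np.ndarray
    N: np.ndarray
    O: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        self.O = np.asarray(self.O, dtype=np.int64)

    @property
    def L(self) -> int:
        return len(self.M) - 2

    def level_segment(self, level: int) -> slice:
        return slice(int(self.M[level]), int(self.M[level + 1]))

    def validate(self) -> None:
        if len(self.M) < 2:
            raise ValueError("M must contain at least two fencepost entries")
        if self.M[0] != 0 or self.M[-1] != len(self.N):
            raise ValueError("M fenceposts must span N exactly")
        if np.any(np.diff(self.M) <= 0):
            raise ValueError("every level segment must be non-empty")
        if len(self.N) != len(self.O):
            raise ValueError("N and O must have equal length")
        if self.M[1] - self.M[0] != 1:
            raise ValueError("level-0 segment must contain exactly the root")
        if self.O[0] != 0:
            raise ValueError("root parent label must be the sentinel 0")
        for lev in range(self.L + 1):
            seg = self.level_segment(lev)
            labels = self.N[seg]
            if len(np.unique(labels)) != len(labels):
                dup = labels[np.argmax(np.bincount(labels) > 1)]
                raise ValueError(
                    f"duplicate label {int(dup)} at level {lev}"
                )
            if lev >= 1:
                parent_labels = set(self.N[self.level_segment(lev - 1)].tolist())
                for lab, par in zip(labels, self.O[seg]):
                    if int(par) not in parent_labels:
                        raise ValueError(
                            f"orphan record: unit {int(lab)} at level {lev} "
                            f"references parent label {int(par)} absent from "
                            f"level {lev - 1}"
                        )


# ---------------------------------------------------------------------------
# Sorted tree container
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Sorted flat-array tree.

    ``A`` and ``B`` are retained only for structural conversions; the
    estimator layer receives ``(C, D)`` and never touches them, so a
    caller may set them to ``None`` (``release_paths``) once the tree is
    built.  ``labels`` records, per sorted node, the unit label used in
    the on-disk dataset (defaults to the within-level 1-based position).
    """

    L: int
    A: np.ndarray | None
    B: np.ndarray | None
    C: np.ndarray
    D: np.ndarray
    labels: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.D[-1, 1])

    @property
    def n_leaves(self) -> int:
        return int(self.D[self.L, 1] - self.D[self.L, 0])

    def level_slice(self, level: int) -> slice:
        return slice(int(self.D[level, 0]), int(self.D[level, 1]))

    def level_count(self, level: int) -> int:
        return int(self.D[level, 1] - self.D[level, 0])

    @property
    def n_internal(self) -> int:
        return int(self.D[self.L, 0])

    def release_paths(self) -> None:
        """Drop A and B; only C and D are needed for statistics."""
        self.A = None
        self.B = None

    def validate(self) -> None:
        n1 = self.n_nodes
        if len(self.C) != n1:
            raise ValueError("C length must equal the node count")
        if self.D.shape != (self.L + 1, 2):
            raise ValueError("D must have one (start, stop) row per level")
        if self.D[0, 0] != 0 or self.D[0, 1] != 1:
            raise ValueError("level 0 must contain exactly the root")
        if np.any(self.D[1:, 0] != self.D[:-1, 1]):
            raise ValueError("level ranges must partition 1..N1 without gaps")
        leaves = self.level_slice(self.L)
        if np.any(self.C[leaves] != 0):
            raise ValueError("leaf nodes must have zero children")
        for lev in range(self.L):
            seg = self.level_slice(lev)
            if np.any(self.C[seg] < 1):
                pos = int(np.flatnonzero(self.C[seg] < 1)[0]) + 1
                raise ValueError(
                    f"internal node at level {lev}, position {pos} has no children"
                )
            if int(self.C[seg].sum()) != self.level_count(lev + 1):
                raise ValueError(
                    f"children counts at level {lev} do not sum to the "
                    f"level-{lev + 1} node count"
                )

    @classmethod
    def from_unsorted(
        cls,
        A: np.ndarray,
        B: np.ndarray,
        labels: np.ndarray | None = None,
    ) -> "Tree":
        """Sort ``(A, B)`` and derive ``C`` and ``D``."""
        A = np.asarray(A, dtype=np.int64).copy()
        B = np.asarray(B, dtype=np.int64).copy()
        T = build_reorder_index(A, B)
        reorder_in_place(A, T)
        reorder_in_place(B, T, 0, B.shape[1] - 1)
        if labels is not None:
            labels = np.asarray(labels, dtype=np.int64).copy()
            reorder_in_place(labels, T)
        D = build_level_access(A)
        C = count_children(B, D)
        L = int(A[-1])
        tree = cls(L=L, A=A, B=B, C=C, D=D, labels=labels)
        tree.validate()
        return tree

    @classmethod
    def from_dataset(cls, ds: DatasetArrays) -> "Tree":
        A, B = dataset_to_tree(ds)
        return cls.from_unsorted(A, B, labels=ds.N)

    def to_dataset(self) -> DatasetArrays:
        if self.A is None or self.B is None:
            raise ValueError("paths released; dataset conversion needs A and B")
        return tree_to_dataset(self.A, self.B, self.D, labels=self.labels)


# ---------------------------------------------------------------------------
# Conversions dataset <-> (A, B)
# ---------------------------------------------------------------------------


def dataset_to_tree(ds: DatasetArrays) -> tuple[np.ndarray, np.ndarray]:
    """Convert a level-delimited dataset into (unsorted) level/path arrays.

    Each record becomes one node; its path row is its parent's path with
    the node's 1-based position among that parent's children appended,
    remaining cells 0-filled.  Raises a structural error for orphan
    records (parent label absent from the previous level).
    """
    ds.validate()
    L = ds.L
    n1 = len(ds.N)
    A = np.zeros(n1, dtype=np.int64)
    B = np.zeros((n1, L + 1), dtype=np.int64)
    # per level: label -> row index of that unit
    prev_rows: dict[int, int] = {}
    child_counter: dict[int, int] = {}
    for lev in range(L + 1):
        seg = ds.level_segment(lev)
        rows: dict[int, int] = {}
        child_counter = dict.fromkeys(prev_rows.values(), 0)
        for idx in range(seg.start, seg.stop):
            A[idx] = lev
            lab = int(ds.N[idx])
            rows[lab] = idx
            if lev >= 1:
                par = int(ds.O[idx])
                if par not in prev_rows:
                    raise ValueError(
                        f"orphan record: unit {lab} at level {lev} references "
                        f"parent label {par} absent from level {lev - 1}"
                    )
                prow = prev_rows[par]
                child_counter[prow] += 1
                B[idx, : lev - 1] = B[prow, : lev - 1]
                B[idx, lev - 1] = child_counter[prow]
        prev_rows = rows
    return A, B


def tree_to_dataset(
    A: np.ndarray,
    B: np.ndarray,
    D: np.ndarray,
    labels: np.ndarray | None = None,
) -> DatasetArrays:
    """Inverse of :func:`dataset_to_tree` on sorted input.

    Unit labels default to 1-based within-level positions; the parent
    label of a node is its parent's label.  Round-tripping through
    :func:`dataset_to_tree` and re-sorting is the identity on (A, B).
    """
    A = np.asarray(A)
    B = np.asarray(B)
    if np.any(np.diff(A) < 0):
        raise ValueError("tree arrays must be sorted before conversion")
    L = int(D.shape[0] - 1)
    n1 = int(D[-1, 1])
    if labels is None:
        labels = np.concatenate(
            [np.arange(1, D[lev, 1] - D[lev, 0] + 1) for lev in range(L + 1)]
        ).astype(np.int64)
    N_arr = np.asarray(labels, dtype=np.int64).copy()
    O_arr = np.zeros(n1, dtype=np.int64)
    for lev in range(1, L + 1):
        start, stop = int(D[lev, 0]), int(D[lev, 1])
        pstart, pstop = int(D[lev - 1, 0]), int(D[lev - 1, 1])
        p = pstart
        for v in range(start, stop):
            # advance the parent pointer until the path prefix matches
            while p < pstop and not np.array_equal(
                B[p, : lev - 1], B[v, : lev - 1]
            ):
                p += 1
            if p == pstop:
                raise ValueError(
                    f"node at level {lev}, position {v - start + 1} has no "
                    f"matching parent path"
                )
            O_arr[v] = N_arr[p]
    M = np.concatenate(([0], D[:, 1])).astype(np.int64)
    ds = DatasetArrays(M=M, N=N_arr, O=O_arr)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Sorting and level access
# ---------------------------------------------------------------------------


def build_reorder_index(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Permutation sorting rows lexicographically by (level, path), stable."""
    A = np.asarray(A)
    B = np.asarray(B)
    if len(A) != len(B):
        raise ValueError("A and B must have the same number of rows")
    keys = tuple(B[:, k] for k in range(B.shape[1] - 1, -1, -1)) + (A,)
    return np.lexsort(keys)


def reorder_in_place(
    G: np.ndarray,
    T: np.ndarray,
    LB: int = 0,
    UB: int = -1,
) -> None:
    """Permute the rows of ``G`` so that new row ``r`` is old row ``T[r]``.

    ``UB < LB`` signals that ``G`` is one-dimensional (the column bounds
    are then ignored); otherwise only columns ``LB..UB`` (inclusive) are
    permuted.
    """
    T = np.asarray(T)
    if len(T) != len(G):
        raise ValueError("permutation length must match the number of rows")
    if G.ndim == 1 or UB < LB:
        G[:] = G[T]
    else:
        G[:, LB : UB + 1] = G[T, LB : UB + 1]


def build_level_access(A: np.ndarray) -> np.ndarray:
    """Per-level (start, stop) ranges of a sorted level array.

    ``D[l] = (start, stop)`` is a 0-based half-open range; the final stop
    equals the total node count.
    """
    A = np.asarray(A)
    if np.any(np.diff(A) < 0):
        raise ValueError("level array must be sorted nondecreasing")
    if A[0] != 0:
        raise ValueError("sorted level array must start at the root level 0")
    L = int(A[-1])
    D = np.zeros((L + 1, 2), dtype=np.int64)
    bounds = np.searchsorted(A, np.arange(L + 2))
    D[:, 0] = bounds[:-1]
    D[:, 1] = bounds[1:]
    return D


def count_children(B: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Children counts for a sorted tree.

    A node's children are the next-level nodes whose path prefix equals
    the node's path; after sorting they form a contiguous block.
    """
    B = np.asarray(B)
    L = int(D.shape[0] - 1)
    n1 = int(D[-1, 1])
    C = np.zeros(n1, dtype=np.int64)
    for lev in range(1, L + 1):
        start, stop = int(D[lev, 0]), int(D[lev, 1])
        pstart, pstop = int(D[lev - 1, 0]), int(D[lev - 1, 1])
        p = pstart
        for v in range(start, stop):
            while p < pstop and not np.array_equal(
                B[p, : lev - 1], B[v, : lev - 1]
            ):
                p += 1
            if p == pstop:
                raise ValueError(
                    f"node at level {lev}, position {v - start + 1} has no "
                    f"matching parent path"
                )
            C[p] += 1
    return C


def child_starts(C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Start position of each internal node's children block.

    Children of the internal node at sorted position ``v`` occupy
    ``cs[v] : cs[v] + C[v]`` at the next level.  Derived from ``C`` and
    ``D`` alone, honouring the contract that paths are not needed after
    tree construction.
    """
    L = int(D.shape[0] - 1)
    n_internal = int(D[L, 0])
    cs = np.zeros(n_internal, dtype=np.int64)
    for lev in range(L):
        start, stop = int(D[lev, 0]), int(D[lev, 1])
        offs = np.cumsum(C[start:stop])
        cs[start:stop] = int(D[lev + 1, 0]) + np.concatenate(([0], offs[:-1]))
    return cs


# ---------------------------------------------------------------------------
# Random hierarchy generation
# ---------------------------------------------------------------------------


def generate_random_tree(
    L: int,
    MIN: int,
    MAX: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Generate a random hierarchy of sampling units on ``L`` levels.

    Every internal node receives a children count drawn uniformly in
    ``[MIN, MAX]``.  Returns ``(N1, A, B, C)`` in creation (depth-first)
    order; sort with :meth:`Tree.from_unsorted` before statistical use.
    This is the only routine that simulates tree recursion (with an
    explicit stack); everything downstream is purely iterative.
    """
    if L < 1:
        raise ValueError("number of stages L must be >= 1")
    if not (1 <= MIN <= MAX):
        raise ValueError("children bounds must satisfy 1 <= MIN <= MAX")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A_list: list[int] = []
    B_list: list[np.ndarray] = []
    C_list: list[int] = []
    root_path = np.zeros(L + 1, dtype=np.int64)
    # stack of (level, path); children pushed in reverse for left-to-right DFS
    stack: list[tuple[int, np.ndarray]] = [(0, root_path)]
    while stack:
        lev, path = stack.pop()
        A_list.append(lev)
        B_list.append(path)
        if lev < L:
            k = int(rng.integers(MIN, MAX + 1))
            C_list.append(k)
            for pos in range(k, 0, -1):
                child = path.copy()
                child[lev] = pos
                stack.append((lev + 1, child))
        else:
            C_list.append(0)
    return (
        len(A_list),
        np.asarray(A_list, dtype=np.int64),
        np.asarray(B_list, dtype=np.int64),
        np.asarray(C_list, dtype=np.int64),
    )


def random_tree(
    L: int,
    MIN: int,
    MAX: int,
    seed: int | np.random.Generator | None = None,
) -> Tree:
    """Convenience wrapper: generate, sort and validate a random tree."""
    _, A, B, _ = generate_random_tree(L, MIN, MAX, seed)
    return Tree.from_unsorted(A, B)
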