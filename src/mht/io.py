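"""File formats: hierarchy/variable/indicator CSV and JSON reports.

The hierarchy is exchanged as a plain CSV with columns
``level,label,parent_label`` (root row ``0,1,0``), labels being
integers unique within a level.  Leaf variables are CSV keyed by the
level-L labels.  Reports are JSON with deterministic key order; every
report echoes the seed and configuration that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import (
    PPSWOR,
    SRSWOR,
    DesignPlan,
    StageDesignSpec,
    build_plan,
    build_selfweighted_plan,
)
from .tree import DatasetArrays, Tree

__all__ = [
    "read_hierarchy_csv",
    "write_hierarchy_csv",
    "read_leaf_values_csv",
    "read_indicator_csv",
    "write_indicator_csv",
    "read_design_config",
    "plan_from_config",
    "write_report",
]

_HIER_COLS = ["level", "label", "parent_label"]


def read_hierarchy_csv(path: str | Path) -> DatasetArrays:
    """Read a ``level,label,parent_label`` hierarchy into level-delimited
    arrays, validating structure (line numbers in errors are 1-based and
    include the header)."""
    df = pd.read_csv(path)
    if list(df.columns) != _HIER_COLS:
        raise ValueError(
            f"{path}: expected header {','.join(_HIER_COLS)}, got {','.join(df.columns)}"
        )
    for col in _HIER_COLS:
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}:{line}: non-integer value in column {col!r}")
    df = df.sort_values("level", kind="stable")
    levels = df["level"].to_numpy()
    if levels[0] != 0:
        raise ValueError(f"{path}: missing root row (level 0)")
    L = int(levels[-1])
    expected = np.arange(L + 1)
    present = np.unique(levels)
    if not np.array_equal(present, expected):
        raise ValueError(f"{path}: levels must be contiguous 0..{L}")
    M = np.concatenate(([0], np.searchsorted(levels, expected + 1)))
    dup = df.duplicated(subset=["level", "label"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (level, label) = ({int(row['level'])}, {int(row['label'])})"
        )
    ds = DatasetArrays(
        M=M,
        N=df["label"].to_numpy(np.int64),
        O=df["parent_label"].to_numpy(np.int64),
    )
    ds.validate()
    return ds


def write_hierarchy_csv(ds: DatasetArrays, path: str | Path) -> None:
    levels = np.repeat(np.arange(ds.L + 1), np.diff(ds.M))
    pd.DataFrame({"level": levels, "label": ds.N, "parent_label": ds.O}).to_csv(
        path, index=False
    )


def _leaf_label_map(tree: Tree) -> dict[int, int]:
    """Leaf label -> 0-based leaf position (within the leaf level)."""
    if tree.labels is None:
        leaf = tree.level_slice(tree.L)
        return {pos + 1: pos for pos in range(leaf.stop - leaf.start)}
    leaf = tree.level_slice(tree.L)
    return {int(lab): pos for pos, lab in enumerate(tree.labels[leaf])}


def read_leaf_values_csv(
    path: str | Path, tree: Tree
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read ``label,y[,x]`` keyed by elementary-unit labels.

    Returns per-leaf arrays in sorted leaf order; leaves absent from the
    file get NaN (legitimate for unsampled units in estimation runs).
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["label", "y"]:
        raise ValueError(f"{path}: expected header label,y[,x]")
    lab_map = _leaf_label_map(tree)
    y = np.full(tree.n_leaves, np.nan)
    x = np.full(tree.n_leaves, np.nan) if "x" in df.columns else None
    for i, row in df.iterrows():
        lab = int(row["label"])
        if lab not in lab_map:
            raise ValueError(f"{path}:{i + 2}: unknown elementary-unit label {lab}")
        y[lab_map[lab]] = float(row["y"])
        if x is not None:
            x[lab_map[lab]] = float(row["x"])
    return y, x


def write_indicator_csv(tree: Tree, I: np.ndarray, path: str | Path) -> None:
    levels = np.concatenate(
        [np.full(tree.level_count(l), l) for l in range(tree.L + 1)]
    )
    labels = (
        tree.labels
        if tree.labels is not None
        else np.concatenate(
            [np.arange(1, tree.level_count(l) + 1) for l in range(tree.L + 1)]
        )
    )
    pd.DataFrame({"level": levels, "label": labels, "indicator": I}).to_csv(
        path, index=False
    )


def read_indicator_csv(path: str | Path, tree: Tree) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["level", "label", "indicator"]:
        raise ValueError(f"{path}: expected header level,label,indicator")
    labels = (
        tree.labels
        if tree.labels is not None
        else np.concatenate(
            [np.arange(1, tree.level_count(l) + 1) for l in range(tree.L + 1)]
        )
    )
    key = {}
    pos = 0
    for lev in range(tree.L + 1):
        for _ in range(tree.level_count(lev)):
            key[(lev, int(labels[pos]))] = pos
            pos += 1
    I = np.zeros(tree.n_nodes, dtype=np.int64)
    for i, row in df.iterrows():
        k = (int(row["level"]), int(row["label"]))
        if k not in key:
            raise ValueError(f"{path}:{i + 2}: unknown unit {k}")
        I[key[k]] = int(row["indicator"])
    return I


def read_design_config(path: str | Path) -> dict:
    """Design configuration from JSON or YAML.

    Either ``{"stages": [{"kind": "srswor"|"ppswor", "n": int}, ...]}``
    (one entry per stage, outermost first) or
    ``{"selfweighted": {"m": [m1, ..., mL]}}``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict) or not ({"stages", "selfweighted"} & cfg.keys()):
        raise ValueError(f"{path}: config must define 'stages' or 'selfweighted'")
    return cfg


def plan_from_config(
    tree: Tree, cfg: dict, x: np.ndarray | None = None
) -> tuple[StageDesignSpec, DesignPlan]:
    if "selfweighted" in cfg:
        m = [int(v) for v in cfg["selfweighted"]["m"]]
        spec, _, plan = build_selfweighted_plan(tree, m)
        return spec, plan
    stages = cfg["stages"]
    kinds = [str(s["kind"]).lower() for s in stages]
    n = [int(s["n"]) for s in stages]
    spec = StageDesignSpec.per_stage(tree, kinds, n, x=x)
    plan = build_plan(tree, spec)
    return spec, plan


def write_report(report: dict, path: str | Path) -> None:
    """Write a JSON report with deterministic key order."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
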