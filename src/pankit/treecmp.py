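"""Tree-to-tree distances and representative-gene selection.

Implements three distances on unrooted leaf-labelled trees with identical
leaf sets — Robinson–Foulds (symmetric difference of nontrivial
bipartitions), matching split (exact minimum-weight perfect matching
between the two split sets, Bogdanowicz–Giaro), and quartet distance
(explicit enumeration of all C(n,4) four-leaf subsets) — and ranks gene
trees against a reference to select the top fraction that mirror it most
closely.

Splits are encoded as leaf-set bitmasks over a fixed leaf order,
normalized to the side *not* containing the first leaf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skbio import TreeNode

__all__ = [
    "split_set",
    "rf_distance",
    "matching_split_distance",
    "quartet_distance",
    "quartet_comparison",
    "TreeDistanceReport",
    "select_representatives",
]


def _leaf_names(tree: TreeNode) -> list[str]:
    return sorted(t.name for t in tree.tips())


def split_set(tree: TreeNode, leaf_order: list[str] | None = None) -> set[int]:
    """Nontrivial bipartitions of an unrooted tree as leaf bitmasks.

    Each split is stored as the mask of the side not containing
    ``leaf_order[0]``; trivial splits (a single leaf on either side) are
    dropped, and the rooted-tree artifact of the two root-child edges
    inducing the same bipartition collapses in the set.
    """
    if leaf_order is None:
        leaf_order = _leaf_names(tree)
    idx = {name: i for i, name in enumerate(leaf_order)}
    n = len(leaf_order)
    full = (1 << n) - 1
    splits: set[int] = set()

    def mask_of(node: TreeNode) -> int:
        if node.is_tip():
            return 1 << idx[node.name]
        m = 0
        for child in node.children:
            m |= mask_of(child)
        if node.parent is not None:
            norm = (full ^ m) if (m & 1) else m
            c = bin(norm).count("1")
            if 2 <= c <= n - 2:
                splits.add(norm)
        return m

    mask_of(tree)
    return splits


def _common_leaves(t1: TreeNode, t2: TreeNode) -> list[str]:
    l1, l2 = _leaf_names(t1), _leaf_names(t2)
    if l1 != l2:
        raise ValueError("trees must share an identical leaf set")
    return l1


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds distance: |S1 Δ S2| over nontrivial splits."""
    order = _common_leaves(t1, t2)
    return len(split_set(t1, order) ^ split_set(t2, order))


def _split_pair_cost(a: int, b: int, full: int) -> int:
    """Minimal leaf disagreement between bipartitions a|a' and b|b'."""
    ca, cb = full ^ a, full ^ b
    h1 = bin(a & cb).count("1") + bin(ca & b).count("1")
    h2 = bin(a & b).count("1") + bin(ca & cb).count("1")
    return min(h1, h2)


def matching_split_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Matching split distance, solved exactly by the Hungarian algorithm.

    The smaller split set is padded with "null" splits; matching a real
    split A|B to a null costs min(|A|, |B|), and matching two splits costs
    the smaller of the two ways of pairing their sides.
    """
    order = _common_leaves(t1, t2)
    n = len(order)
    full = (1 << n) - 1
    s1 = sorted(split_set(t1, order))
    s2 = sorted(split_set(t2, order))
    m = max(len(s1), len(s2))
    if m == 0:
        return 0
    cost = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(m):
            if i < len(s1) and j < len(s2):
                cost[i, j] = _split_pair_cost(s1[i], s2[j], full)
            elif i < len(s1):
                k = bin(s1[i]).count("1")
                cost[i, j] = min(k, n - k)
            elif j < len(s2):
                k = bin(s2[j]).count("1")
                cost[i, j] = min(k, n - k)
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def _topological_distances(tree: TreeNode, order: list[str]) -> np.ndarray:
    t = tree.copy()
    for node in t.traverse(include_self=False):
        node.length = 1.0
    dm = t.tip_tip_distances()
    ids = list(dm.ids)
    perm = [ids.index(name) for name in order]
    return dm.data[np.ix_(perm, perm)]


def _quartet_codes(D: np.ndarray, quartets: np.ndarray) -> np.ndarray:
    """Induced topology code per 4-leaf subset: 1/2/3 for the pairing with
    the strictly smallest topological path-length sum (four-point
    condition), 0 when the quartet is unresolved (star)."""
    a, b, c, d = quartets.T
    sums = np.stack(
        [D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]], axis=1
    )
    mins = sums.min(axis=1, keepdims=True)
    is_min = sums == mins
    codes = np.where(is_min.sum(axis=1) == 1, sums.argmin(axis=1) + 1, 0)
    return codes


def quartet_comparison(t1: TreeNode, t2: TreeNode) -> dict[str, int]:
    """Per-category quartet counts between two trees.

    An unresolved quartet differs from any resolved one and matches
    another unresolved one; categories sum to C(n, 4).
    """
    order = _common_leaves(t1, t2)
    n = len(order)
    if n < 4:
        raise ValueError("quartet distance requires >= 4 leaves")
    quartets = np.array(list(combinations(range(n), 4)), dtype=np.intp)
    c1 = _quartet_codes(_topological_distances(t1, order), quartets)
    c2 = _quartet_codes(_topological_distances(t2, order), quartets)
    both_res = (c1 > 0) & (c2 > 0)
    return {
        "resolved_same": int(((c1 == c2) & both_res).sum()),
        "resolved_different": int((c1 != c2)[both_res].sum()),
        "one_unresolved": int(((c1 == 0) ^ (c2 == 0)).sum()),
        "both_unresolved": int(((c1 == 0) & (c2 == 0)).sum()),
        "total": len(quartets),
    }


def quartet_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Number of 4-leaf subsets whose induced topology differs."""
    c = quartet_comparison(t1, t2)
    return c["resolved_different"] + c["one_unresolved"]


@dataclass
class TreeDistanceReport:
    """Per-gene distances to the reference tree and the selection."""

    table: pd.DataFrame          # index: gene/cluster id
    top_frac: float
    metric: str

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def select_representatives(
    gene_trees: Mapping[str, TreeNode],
    reference: TreeNode,
    top_frac: float = 0.05,
    metric: str = "both",
) -> TreeDistanceReport:
    """Rank gene trees by similarity to the reference; keep the top fraction.

    Each eligible gene tree (leaf set identical to the reference's) gets
    its RF, matching-split and quartet distances; genes are ranked by
    matching split and by quartet (average ranks on ties) and combined by
    rank sum (``metric='both'``) or a single metric's rank.  The selected
    set is the ceil(top_frac · n) best by combined rank, with boundary
    ties included.  Genes whose trees lack leaves are excluded with a
    warning.
    """
    if not (0.0 < top_frac <= 1.0):
        raise ValueError("top_frac must lie in (0, 1]")
    if metric not in ("both", "ms", "quartet"):
        raise ValueError("metric must be 'both', 'ms' or 'quartet'")
    ref_leaves = _leaf_names(reference)
    rows = {}
    for gene, tree in gene_trees.items():
        if _leaf_names(tree) != ref_leaves:
            warnings.warn(f"gene {gene}: leaf set differs from reference; excluded")
            continue
        rows[gene] = {
            "rf": rf_distance(tree, reference),
            "ms": matching_split_distance(tree, reference),
            "quartet": quartet_distance(tree, reference),
        }
    if not rows:
        raise ValueError("no gene tree shares the reference leaf set")
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df["rank_ms"] = df["ms"].rank(method="average")
    df["rank_quartet"] = df["quartet"].rank(method="average")
    if metric == "both":
        df["combined_rank"] = df["rank_ms"] + df["rank_quartet"]
    elif metric == "ms":
        df["combined_rank"] = df["rank_ms"]
    else:
        df["combined_rank"] = df["rank_quartet"]
    k = math.ceil(top_frac * len(df))
    threshold = df["combined_rank"].nsmallest(k).iloc[-1]
    df["selected"] = df["combined_rank"] <= threshold
    return TreeDistanceReport(df, top_frac, metric)
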