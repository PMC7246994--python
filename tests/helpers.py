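"""Independent oracles and random generators shared by the test suite.

Everything here is deliberately implemented by a different route than the
package code it checks: exhaustive enumeration instead of dynamic
programming or the Hungarian algorithm, set arithmetic instead of
bitmasks, explicit combinatorics instead of scipy distributions.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from skbio import TreeNode

# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------


def random_unrooted_tree(names: list[str], rng: np.random.Generator,
                         min_len: float = 0.1, max_len: float = 1.0) -> TreeNode:
    """Random binary tree with a trifurcating root and uniform branch lengths."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(min_len, max_len))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode(children=[a, b], length=float(rng.uniform(min_len, max_len)))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root


def random_ultrametric_tree(names: list[str], rng: np.random.Generator,
                            height: float = 10.0) -> TreeNode:
    """Random rooted binary ultrametric tree (all leaves at distance
    ``height`` from the root, internal heights strictly decreasing)."""

    def build(sub: list[str], h: float) -> TreeNode:
        if len(sub) == 1:
            return TreeNode(name=sub[0])          # leaf: height 0
        k = int(rng.integers(1, len(sub)))
        hl = float(rng.uniform(0.2 * h, 0.8 * h)) if k > 1 else 0.0
        hr = float(rng.uniform(0.2 * h, 0.8 * h)) if len(sub) - k > 1 else 0.0
        left = build(sub[:k], hl)
        right = build(sub[k:], hr)
        left.length = h - hl
        right.length = h - hr
        return TreeNode(children=[left, right])

    return build(list(names), height)


def tree_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    dm = tree.tip_tip_distances()
    ids = sorted(dm.ids)
    perm = [list(dm.ids).index(i) for i in ids]
    return ids, dm.data[np.ix_(perm, perm)]


# ---------------------------------------------------------------------------
# splits as frozensets (independent of the package's bitmask encoding)
# ---------------------------------------------------------------------------


def frozenset_splits(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions, each as the frozenset of the side not
    containing the lexicographically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    n = len(leaves)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def brute_force_matching_split(t1: TreeNode, t2: TreeNode) -> int:
    """Minimum total cost over all split matchings, by factorial enumeration."""
    leaves = sorted(t.name for t in t1.tips())
    full = set(leaves)
    s1 = sorted(frozenset_splits(t1), key=sorted)
    s2 = sorted(frozenset_splits(t2), key=sorted)
    m = max(len(s1), len(s2))
    if m == 0:
        return 0
    s1 = list(s1) + [None] * (m - len(s1))
    s2 = list(s2) + [None] * (m - len(s2))

    def cost(x, y):
        if x is None and y is None:
            return 0
        if x is None or y is None:
            s = x if x is not None else y
            return min(len(s), len(full) - len(s))
        a, b = set(x), full - set(x)
        c, d = set(y), full - set(y)
        return min(len(a & d) + len(b & c), len(a & c) + len(b & d))

    best = None
    for perm in permutations(range(m)):
        total = sum(cost(s1[i], s2[perm[i]]) for i in range(m))
        if best is None or total < best:
            best = total
    return best


def split_quartet_topology(splits: set[frozenset], leaves: list[str],
                           quartet: tuple[str, str, str, str]):
    """Induced quartet topology via split containment: (x,y) vs (z,w) iff
    some nontrivial split has x,y on one side and z,w on the other.
    Returns a frozenset pairing or None when unresolved."""
    a, b, c, d = quartet
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    full = set(leaves)
    for (x, y), (z, w) in pairings:
        for s in splits:
            comp = full - s
            if ({x, y} <= s and {z, w} <= comp) or ({x, y} <= comp and {z, w} <= s):
                return frozenset([frozenset([x, y]), frozenset([z, w])])
    return None


def brute_force_quartet_distance(t1: TreeNode, t2: TreeNode) -> int:
    leaves = sorted(t.name for t in t1.tips())
    s1, s2 = frozenset_splits(t1), frozenset_splits(t2)
    dist = 0
    for quartet in combinations(leaves, 4):
        q1 = split_quartet_topology(s1, leaves, quartet)
        q2 = split_quartet_topology(s2, leaves, quartet)
        if q1 != q2:
            dist += 1
    return dist


def all_unrooted_topologies(names: list[str]) -> list[str]:
    """All unrooted binary topologies on 4 or 5 leaves as newick strings."""
    if len(names) == 4:
        a, b, c, d = names
        return [
            f"(({a},{b}),{c},{d});",
            f"(({a},{c}),{b},{d});",
            f"(({a},{d}),{b},{c});",
        ]
    if len(names) == 5:
        out = []
        for mid in names:
            rest = [n for n in names if n != mid]
            a = rest[0]
            for b in rest[1:]:
                c, d = [n for n in rest[1:] if n != b]
                out.append(f"(({a},{b}),{mid},({c},{d}));")
        return out
    raise ValueError("only 4 or 5 leaves supported")


# ---------------------------------------------------------------------------
# alignment oracles
# ---------------------------------------------------------------------------


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)


def alignment_score(ra: str, rb: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    s = 0.0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            s += gap
        elif x == y:
            s += match
        else:
            s += mismatch
    return s


def optimal_alignment_identities(a: str, b: str, **scores) -> set[float]:
    """Identity (%) of every maximum-score global alignment."""
    best, idents = None, set()
    for ra, rb in enumerate_global_alignments(a, b):
        s = alignment_score(ra, rb, **scores)
        matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
        ident = 100.0 * matches / len(ra)
        if best is None or s > best:
            best, idents = s, {ident}
        elif s == best:
            idents.add(ident)
    return idents


# ---------------------------------------------------------------------------
# Jukes–Cantor pattern oracle for tiny trees
# ---------------------------------------------------------------------------


def _jc_transition(t: float) -> np.ndarray:
    s = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    off = (1.0 - s) / 3.0
    return np.full((4, 4), off) + np.eye(4) * (s - off)


def jc_snp_column_probability(tree: TreeNode) -> float:
    """Exact probability that one alignment column evolved on ``tree``
    under Jukes–Cantor is a consensus SNP column: polymorphic with a
    unique plurality base.  Enumerates every leaf pattern (tiny trees
    only) with Felsenstein-style conditional likelihoods."""
    from itertools import product

    leaves = [t.name for t in tree.tips()]

    def conditional(node, pattern):
        if node.is_tip():
            v = np.zeros(4)
            v[pattern[node.name]] = 1.0
            return v
        out = np.ones(4)
        for child in node.children:
            T = _jc_transition(child.length or 0.0)
            out = out * (T @ conditional(child, pattern))
        return out

    p_snp = 0.0
    for bases in product(range(4), repeat=len(leaves)):
        pattern = dict(zip(leaves, bases))
        counts = np.bincount(bases, minlength=4)
        top = np.sort(counts)[::-1]
        is_snp = (top[0] < len(leaves)) and (top[0] > top[1])
        if is_snp:
            p_snp += 0.25 * conditional(tree, pattern).sum()
    return p_snp


# ---------------------------------------------------------------------------
# hypergeometric oracle
# ---------------------------------------------------------------------------


def brute_force_hypergeom_upper(background: set, hits: set, drawn: set) -> float:
    """P(overlap >= |drawn ∩ hits|) by enumerating every equal-size draw."""
    k_obs = len(drawn & hits)
    n_draw = len(drawn)
    count = 0
    total = 0
    for combo in combinations(sorted(background), n_draw):
        total += 1
        if len(set(combo) & hits) >= k_obs:
            count += 1
    return count / total
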