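"""ANI matrices, cluster alignments, Jukes–Cantor distances, NJ/UPGMA trees.

Average nucleotide identity between two genomes is the mean pairwise
percent identity over ortholog clusters in which both genomes contribute
exactly one gene (an orthoANI-flavoured definition; the conventional 95%
species boundary applies unchanged).  Per-cluster alignments come from a
deterministic center-star procedure (exact for the indel-free case),
distances from the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), and
trees from Saitou–Nei neighbor joining (optionally with column-resampling
bootstrap supports) or UPGMA for the ultrametric reference clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj
from skbio.tree import upgma as _skbio_upgma

from .orthology import GeneRecord, GenomeSet, OrthologCatalog, _make_aligner
from .treecmp import split_set

__all__ = [
    "ANIMatrix",
    "ClusterAlignment",
    "ani_matrix",
    "center_star_align",
    "jc_distance_matrix",
    "build_nj",
    "build_upgma",
]

JC_SATURATION_CAP = 5.0  # subst/site reported when p >= 3/4 (d undefined)


# ---------------------------------------------------------------------------
# Cluster alignment (center star)
# ---------------------------------------------------------------------------


@dataclass
class ClusterAlignment:
    """Aligned cluster: equal-length rows over {A,C,G,T,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have >= 1 row")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def to_matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            len(self.rows), -1
        )


def _pairwise_to_center(center: str, seq: str, aligner) -> tuple[list[str], list[str]]:
    """Align seq to center; return per-center-slot insertions and the
    character of seq aligned to each center position.

    ``inserts[i]`` holds seq characters falling before center position i
    (i = len(center) collects the tail); ``chars[i]`` is the seq character
    (or '-') aligned to center position i.
    """
    aln = aligner.align(center, seq)[0]
    c_aln, s_aln = str(aln[0]), str(aln[1])
    inserts = [""] * (len(center) + 1)
    chars = [""] * len(center)
    ci = 0
    for cc, sc in zip(c_aln, s_aln):
        if cc == "-":
            inserts[ci] += sc
        else:
            chars[ci] = sc
            ci += 1
    return inserts, chars


def center_star_align(
    cluster: Sequence[GeneRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> ClusterAlignment:
    """Deterministic center-star multiple alignment of a gene cluster.

    The longest member (ties broken by smallest (genome, gene) key) is the
    center; every other member is globally aligned to it and the pairwise
    alignments are merged on the center's coordinates.  On the
    simulator's ungapped equal-length families the output is gap-free
    with column count equal to the gene length.
    """
    members = sorted(cluster, key=lambda r: r.key)
    if not members:
        raise ValueError("center_star_align requires a non-empty cluster")
    ids = [f"{r.genome_id}|{r.gene_id}" for r in members]
    if len(members) == 1:
        return ClusterAlignment(ids, [members[0].sequence])
    # center: longest member, ties broken by smallest key
    center_idx = sorted(
        range(len(members)), key=lambda i: (-len(members[i]), members[i].key)
    )[0]
    center = members[center_idx].sequence
    aligner = _make_aligner(match, mismatch, gap)
    per_member: list[tuple[list[str], list[str]]] = []
    for i, rec in enumerate(members):
        if i == center_idx:
            continue
        per_member.append(_pairwise_to_center(center, rec.sequence, aligner))
    master_ins = [0] * (len(center) + 1)
    for inserts, _chars in per_member:
        for slot, ins in enumerate(inserts):
            master_ins[slot] = max(master_ins[slot], len(ins))

    def build_row(inserts: list[str], chars: list[str]) -> str:
        parts = []
        for i in range(len(center)):
            parts.append(inserts[i].ljust(master_ins[i], "-"))
            parts.append(chars[i])
        parts.append(inserts[len(center)].ljust(master_ins[len(center)], "-"))
        return "".join(parts)

    center_row = build_row([""] * (len(center) + 1), list(center))
    rows: list[str] = []
    it = iter(per_member)
    for i in range(len(members)):
        if i == center_idx:
            rows.append(center_row)
        else:
            inserts, chars = next(it)
            rows.append(build_row(inserts, chars))
    return ClusterAlignment(ids, rows)


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------


class ANIMatrix:
    """Square percent-identity matrix over genomes (diagonal 100)."""

    def __init__(self, df: pd.DataFrame):
        self.df = df

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.index)

    def value(self, a: str, b: str) -> float:
        return float(self.df.loc[a, b])

    def species_components(self, threshold: float = 95.0) -> list[set[str]]:
        """Connected components of the ANI >= threshold graph — the
        conventional species delimitation at the 95% cutoff."""
        genomes = self.genome_ids
        adj = {g: set() for g in genomes}
        for i, a in enumerate(genomes):
            for b in genomes[i + 1 :]:
                v = self.df.loc[a, b]
                if pd.notna(v) and v >= threshold:
                    adj[a].add(b)
                    adj[b].add(a)
        seen: set[str] = set()
        comps = []
        for g in genomes:
            if g in seen:
                continue
            stack, comp = [g], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    def to_distance_matrix(self) -> DistanceMatrix:
        """100 − ANI, for UPGMA/NJ clustering of genomes."""
        d = 100.0 - self.df.to_numpy(dtype=float)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(d, self.genome_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="genome_id")


def _identity_matrix_from_alignment(mat: np.ndarray) -> np.ndarray:
    """Pairwise percent identity over columns where both rows are non-gap."""
    gap = ord("-")
    nongap = mat != gap
    eq = (mat[:, None, :] == mat[None, :, :]) & nongap[:, None, :] & nongap[None, :, :]
    both = nongap[:, None, :] & nongap[None, :, :]
    denom = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        idm = 100.0 * eq.sum(axis=2) / denom
    return idm


def ani_matrix(genomes: GenomeSet, catalog: OrthologCatalog) -> ANIMatrix:
    """Mean ortholog identity between every genome pair.

    Only clusters where both genomes of a pair contribute exactly one
    gene enter that pair's mean.  Pairs sharing no such cluster are
    reported missing (NaN) with a warning.
    """
    gids = genomes.genome_ids
    if len(gids) < 2:
        raise ValueError("ANI requires >= 2 genomes")
    index = {g: i for i, g in enumerate(gids)}
    n = len(gids)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    for _cid, members in catalog.items():
        per_genome: dict[str, list[GeneRecord]] = {}
        for rec in members:
            per_genome.setdefault(rec.genome_id, []).append(rec)
        single = sorted(g for g, rs in per_genome.items() if len(rs) == 1)
        if len(single) < 2:
            continue
        recs = [per_genome[g][0] for g in single]
        if len({len(r.sequence) for r in recs}) == 1:
            mat = np.frombuffer(
                "".join(r.sequence for r in recs).encode(), dtype=np.uint8
            ).reshape(len(recs), -1)
        else:
            mat = center_star_align(recs).to_matrix()
        idm = _identity_matrix_from_alignment(mat)
        gidx = np.array([index[g] for g in single])
        sums[np.ix_(gidx, gidx)] += idm
        counts[np.ix_(gidx, gidx)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ani = sums / counts
    np.fill_diagonal(ani, 100.0)
    off_missing = (counts == 0) & ~np.eye(n, dtype=bool)
    if off_missing.any():
        warnings.warn(
            f"{int(off_missing.sum()) // 2} genome pair(s) share no single-copy cluster; ANI missing"
        )
        ani[off_missing] = np.nan
    return ANIMatrix(pd.DataFrame(ani, index=gids, columns=gids))


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------


def jc_distance_matrix(alignment: ClusterAlignment) -> DistanceMatrix:
    """Jukes–Cantor distances d = −(3/4)·ln(1 − 4p/3) between all rows.

    p is the mismatch proportion over columns where both rows are
    ungapped; p >= 3/4 is saturated and reported capped at
    ``JC_SATURATION_CAP`` with a warning.  Zero comparable columns for
    any pair is an error.
    """
    mat = alignment.to_matrix()
    if mat.shape[0] < 2:
        raise ValueError("JC distances require >= 2 sequences")
    gap = ord("-")
    nongap = mat != gap
    both = nongap[:, None, :] & nongap[None, :, :]
    denom = both.sum(axis=2)
    if (denom[~np.eye(len(mat), dtype=bool)] == 0).any():
        raise ValueError("a sequence pair has zero comparable columns")
    diff = ((mat[:, None, :] != mat[None, :, :]) & both).sum(axis=2)
    p = diff / denom
    saturated = p >= 0.75
    np.fill_diagonal(saturated, False)
    if saturated.any():
        warnings.warn(
            f"{int(saturated.sum()) // 2} pair(s) at JC saturation (p >= 3/4); distance capped"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    d[saturated] = JC_SATURATION_CAP
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, alignment.ids)


def _check_distance_input(dist: DistanceMatrix, min_taxa: int) -> DistanceMatrix:
    if not isinstance(dist, DistanceMatrix):
        arr = np.asarray(dist, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be square and symmetric")
        if (arr < 0).any():
            raise ValueError("distance matrix must be non-negative")
        dist = DistanceMatrix(arr)
    if dist.shape[0] < min_taxa:
        raise ValueError(f"need >= {min_taxa} taxa")
    # lexicographic taxon order makes agglomeration tie-breaks deterministic
    order = sorted(dist.ids)
    return dist.filter(order)


def build_nj(
    dist: DistanceMatrix,
    bootstrap: int = 0,
    alignment: ClusterAlignment | None = None,
    seed: int = 0,
) -> TreeNode:
    """Saitou–Nei neighbor-joining tree (negative branch lengths clamped).

    With ``bootstrap`` > 0 and an alignment whose rows correspond to the
    distance matrix ids, internal nodes carry percent support: the share
    of column-resampled replicates whose NJ tree contains the same
    bipartition, stored both as ``node.support`` and the internal node
    name.
    """
    dist = _check_distance_input(dist, 3)
    tree = _skbio_nj(dist)
    if bootstrap > 0:
        if alignment is None:
            raise ValueError("bootstrap requires an alignment")
        if sorted(alignment.ids) != sorted(dist.ids):
            raise ValueError("alignment ids do not match the distance matrix")
        rng = np.random.default_rng(seed)
        order = sorted(alignment.ids)
        ncols = alignment.n_columns
        counts: dict[int, int] = {}
        base_mat = alignment.to_matrix()
        row_of = {i: alignment.ids.index(i) for i in order}
        for _ in range(bootstrap):
            cols = rng.integers(0, ncols, size=ncols)
            rep_rows = [base_mat[row_of[i]][cols].tobytes().decode() for i in order]
            rep_aln = ClusterAlignment(list(order), rep_rows)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep_tree = _skbio_nj(jc_distance_matrix(rep_aln))
            for s in split_set(rep_tree, order):
                counts[s] = counts.get(s, 0) + 1
        full = (1 << len(order)) - 1
        idx = {name: i for i, name in enumerate(order)}
        for node in tree.non_tips(include_self=False):
            m = 0
            for tip in node.tips():
                m |= 1 << idx[tip.name]
            norm = (full ^ m) if (m & 1) else m
            c = bin(norm).count("1")
            if 2 <= c <= len(order) - 2:
                pct = 100.0 * counts.get(norm, 0) / bootstrap
                node.support = pct
                node.name = f"{pct:g}"
    return tree


def build_upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering tree; ultrametric output."""
    dist = _check_distance_input(dist, 2)
    if dist.shape[0] == 2:
        a, b = dist.ids
        h = dist[a, b] / 2.0
        return TreeNode.read([f"({a}:{h:g},{b}:{h:g});"], convert_underscores=False)
    return _skbio_upgma(dist)
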