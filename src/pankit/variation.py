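"""Consensus-based SNP calling and a simplified HGT screen.

SNPs are defined against each core cluster's per-column consensus: a SNP
is a non-ambiguous alignment column in which at least one genome deviates
from the strict-majority base.  Columns containing any gap, or with a tie
for the plurality base, are ambiguous and never yield calls.  The primary
reported total is the number of polymorphic columns; per-genome deviation
counts are emitted alongside for transparency.

The HGT screen is a deliberately simplified best-match + tree-incongruence
analogue of contig-level transfer detectors (it is not a port of any of
them): a gene copy is a candidate when its best identity to a foreign
species group exceeds its mean identity to its own group *and* its gene
tree places it inside a clade dominated by that foreign group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .orthology import OrthologCatalog
from .phylogeny import ClusterAlignment, _identity_matrix_from_alignment, center_star_align

__all__ = [
    "SnpRecord",
    "SnpSummary",
    "HgtCandidate",
    "build_consensus",
    "call_snps",
    "call_snps_catalog",
    "detect_hgt",
    "hgt_pair_table",
]

_GAP = ord("-")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SnpRecord:
    cluster_id: str
    column: int                     # 1-based alignment coordinate
    consensus_base: str
    deviations: tuple[tuple[str, str], ...]   # ((row_id, base), ...)


@dataclass
class SnpSummary:
    cluster_id: str
    n_columns: int
    n_polymorphic: int
    n_deviations: int               # per-genome deviating bases, summed
    n_ambiguous: int

    @property
    def density(self) -> float:
        """Polymorphic columns per bp of alignment."""
        return self.n_polymorphic / self.n_columns


def build_consensus(alignment: ClusterAlignment) -> tuple[str, set[int]]:
    """Strict-majority consensus and the set of ambiguous columns (0-based).

    A column is ambiguous when any row holds a gap or when two bases tie
    for the plurality; ambiguous consensus positions are reported as 'N'.
    """
    mat = alignment.to_matrix()
    if mat.shape[0] < 2:
        raise ValueError("consensus requires >= 2 rows")
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])   # 4 x L
    order = np.sort(counts, axis=0)
    top, second = order[-1], order[-2]
    has_gap = (mat == _GAP).any(axis=0)
    ambiguous = has_gap | (top == second)
    best = counts.argmax(axis=0)
    cons = _BASES[best].copy()
    cons[ambiguous] = ord("N")
    return cons.tobytes().decode(), set(np.flatnonzero(ambiguous).tolist())


def call_snps(
    alignment: ClusterAlignment,
    consensus: str,
    ambiguous: set[int],
    cluster_id: str = "",
) -> tuple[list[SnpRecord], SnpSummary]:
    """One SNP record per non-ambiguous column with >= 1 deviating row."""
    mat = alignment.to_matrix()
    if len(consensus) != mat.shape[1]:
        raise ValueError("consensus length does not match the alignment")
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    amb_mask = np.zeros(mat.shape[1], dtype=bool)
    if ambiguous:
        amb_mask[sorted(ambiguous)] = True
    dev = (mat != cons[None, :]) & ~amb_mask[None, :]
    poly_cols = np.flatnonzero(dev.any(axis=0))
    records = []
    for col in poly_cols:
        rows = np.flatnonzero(dev[:, col])
        records.append(
            SnpRecord(
                cluster_id=cluster_id,
                column=int(col) + 1,
                consensus_base=consensus[col],
                deviations=tuple(
                    (alignment.ids[r], chr(mat[r, col])) for r in rows
                ),
            )
        )
    summary = SnpSummary(
        cluster_id=cluster_id,
        n_columns=mat.shape[1],
        n_polymorphic=len(poly_cols),
        n_deviations=int(dev.sum()),
        n_ambiguous=int(amb_mask.sum()),
    )
    return records, summary


def call_snps_catalog(
    catalog: OrthologCatalog,
    cluster_ids: list[str] | None = None,
) -> tuple[list[SnpRecord], pd.DataFrame]:
    """Consensus SNP calling over (a subset of) a catalog's clusters.

    Equal-length clusters align gaplessly (positional homology); mixed-
    length clusters go through center star.  Consensus is built per
    cluster and SNPs called against it.  Returns all records plus a
    per-cluster summary frame whose ``n_polymorphic`` column sums to the
    pipeline total.
    """
    wanted = set(cluster_ids) if cluster_ids is not None else None
    all_records: list[SnpRecord] = []
    rows = []
    for cid, members in catalog.items():
        if wanted is not None and cid not in wanted:
            continue
        if len(members) < 2:
            continue
        ordered = sorted(members, key=lambda r: r.key)
        if len({len(r.sequence) for r in ordered}) == 1:
            aln = ClusterAlignment(
                [f"{r.genome_id}|{r.gene_id}" for r in ordered],
                [r.sequence for r in ordered],
            )
        else:
            aln = center_star_align(ordered)
        cons, amb = build_consensus(aln)
        recs, summary = call_snps(aln, cons, amb, cluster_id=cid)
        all_records.extend(recs)
        rows.append(
            (cid, summary.n_columns, summary.n_polymorphic, summary.n_deviations,
             summary.n_ambiguous, summary.density)
        )
    df = pd.DataFrame(
        rows,
        columns=["cluster_id", "n_columns", "n_polymorphic", "n_deviations",
                 "n_ambiguous", "density"],
    ).set_index("cluster_id")
    return all_records, df


def snp_records_to_frame(records: list[SnpRecord]) -> pd.DataFrame:
    rows = [
        (r.cluster_id, r.column, r.consensus_base, rid, base)
        for r in records
        for rid, base in r.deviations
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "column", "consensus", "sequence_id", "base"]
    )


# ---------------------------------------------------------------------------
# HGT screen
# ---------------------------------------------------------------------------


@dataclass
class HgtCandidate:
    cluster_id: str
    recipient_genome: str
    recipient_group: str
    best_foreign_group: str
    within_group_identity: float     # mean %, same-group copies
    best_foreign_identity: float     # best %, copies of the flagged group
    incongruent: bool = True

    @property
    def identity_gap(self) -> float:
        return self.best_foreign_identity - self.within_group_identity


def _leaf_parent_group_fraction(
    tree: TreeNode, leaf_id: str, leaf_group: Mapping[str, str], group: str
) -> float:
    """Fraction of the query leaf's smallest enclosing clade (its parent's
    leaves, query excluded) belonging to ``group``."""
    node = tree.find(leaf_id)
    sibs = [t.name for t in node.parent.tips() if t.name != leaf_id]
    if not sibs:
        return 0.0
    return sum(leaf_group.get(s) == group for s in sibs) / len(sibs)


def detect_hgt(
    catalog: OrthologCatalog,
    groups: Mapping[str, str],
    gene_trees: Mapping[str, TreeNode],
    min_identity_gap: float = 2.5,
) -> list[HgtCandidate]:
    """Best-match + tree-incongruence screen for transferred gene copies.

    For every single-copy-per-genome cluster member, the mean identity to
    same-group copies and the best identity to each foreign group are
    computed from the cluster alignment.  A copy is a candidate when its
    best foreign identity exceeds its within-group mean by more than
    ``min_identity_gap`` *and* the smallest clade enclosing it in the gene
    tree is majority-occupied by that foreign group.  The default gap of
    2.5 identity points is a noise margin: per-pair identity estimates on
    kilobase genes carry ~1-point sampling error, so the best-of-many
    foreign identity can exceed the within-group mean by ~2 points by
    chance; genuine cross-species transfers at the conventional 95/92%
    within/between split show gaps of 4+ points.  Genomes whose group has
    a single member are skipped with a warning (the within-group mean is
    undefined).  Output is sorted by identity gap, largest first.
    """
    missing = [g for g in {r.genome_id for c in catalog.clusters for r in c} if g not in groups]
    if missing:
        raise KeyError(f"genomes without a group assignment: {sorted(missing)}")
    singleton_groups = {
        grp for grp in set(groups.values())
        if sum(v == grp for v in groups.values()) == 1
    }
    if singleton_groups:
        warnings.warn(
            f"group(s) with a single genome skipped: {sorted(singleton_groups)}"
        )
    candidates: list[HgtCandidate] = []
    for cid, members in catalog.items():
        if cid not in gene_trees:
            continue
        per_genome: dict[str, list] = {}
        for rec in members:
            per_genome.setdefault(rec.genome_id, []).append(rec)
        single = sorted(g for g, rs in per_genome.items() if len(rs) == 1)
        if len(single) < 3:
            continue
        recs = [per_genome[g][0] for g in single]
        if len({len(r.sequence) for r in recs}) == 1:
            mat = np.frombuffer(
                "".join(r.sequence for r in recs).encode(), dtype=np.uint8
            ).reshape(len(recs), -1)
        else:
            mat = center_star_align(recs).to_matrix()
        idm = _identity_matrix_from_alignment(mat)
        tree = gene_trees[cid]
        tree_leaves = {t.name for t in tree.tips()}
        leaf_group = {}
        leaf_of = {}
        for g, rec in zip(single, recs):
            lid = f"{rec.genome_id}|{rec.gene_id}"
            if lid not in tree_leaves and g in tree_leaves:
                lid = g            # trees may be labelled by genome only
            leaf_of[g] = lid
            leaf_group[lid] = groups[g]
        group_of = {g: groups[g] for g in single}
        present_groups = sorted(set(group_of.values()))
        for qi, g in enumerate(single):
            grp = group_of[g]
            if grp in singleton_groups:
                continue
            same = [i for i, h in enumerate(single) if i != qi and group_of[h] == grp]
            if not same:
                continue
            within_mean = float(idm[qi, same].mean())
            best_grp, best_id = None, -np.inf
            for fg in present_groups:
                if fg == grp:
                    continue
                others = [i for i, h in enumerate(single) if group_of[h] == fg]
                if not others:
                    continue
                top = float(idm[qi, others].max())
                if top > best_id:
                    best_grp, best_id = fg, top
            if best_grp is None or best_id - within_mean <= min_identity_gap:
                continue
            if leaf_of[g] not in tree_leaves:
                continue
            frac = _leaf_parent_group_fraction(tree, leaf_of[g], leaf_group, best_grp)
            if frac > 0.5:
                candidates.append(
                    HgtCandidate(
                        cluster_id=cid,
                        recipient_genome=g,
                        recipient_group=grp,
                        best_foreign_group=best_grp,
                        within_group_identity=within_mean,
                        best_foreign_identity=best_id,
                    )
                )
    candidates.sort(key=lambda c: (-c.identity_gap, c.cluster_id, c.recipient_genome))
    return candidates


def hgt_pair_table(candidates: list[HgtCandidate]) -> pd.DataFrame:
    """Species-pair event counts (inferred donor group, recipient group)."""
    rows = [(c.best_foreign_group, c.recipient_group) for c in candidates]
    df = pd.DataFrame(rows, columns=["donor_group", "recipient_group"])
    if df.empty:
        return pd.DataFrame(columns=["donor_group", "recipient_group", "n_events"])
    return (
        df.value_counts().rename("n_events").reset_index()
        .sort_values(["donor_group", "recipient_group"], ignore_index=True)
    )


def hgt_to_frame(candidates: list[HgtCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.cluster_id, c.recipient_genome, c.recipient_group, c.best_foreign_group,
             c.within_group_identity, c.best_foreign_identity, c.identity_gap)
            for c in candidates
        ],
        columns=["cluster_id", "recipient_genome", "recipient_group",
                 "best_foreign_group", "within_group_identity",
                 "best_foreign_identity", "identity_gap"],
    )


def write_snps(
    records: list[SnpRecord], summary: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snp_records_to_frame(records).to_csv(outdir / "snps.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "snp_summary.tsv", sep="\t")
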