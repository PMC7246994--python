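"""Category bookkeeping and accessory-genome enrichment.

Two user-facing analyses over a gene/cluster -> category table:

* fold extension — per-category counts of annotated clusters in the pan,
  softcore (inclusive >= 95% tier) and core genomes, with the
  pan-to-subset extension ratios displayed at one decimal (full precision
  retained internally);
* set enrichment — upper-tail hypergeometric test of a gene set (e.g. a
  species' specific accessory genome) against a background, reported with
  the rich factor (set hits / background hits) and Benjamini–Hochberg
  q-values.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .orthology import PresenceAbsenceMatrix
from .pangenome import PangenomePartition

__all__ = [
    "CategoryTable",
    "tabulate_fold_extension",
    "species_specific_accessory",
    "enrich",
]


class CategoryTable:
    """Mapping cluster/gene -> one or more category labels.

    Multi-category members count once per category (no fractional
    weighting); unannotated members are simply absent from the table.
    """

    def __init__(self, assignments: Iterable[tuple[str, str]] | Mapping[str, Iterable[str]]):
        pairs: list[tuple[str, str]] = []
        if isinstance(assignments, Mapping):
            for member, cats in assignments.items():
                for c in cats:
                    pairs.append((member, c))
        else:
            pairs = list(assignments)
        for member, cat in pairs:
            if not cat:
                raise ValueError(f"empty category label for {member!r}")
        self._of: dict[str, set[str]] = {}
        self._members: dict[str, set[str]] = {}
        for member, cat in pairs:
            self._of.setdefault(member, set()).add(cat)
            self._members.setdefault(cat, set()).add(member)

    @property
    def categories(self) -> list[str]:
        return sorted(self._members)

    def members_of(self, category: str) -> set[str]:
        return set(self._members.get(category, set()))

    def categories_of(self, member: str) -> set[str]:
        return set(self._of.get(member, set()))

    def annotated(self) -> set[str]:
        return set(self._of)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryTable":
        df = pd.read_csv(path, sep="\t")
        cols = [c.lower() for c in df.columns]
        member_col = df.columns[cols.index("cluster_id")] if "cluster_id" in cols else df.columns[0]
        cat_col = df.columns[cols.index("category")] if "category" in cols else df.columns[1]
        return cls(list(zip(df[member_col].astype(str), df[cat_col].astype(str))))


def _display_ratio(x: float | None) -> float | None:
    return None if x is None else round(x, 1)


def tabulate_fold_extension(
    categories: CategoryTable,
    partition: PangenomePartition,
) -> pd.DataFrame:
    """Per-category pan/softcore/core counts and pan-to-subset extensions.

    ``softcore`` is the inclusive >= 95% tier (core included).  Extension
    = pan count / subset count; an empty subset leaves the extension
    missing.  The frame carries full-precision ``*_extension`` columns and
    1-decimal ``*_extension_display`` columns, plus a ``Total`` row
    summing the counts with ratios recomputed from the summed counts.
    """
    pan_clusters = set(partition.labels.index)
    soft_clusters = partition.clusters_with("core", "softcore")
    core_clusters = partition.clusters_with("core")
    rows = []
    for cat in categories.categories:
        members = categories.members_of(cat) & pan_clusters
        if not members:
            continue
        rows.append((cat, len(members), len(members & soft_clusters), len(members & core_clusters)))
    df = pd.DataFrame(rows, columns=["category", "pan", "softcore", "core"]).set_index("category")
    total = df.sum(axis=0)
    total.name = "Total"
    df = pd.concat([df, total.to_frame().T])
    for subset in ("softcore", "core"):
        ext = df["pan"] / df[subset].where(df[subset] > 0)
        df[f"{subset}_to_pan_extension"] = ext
        df[f"{subset}_to_pan_extension_display"] = ext.round(1)
    return df


def species_specific_accessory(
    matrix: PresenceAbsenceMatrix,
    partition: PangenomePartition,
    groups: Mapping[str, str],
) -> dict[str, set[str]]:
    """Per-species specific accessory clusters.

    For each species: the non-core clusters present in at least one of its
    genomes and absent from every genome of every other species.
    """
    missing = [g for g in matrix.genome_ids if g not in groups]
    if missing:
        raise KeyError(f"genomes without a group assignment: {missing}")
    non_core = partition.clusters_with("softcore", "shell", "cloud")
    df = matrix.df
    out: dict[str, set[str]] = {}
    for sp in sorted(set(groups[g] for g in matrix.genome_ids)):
        own = [g for g in matrix.genome_ids if groups[g] == sp]
        other = [g for g in matrix.genome_ids if groups[g] != sp]
        present = df[own].sum(axis=1) > 0
        absent_elsewhere = (df[other].sum(axis=1) == 0) if other else pd.Series(True, index=df.index)
        hits = set(df.index[present & absent_elsewhere]) & non_core
        out[sp] = hits
    return out


def enrich(
    gene_set: set[str],
    background: set[str],
    categories: CategoryTable,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH-adjusted q-values.

    For each category with at least one annotated background member:
    ``p = P(X >= set_count)`` for X hypergeometric(background_size,
    background_count, set_size); ``rich_factor = set_count /
    background_count``.  q-values are Benjamini–Hochberg over all tested
    categories; rows are sorted by (q, p, category).
    """
    if not gene_set or not background:
        raise ValueError("gene set and background must be non-empty")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    M = len(background)
    N = len(gene_set)
    rows = []
    for cat in categories.categories:
        bg_hits = categories.members_of(cat) & background
        K = len(bg_hits)
        if K == 0:
            continue
        k = len(bg_hits & gene_set)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append((cat, k, N, K, M, k / K, p))
    if not rows:
        warnings.warn("no category annotates the background; empty result")
        return pd.DataFrame(
            columns=["category", "set_count", "set_size", "background_count",
                     "background_size", "rich_factor", "p", "q"]
        )
    df = pd.DataFrame(
        rows,
        columns=["category", "set_count", "set_size", "background_count",
                 "background_size", "rich_factor", "p"],
    )
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["q", "p", "category"], ignore_index=True)
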