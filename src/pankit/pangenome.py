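"""Pan-genome partitioning, accumulation curves and Heaps'-law openness.

Clusters are partitioned by occupancy following the standard four-tier
scheme: *core* = present in every genome; *softcore* = present in at
least 95% of genomes (ceil(0.95·n)) but not all; *cloud* = present in at
most two genomes; *shell* = everything in between.  Pan- and core-genome
accumulation curves are computed over randomized genome orderings
(10 permutations by default) and the openness exponent is obtained by a
log–log least-squares fit of the median number of *new* gene clusters
contributed by the N-th genome, n(N) = k·N^(−α); α < 1 marks an open
pan-genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .orthology import GenomeSet, PresenceAbsenceMatrix

__all__ = [
    "PangenomePartition",
    "AccumulationCurves",
    "HeapsFit",
    "PangenomeReport",
    "partition_clusters",
    "accumulation_curves",
    "fit_heaps",
    "pangenome_report",
]

LABELS = ("core", "softcore", "shell", "cloud")


@dataclass
class PangenomePartition:
    """Exclusive core/softcore/shell/cloud label per cluster."""

    labels: pd.Series            # cluster_id -> label
    n_genomes: int
    softcore_frac: float = 0.95
    cloud_max: int = 2

    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {lab: int(c.get(lab, 0)) for lab in LABELS}

    def clusters_with(self, *labels: str) -> set[str]:
        return set(self.labels.index[self.labels.isin(labels)])

    def to_tsv(self, path: str | Path, presence: pd.Series | None = None) -> None:
        df = pd.DataFrame({"label": self.labels})
        if presence is not None:
            df.insert(0, "presence", presence)
        df.to_csv(path, sep="\t", index_label="cluster_id")


def partition_clusters(
    matrix: PresenceAbsenceMatrix,
    softcore_frac: float = 0.95,
    cloud_max: int = 2,
) -> PangenomePartition:
    """Label every cluster core/softcore/shell/cloud by genome occupancy.

    Precedence core > softcore > cloud > shell resolves the degenerate
    overlaps that arise at tiny n (e.g. n <= 20 where ceil(0.95·n) = n
    collapses softcore onto core, or n <= 2 where every presence count is
    also a cloud count).
    """
    if not (0.0 < softcore_frac <= 1.0):
        raise ValueError("softcore_frac must lie in (0, 1]")
    if matrix.df.empty:
        raise ValueError("presence/absence matrix is empty")
    n = matrix.n_genomes
    soft_min = math.ceil(softcore_frac * n)
    presence = matrix.presence_counts()

    def label(p: int) -> str:
        if p == n:
            return "core"
        if p >= soft_min:
            return "softcore"
        if p <= cloud_max:
            return "cloud"
        return "shell"

    labels = presence.map(label)
    labels.name = "label"
    return PangenomePartition(labels, n, softcore_frac, cloud_max)


@dataclass
class AccumulationCurves:
    """Pan/core accumulation over randomized genome orderings.

    ``pan[i, N-1]`` (resp. ``core``) is the number of clusters present in
    at least one (resp. all) of the first N genomes of permutation i;
    ``new`` is the first difference of ``pan`` with new(1) = pan(1).
    """

    pan: np.ndarray
    core: np.ndarray
    new: np.ndarray
    orders: list[list[str]]

    @property
    def n_perm(self) -> int:
        return self.pan.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.pan.shape[1]

    def median_pan(self) -> np.ndarray:
        return np.median(self.pan, axis=0)

    def median_core(self) -> np.ndarray:
        return np.median(self.core, axis=0)

    def median_new(self) -> np.ndarray:
        return np.median(self.new, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_perm):
            for N in range(self.n_genomes):
                rows.append((i, N + 1, self.pan[i, N], self.core[i, N], self.new[i, N]))
        return pd.DataFrame(rows, columns=["perm", "N", "pan", "core", "new"])


def accumulation_curves(
    matrix: PresenceAbsenceMatrix,
    n_perm: int = 10,
    seed: int = 0,
) -> AccumulationCurves:
    """Pan/core curves: add one genome at a time, order randomized ``n_perm`` times."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    occ = matrix.df.to_numpy(dtype=bool)        # clusters x genomes
    genomes = matrix.genome_ids
    n = len(genomes)
    pan = np.zeros((n_perm, n), dtype=float)
    core = np.zeros((n_perm, n), dtype=float)
    orders = []
    for i in range(n_perm):
        order = rng.permutation(n)
        orders.append([genomes[j] for j in order])
        cum_any = np.logical_or.accumulate(occ[:, order], axis=1)
        cum_all = np.logical_and.accumulate(occ[:, order], axis=1)
        pan[i] = cum_any.sum(axis=0)
        core[i] = cum_all.sum(axis=0)
    new = np.diff(pan, axis=1, prepend=0.0)
    return AccumulationCurves(pan, core, new, orders)


@dataclass
class HeapsFit:
    """Openness fit n(N) = k·N^(−α) on median new-genes-per-genome."""

    k: float
    alpha: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @property
    def open_flag(self) -> bool:
        return self.alpha < 1.0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "alpha": self.alpha,
            "open": self.open_flag,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_heaps(curves: AccumulationCurves, pseudocount: float = 0.5) -> HeapsFit:
    """Least-squares log–log fit of median new genes vs genome number.

    Uses N = 2..n (the first genome's "new" count is its whole gene set,
    not a discovery increment).  Zero medians are replaced by
    ``pseudocount`` so the log stays defined.  Returns k = exp(intercept)
    and α = −slope; α < 1 flags an open pan-genome.
    """
    n = curves.n_genomes
    if n < 3:
        raise ValueError("Heaps fit requires >= 3 genomes (>= 2 usable points)")
    med_new = curves.median_new()[1:]           # N = 2..n
    N = np.arange(2, n + 1, dtype=float)
    y = np.where(med_new > 0, med_new, pseudocount)
    res = stats.linregress(np.log(N), np.log(y))
    return HeapsFit(
        k=float(np.exp(res.intercept)),
        alpha=float(-res.slope),
        r_squared=float(res.rvalue**2),
        n_points=len(N),
    )


@dataclass
class PangenomeReport:
    """Per-set summary in the shape of a genomic-statistics table row.

    ``n_softcore`` is the inclusive >= ceil(0.95·n) tier (it contains the
    core), so n_softcore + n_shell + n_cloud = n_pan always holds; at
    n <= 20 the softcore tier collapses onto the core and
    n_core + n_shell + n_cloud = n_pan as well.
    """

    n_genomes: int
    n_core: int
    n_softcore: int
    n_shell: int
    n_cloud: int
    n_pan: int
    mean_genome_bp: float | None = None
    sd_genome_bp: float | None = None
    mean_gene_count: float | None = None
    sd_gene_count: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pangenome_report(
    matrix: PresenceAbsenceMatrix,
    partition: PangenomePartition,
    genomes: GenomeSet | None = None,
) -> PangenomeReport:
    """Assemble the per-set report from a matrix and its partition.

    If a :class:`GenomeSet` is given, per-genome size (total gene bp, a
    coding-complement proxy) and gene-count summaries are included.
    """
    if sorted(partition.labels.index) != sorted(matrix.cluster_ids):
        raise ValueError("partition does not match the matrix's clusters")
    if partition.n_genomes != matrix.n_genomes:
        raise ValueError("partition computed for a different genome count")
    c = partition.counts()
    n_pan = len(matrix.cluster_ids)
    rep = PangenomeReport(
        n_genomes=matrix.n_genomes,
        n_core=c["core"],
        n_softcore=c["core"] + c["softcore"],
        n_shell=c["shell"],
        n_cloud=c["cloud"],
        n_pan=n_pan,
    )
    if genomes is not None:
        sizes = genomes.genome_sizes_bp().reindex(matrix.genome_ids)
        counts = genomes.genome_gene_counts().reindex(matrix.genome_ids)
        rep.mean_genome_bp = float(sizes.mean())
        rep.sd_genome_bp = float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0
        rep.mean_gene_count = float(counts.mean())
        rep.sd_gene_count = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return rep
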