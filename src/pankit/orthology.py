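"""Orthologous gene clustering and presence/absence bookkeeping.

The gene universe is a :class:`GenomeSet` of genome-tagged nucleotide
sequences.  Homologous families are recovered by single-linkage clustering
of the pairwise-similarity graph: two genes are joined when their global
alignment reaches both an identity and a coverage cutoff (defaults follow
common pan-genome practice: 70% identity, 75% coverage).  The resulting
:class:`OrthologCatalog` partitions the gene universe, and
:func:`build_presence_absence` reduces it to the binary cluster x genome
occupancy matrix that every downstream stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "GenomeSet",
    "OrthologCatalog",
    "PresenceAbsenceMatrix",
    "align_pair",
    "cluster_genes",
    "build_presence_absence",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GeneRecord:
    """A single gene: genome of origin, identifier, DNA sequence (A/C/G/T)."""

    genome_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("GeneRecord sequence must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeSet:
    """An ordered collection of :class:`GeneRecord` spanning one or more genomes.

    (genome_id, gene_id) pairs are unique.  Iteration order is insertion
    order; ``genome_ids`` are reported sorted for deterministic downstream
    output.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate gene key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def genome_ids(self) -> list[str]:
        return sorted({r.genome_id for r in self.records})

    def by_genome(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {g: [] for g in self.genome_ids}
        for rec in self.records:
            out[rec.genome_id].append(rec)
        return out

    def genome_gene_counts(self) -> pd.Series:
        return pd.Series(
            {g: len(v) for g, v in self.by_genome().items()}, name="n_genes"
        ).sort_index()

    def genome_sizes_bp(self) -> pd.Series:
        """Total gene length per genome (bp) — the coding-complement proxy
        for genome size when only gene sequences are available."""
        sizes = {g: sum(len(r) for r in v) for g, v in self.by_genome().items()}
        return pd.Series(sizes, name="size_bp").sort_index()

    # -- FASTA I/O.  Header convention: >{genome_id}|{family_id}|{gene_id};
    #    a two-field header >{genome_id}|{gene_id} is also accepted.
    def to_fasta(self, path: str | Path, family_of: Mapping[tuple[str, str], str] | None = None) -> None:
        recs = []
        for r in self.records:
            fam = family_of.get(r.key, "NA") if family_of else "NA"
            recs.append(
                SeqRecord(Seq(r.sequence), id=f"{r.genome_id}|{fam}|{r.gene_id}", description="")
            )
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, paths: str | Path | Sequence[str | Path]) -> "GenomeSet":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        records = []
        for p in paths:
            for sr in SeqIO.parse(str(p), "fasta"):
                parts = sr.id.split("|")
                if len(parts) == 3:
                    genome, _fam, gene = parts
                elif len(parts) == 2:
                    genome, gene = parts
                else:
                    raise ValueError(
                        f"FASTA header {sr.id!r}: expected genome|family|gene or genome|gene"
                    )
                records.append(GeneRecord(genome, gene, str(sr.seq).upper()))
        return cls(records)


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_pair(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[float, float]:
    """Globally align two DNA strings; return (identity %, coverage %).

    Identity is matches / aligned columns (a pairwise global alignment has
    no double-gap columns) x 100.  Coverage is the number of columns where
    both sequences contribute a residue, over the shorter sequence's
    length, x 100.  The result is symmetric in its arguments: the pair is
    canonically ordered before aligning so that tie-breaking among
    co-optimal alignments cannot depend on argument order.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    if b < a:
        a, b = b, a
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    cols = len(ra)
    matches = sum(x == y for x, y in zip(ra, rb) if x != "-" and y != "-")
    both = sum(x != "-" and y != "-" for x, y in zip(ra, rb))
    identity = 100.0 * matches / cols
    coverage = 100.0 * both / min(len(a), len(b))
    return identity, coverage


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of the gapless (end-to-end, equal-length) alignment."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float((xa == xb).mean())


# ---------------------------------------------------------------------------
# Single-linkage ortholog clustering
# ---------------------------------------------------------------------------


@dataclass
class OrthologCatalog:
    """Clusters of homologous genes partitioning the gene universe."""

    clusters: list[list[GeneRecord]]
    cluster_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cluster_ids:
            self.cluster_ids = [f"C{i:05d}" for i in range(len(self.clusters))]

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.clusters)

    def items(self):
        return zip(self.cluster_ids, self.clusters)

    def membership(self) -> dict[tuple[str, str], str]:
        """(genome_id, gene_id) -> cluster_id."""
        out = {}
        for cid, members in self.items():
            for rec in members:
                out[rec.key] = cid
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (cid, rec.genome_id, rec.gene_id)
            for cid, members in self.items()
            for rec in members
        ]
        pd.DataFrame(rows, columns=["cluster_id", "genome_id", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _similar(
    a: GeneRecord,
    b: GeneRecord,
    min_identity: float,
    min_coverage: float,
    match: float,
    mismatch: float,
    gap: float,
) -> bool:
    """Decide one edge of the similarity graph.

    Equal-length pairs get a gapless fast path: when the gapless identity
    clears the cutoff the pair is accepted (coverage is 100 by
    construction); when it falls far below, the scored alignment cannot
    plausibly rescue it and the pair is rejected; the band in between falls
    back to the full alignment.
    """
    if len(a) == len(b):
        hid = hamming_identity(a.sequence, b.sequence)
        if hid >= min_identity:
            return min_coverage <= 100.0
        if hid < min_identity - 10.0:
            return False
    identity, coverage = align_pair(a.sequence, b.sequence, match, mismatch, gap)
    return identity >= min_identity and coverage >= min_coverage


def _kmer_codes(seq: str, k: int, stride: int) -> np.ndarray:
    """Integer codes of k-mers sampled every `stride` positions (2 bits/base)."""
    x = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.zeros(x.shape, dtype=np.int64)
    code[x == ord("C")] = 1
    code[x == ord("G")] = 2
    code[x == ord("T")] = 3
    if len(x) < k:
        return np.array([], dtype=np.int64)
    kmers = np.zeros(len(x) - k + 1, dtype=np.int64)
    for off in range(k):
        kmers |= code[off : off + len(kmers)] << (2 * off)
    return kmers[::stride]


_EXHAUSTIVE_LIMIT = 64  # below this, skip the k-mer screen and test all pairs


def cluster_genes(
    genes: Iterable[GeneRecord],
    min_identity: float = 70.0,
    min_coverage: float = 75.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    kmer_size: int = 16,
    kmer_stride: int = 8,
) -> OrthologCatalog:
    """Single-linkage ortholog clustering of the similarity graph.

    Clusters are the connected components of the graph whose edges join
    gene pairs with alignment identity >= ``min_identity`` and coverage >=
    ``min_coverage``.  Small inputs are clustered by exhaustive pairwise
    testing; larger inputs use a k-mer candidate screen (pairs sharing a
    sampled exact ``kmer_size``-mer are nominated, then verified by
    alignment before being linked), which assumes homologous genes retain
    at least one exact shared k-mer — comfortably true above ~75%
    identity.  Output is deterministic: clusters are sorted by their
    smallest (genome_id, gene_id) member key.
    """
    genes = sorted(genes, key=lambda r: r.key)
    if not genes:
        raise ValueError("cluster_genes requires a non-empty gene collection")
    n = len(genes)
    uf = _UnionFind(n)

    if n <= _EXHAUSTIVE_LIMIT:
        for i in range(n):
            for j in range(i + 1, n):
                if uf.find(i) != uf.find(j) and _similar(
                    genes[i], genes[j], min_identity, min_coverage, match, mismatch, gap
                ):
                    uf.union(i, j)
    else:
        first_seen: dict[int, int] = {}
        pending: list[tuple[int, int]] = []
        for i, rec in enumerate(genes):
            for code in _kmer_codes(rec.sequence, kmer_size, kmer_stride):
                j = first_seen.setdefault(int(code), i)
                if j != i:
                    pending.append((j, i))
        # verify candidate edges lazily: an edge inside an existing
        # component needs no alignment
        for i, j in pending:
            if uf.find(i) != uf.find(j) and _similar(
                genes[i], genes[j], min_identity, min_coverage, match, mismatch, gap
            ):
                uf.union(i, j)

    components: dict[int, list[GeneRecord]] = {}
    for i, rec in enumerate(genes):
        components.setdefault(uf.find(i), []).append(rec)
    clusters = sorted(components.values(), key=lambda c: c[0].key)
    return OrthologCatalog(clusters)


# ---------------------------------------------------------------------------
# Presence / absence matrix
# ---------------------------------------------------------------------------


class PresenceAbsenceMatrix:
    """Binary cluster x genome occupancy (1 = genome contributes >= 1 gene)."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.astype(np.int8)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_genomes(self) -> int:
        return self.df.shape[1]

    def presence_counts(self) -> pd.Series:
        return self.df.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="cluster_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="cluster_id"))


def build_presence_absence(
    catalog: OrthologCatalog, genomes: Sequence[str]
) -> PresenceAbsenceMatrix:
    """Reduce a catalog to its binary presence/absence matrix.

    Presence is binary regardless of copy number (paralogs collapse).
    Every member's genome_id must appear in ``genomes``.
    """
    genomes = list(genomes)
    index = {g: k for k, g in enumerate(genomes)}
    mat = np.zeros((len(catalog), len(genomes)), dtype=np.int8)
    for row, (_cid, members) in enumerate(catalog.items()):
        for rec in members:
            col = index.get(rec.genome_id)
            if col is None:
                raise KeyError(
                    f"gene {rec.key} references unknown genome {rec.genome_id!r}"
                )
            mat[row, col] = 1
    df = pd.DataFrame(mat, index=catalog.cluster_ids, columns=genomes)
    empty = df.sum(axis=1) == 0
    if empty.any():  # cannot happen via the constructor above; guard for edits
        warnings.warn("presence/absence matrix has empty rows")
    return PresenceAbsenceMatrix(df)
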