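"""Synthetic multi-species pan-genome generator with known ground truth.

Emulates the statistical structure of a multi-species bacterial gene
collection: a fixed number of species clades each holding several genomes,
a core gene pool carried by every genome, accessory families with
Bernoulli (optionally clade-restricted) presence, Jukes–Cantor sequence
divergence calibrated so that within-species average nucleotide identity
sits near the conventional 95–96% band, and optional planted
horizontal-transfer events.

Default divergences: two genomes of the same species are separated by
0.046 substitutions/site (JC expected identity 95.5%) and genomes of
different species by 0.085 (expected identity ~92%), bracketing the 95%
species cutoff from both sides.  Genes are generated ungapped and
equal-length within a family — no indel process — so cluster alignments
are trivially gap-free and SNP semantics are unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from skbio import TreeNode

from .orthology import GeneRecord, GenomeSet

__all__ = [
    "SimConfig",
    "HgtEvent",
    "SimulationTruth",
    "simulate_species_tree",
    "simulate_genomes",
    "plant_hgt",
    "jc_expected_identity",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def jc_expected_identity(d: float) -> float:
    """Expected per-site identity of two sequences separated by d subst/site
    under Jukes–Cantor: 1/4 + (3/4)·exp(−4d/3)."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


@dataclass(frozen=True)
class SimConfig:
    """Study design for one synthetic pan-genome.

    Divergences are *pairwise path lengths*: ``within_species_divergence``
    is the expected substitutions/site separating two genomes of the same
    species, ``between_species_divergence`` the same for genomes of
    different species.
    """

    n_species: int = 4
    genomes_per_species: int = 8
    n_core_families: int = 600
    n_accessory_families: int = 1200
    accessory_presence_prob: float = 0.25
    clade_restriction_prob: float = 0.0
    gene_length: int = 900
    within_species_divergence: float = 0.046
    between_species_divergence: float = 0.085
    n_hgt_events: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.genomes_per_species, self.n_core_families, self.gene_length) < 1:
            raise ValueError("species, genomes, core families and gene length must be >= 1")
        if self.n_accessory_families < 0 or self.n_hgt_events < 0:
            raise ValueError("accessory family and HGT counts must be >= 0")
        if not (0.0 <= self.accessory_presence_prob <= 1.0):
            raise ValueError("accessory_presence_prob must lie in [0, 1]")
        if not (0.0 <= self.clade_restriction_prob <= 1.0):
            raise ValueError("clade_restriction_prob must lie in [0, 1]")
        if self.within_species_divergence < 0 or self.between_species_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.within_species_divergence > self.between_species_divergence:
            raise ValueError("within-species divergence cannot exceed between-species divergence")


@dataclass(frozen=True)
class HgtEvent:
    family_id: str
    donor_genome: str
    recipient_genome: str
    donor_species: str
    recipient_species: str


@dataclass
class SimulationTruth:
    """Planted design: everything recovery tests score against."""

    config: SimConfig
    species_tree: TreeNode
    genome_species: dict[str, str]
    carriers: dict[str, frozenset[str]]               # family -> carrier genomes
    ancestral: dict[str, str]                         # family -> root sequence
    gene_family: dict[tuple[str, str], str]           # (genome, gene_id) -> family
    hgt_events: list[HgtEvent] = field(default_factory=list)

    @property
    def core_families(self) -> list[str]:
        n = len(self.genome_species)
        return sorted(f for f, c in self.carriers.items() if len(c) == n)

    def pairwise_divergence(self, g1: str, g2: str) -> float:
        """Expected substitutions/site separating two genomes (tree path)."""
        if g1 == g2:
            return 0.0
        t = self.species_tree
        return float(t.find(g1).distance(t.find(g2)))


def _species_id(i: int) -> str:
    return f"sp{i + 1}"


def _genome_id(i: int, j: int) -> str:
    return f"sp{i + 1}_g{j + 1}"


def _random_clade(names: list[str], height: float, rng: np.random.Generator) -> TreeNode:
    """Random resolved ultrametric subtree: all leaves at distance
    ``height`` from the subtree root, internal heights drawn uniformly."""
    if len(names) == 1:
        return TreeNode(name=names[0])
    order = [names[i] for i in rng.permutation(len(names))]
    k = int(rng.integers(1, len(names)))
    parts = [sorted(order[:k]), sorted(order[k:])]
    node = TreeNode()
    for part in parts:
        # heights skew deep so most same-clade pairs sit near the clade
        # root: mean within-species identity stays in the ~95-96% band
        h = float(rng.uniform(0.6, 0.95) * height) if len(part) > 1 else 0.0
        child = _random_clade(part, h, rng)
        child.length = height - h
        node.append(child)
    return node


def simulate_species_tree(
    n_species: int,
    genomes_per_species: int,
    between_div: float = 0.085,
    within_div: float = 0.046,
    seed: int = 0,
) -> TreeNode:
    """Ultrametric genome tree with ``n_species`` monophyletic clades.

    Each species clade is a random resolved ultrametric subtree whose
    root sits at height within_div/2, so same-species genome pairs are
    separated by at most ``within_div`` substitutions/site (pairs split
    at the clade root by exactly that); species stems of length
    (between_div − within_div)/2 place every cross-species pair at
    exactly ``between_div``.  Deterministic for a fixed seed.
    """
    if n_species < 1 or genomes_per_species < 1:
        raise ValueError("counts must be >= 1")
    if within_div < 0 or between_div < within_div:
        raise ValueError("require 0 <= within_div <= between_div")
    rng = np.random.default_rng(seed)
    clade_h = within_div / 2.0 if genomes_per_species > 1 else 0.0
    root_h = between_div / 2.0
    clades = []
    for i in range(n_species):
        names = [_genome_id(i, j) for j in range(genomes_per_species)]
        clade = _random_clade(names, clade_h, rng)
        if len(names) > 1:
            clade.name = _species_id(i)
        clades.append(clade)
    if n_species == 1:
        root = clades[0]
        root.length = None
        return root

    # resolved species-level ultrametric: deepest split at between_div/2,
    # shallower species splits kept well above the clade roots
    lo = clade_h + 0.6 * (root_h - clade_h)

    def join(items: list[TreeNode], heights: list[float], h: float) -> TreeNode:
        if len(items) == 1:
            items[0].length = h - heights[0]
            return items[0]
        order = rng.permutation(len(items))
        k = int(rng.integers(1, len(items)))
        node = TreeNode()
        for part in (order[:k], order[k:]):
            sub_items = [items[i] for i in part]
            sub_heights = [heights[i] for i in part]
            if len(part) > 1:
                low, high = max(lo, 0.75 * h), 0.95 * h
                hc = float(rng.uniform(low, high)) if low < high else high
                # degenerate configs (between ~ within) collapse gracefully
                hc = min(max(hc, max(sub_heights)), h)
            else:
                hc = sub_heights[0]
            child = join(sub_items, sub_heights, hc) if len(part) > 1 else sub_items[0]
            child.length = h - hc
            node.append(child)
        return node

    root = join(clades, [clade_h] * n_species, root_h)
    root.name = "root"
    root.length = None
    return root


def _evolve(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One JC step: each site substitutes w.p. (3/4)(1 − exp(−4t/3)) to a
    uniformly chosen different base.  ``parent`` is (n_seq, L) of 0..3."""
    if t <= 0:
        return parent.copy()
    p_sub = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    child = parent.copy()
    mask = rng.random(parent.shape) < p_sub
    # adding 1..3 mod 4 maps to one of the three other bases uniformly
    child[mask] = (child[mask] + rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)) % 4
    return child


def _decode(row: np.ndarray) -> str:
    return _BASES[row].tobytes().decode()


def simulate_genomes(config: SimConfig) -> tuple[GenomeSet, SimulationTruth]:
    """Generate a genome set and its ground truth from a :class:`SimConfig`.

    Each family starts from a uniform-random ancestral sequence and
    evolves along the species tree under Jukes–Cantor.  Core families are
    carried by every genome; each accessory family is carried
    Bernoulli(``accessory_presence_prob``) per genome, restricted to a
    single random species clade with probability
    ``clade_restriction_prob``.  Accessory families that end up in no
    genome are dropped from the truth.  If ``n_hgt_events`` > 0 the events
    are planted via :func:`plant_hgt` before returning.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_species_tree(
        cfg.n_species,
        cfg.genomes_per_species,
        cfg.between_species_divergence,
        cfg.within_species_divergence,
        seed=cfg.seed,
    )
    genomes = [
        _genome_id(i, j)
        for i in range(cfg.n_species)
        for j in range(cfg.genomes_per_species)
    ]
    genome_species = {g: g.split("_")[0] for g in genomes}
    species = [_species_id(i) for i in range(cfg.n_species)]

    n_fam = cfg.n_core_families + cfg.n_accessory_families
    fam_ids = [f"F{i:05d}" for i in range(n_fam)]
    L = cfg.gene_length

    # ancestral pool, then evolve all families in lock-step along the tree
    root_seqs = rng.integers(0, 4, size=(n_fam, L), dtype=np.uint8)
    tip_seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            child_state = _evolve(state, child.length or 0.0, rng)
            if child.is_tip():
                tip_seqs[child.name] = child_state
            else:
                descend(child, child_state)

    descend(tree, root_seqs)
    if tree.is_tip():  # single-genome edge case
        tip_seqs[tree.name] = root_seqs

    # presence design
    carriers: dict[str, frozenset[str]] = {}
    for k, fam in enumerate(fam_ids):
        if k < cfg.n_core_families:
            carriers[fam] = frozenset(genomes)
            continue
        if cfg.clade_restriction_prob > 0 and rng.random() < cfg.clade_restriction_prob:
            sp = species[int(rng.integers(cfg.n_species))]
            pool = [g for g in genomes if genome_species[g] == sp]
        else:
            pool = genomes
        mask = rng.random(len(pool)) < cfg.accessory_presence_prob
        carried = frozenset(g for g, m in zip(pool, mask) if m)
        if carried:
            carriers[fam] = carried

    fam_index = {f: i for i, f in enumerate(fam_ids)}
    records: list[GeneRecord] = []
    gene_family: dict[tuple[str, str], str] = {}
    for g in genomes:
        counter = 0
        for fam in fam_ids:
            if fam in carriers and g in carriers[fam]:
                gene_id = f"gene{counter:06d}"
                counter += 1
                records.append(GeneRecord(g, gene_id, _decode(tip_seqs[g][fam_index[fam]])))
                gene_family[(g, gene_id)] = fam

    truth = SimulationTruth(
        config=cfg,
        species_tree=tree,
        genome_species=genome_species,
        carriers=carriers,
        ancestral={f: _decode(root_seqs[fam_index[f]]) for f in carriers},
        gene_family=gene_family,
    )
    genome_set = GenomeSet(records)
    if cfg.n_hgt_events > 0:
        # derived seed kept distinct from the main stream
        genome_set, truth = plant_hgt(genome_set, truth, cfg.n_hgt_events, seed=cfg.seed + 1)
    return genome_set, truth


def plant_hgt(
    genomes: GenomeSet,
    truth: SimulationTruth,
    n_events: int,
    seed: int = 0,
) -> tuple[GenomeSet, SimulationTruth]:
    """Plant ``n_events`` cross-species transfers into core families.

    For each event a distinct core family is chosen; a donor genome and a
    recipient genome are drawn from different species clades, and the
    recipient's copy is replaced by a fresh Jukes–Cantor evolution of the
    donor's copy at the within-species divergence.  Returns a new
    GenomeSet and a truth with the events appended.
    """
    cfg = truth.config
    core = truth.core_families
    if n_events > len(core):
        raise ValueError(f"n_events={n_events} exceeds {len(core)} core families")
    if n_events == 0:
        return genomes, truth
    if cfg.n_species < 2:
        raise ValueError("planting HGT requires >= 2 species clades")
    rng = np.random.default_rng(seed)
    fams = [core[i] for i in rng.choice(len(core), size=n_events, replace=False)]
    species = sorted(set(truth.genome_species.values()))
    by_species: dict[str, list[str]] = {s: [] for s in species}
    for g, s in truth.genome_species.items():
        by_species[s].append(g)
    for s in by_species:
        by_species[s].sort()

    seq_of = {(r.genome_id, r.gene_id): r.sequence for r in genomes}
    gene_of: dict[tuple[str, str], str] = {}  # (genome, family) -> gene_id
    for (g, gid), fam in truth.gene_family.items():
        gene_of[(g, fam)] = gid

    events = list(truth.hgt_events)
    for fam in fams:
        d_sp, r_sp = (species[i] for i in rng.choice(len(species), size=2, replace=False))
        donor = by_species[d_sp][int(rng.integers(len(by_species[d_sp])))]
        recip = by_species[r_sp][int(rng.integers(len(by_species[r_sp])))]
        donor_seq = seq_of[(donor, gene_of[(donor, fam)])]
        enc = np.frombuffer(donor_seq.encode(), dtype=np.uint8).copy()
        code = np.zeros_like(enc)
        for v, b in enumerate(b"ACGT"):
            code[enc == b] = v
        new = _decode(_evolve(code[None, :], cfg.within_species_divergence, rng)[0])
        seq_of[(recip, gene_of[(recip, fam)])] = new
        events.append(HgtEvent(fam, donor, recip, d_sp, r_sp))

    new_records = [
        GeneRecord(r.genome_id, r.gene_id, seq_of[(r.genome_id, r.gene_id)])
        for r in genomes
    ]
    new_truth = replace_truth(truth, hgt_events=events)
    return GenomeSet(new_records), new_truth


def replace_truth(truth: SimulationTruth, **kw) -> SimulationTruth:
    return SimulationTruth(
        config=truth.config,
        species_tree=truth.species_tree,
        genome_species=truth.genome_species,
        carriers=truth.carriers,
        ancestral=truth.ancestral,
        gene_family=truth.gene_family,
        hgt_events=kw.get("hgt_events", truth.hgt_events),
    )


def write_simulation(
    genomes: GenomeSet,
    truth: SimulationTruth,
    outdir: str | Path,
    combined: bool = False,
) -> None:
    """Write FASTA (per genome or combined), truth TSVs, Newick tree, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fam_of = truth.gene_family
    if combined:
        genomes.to_fasta(outdir / "genes.fasta", family_of=fam_of)
    else:
        for gid, recs in genomes.by_genome().items():
            GenomeSet(recs).to_fasta(outdir / f"{gid}.fasta", family_of=fam_of)
    pd.DataFrame(
        [(f, g) for f, cs in sorted(truth.carriers.items()) for g in sorted(cs)],
        columns=["family_id", "genome_id"],
    ).to_csv(outdir / "truth_carriers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (e.family_id, e.donor_genome, e.recipient_genome, e.donor_species, e.recipient_species)
            for e in truth.hgt_events
        ],
        columns=["family_id", "donor_genome", "recipient_genome", "donor_species", "recipient_species"],
    ).to_csv(outdir / "truth_hgt.tsv", sep="\t", index=False)
    truth.species_tree.write(str(outdir / "species_tree.nwk"))
    (outdir / "config.json").write_text(json.dumps(truth.config.__dict__, indent=2) + "\n")
    pd.DataFrame(
        [(g, s) for g, s in sorted(truth.genome_species.items())],
        columns=["genome_id", "species"],
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
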