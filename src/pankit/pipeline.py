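"""End-to-end convenience layer over the analysis stages.

Chains ortholog clustering, partitioning, accumulation/openness, ANI and
reference clustering, per-core-gene NJ trees, tree-distance ranking,
consensus SNP calling and the HGT screen into one result object.  Every
stage remains independently callable from its own module; this wrapper
only fixes the plumbing between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from skbio import TreeNode

from .orthology import GenomeSet, OrthologCatalog, PresenceAbsenceMatrix, build_presence_absence, cluster_genes
from .pangenome import (
    AccumulationCurves,
    HeapsFit,
    PangenomePartition,
    PangenomeReport,
    accumulation_curves,
    fit_heaps,
    pangenome_report,
    partition_clusters,
)
from .phylogeny import ANIMatrix, ClusterAlignment, ani_matrix, build_nj, build_upgma, center_star_align, jc_distance_matrix
from .treecmp import TreeDistanceReport, select_representatives
from .variation import HgtCandidate, call_snps_catalog, detect_hgt

__all__ = ["PipelineResult", "run_pipeline", "core_cluster_alignments", "build_gene_trees"]


def core_cluster_alignments(
    genomes: GenomeSet, catalog: OrthologCatalog
) -> dict[str, ClusterAlignment]:
    """Genome-labelled alignments for clusters with exactly one copy in
    *every* genome (the tree-eligible core)."""
    all_genomes = genomes.genome_ids
    out: dict[str, ClusterAlignment] = {}
    for cid, members in catalog.items():
        per_genome: dict[str, list] = {}
        for rec in members:
            per_genome.setdefault(rec.genome_id, []).append(rec)
        if sorted(per_genome) != all_genomes or any(len(v) != 1 for v in per_genome.values()):
            continue
        recs = [per_genome[g][0] for g in all_genomes]
        if len({len(r.sequence) for r in recs}) == 1:
            out[cid] = ClusterAlignment(list(all_genomes), [r.sequence for r in recs])
        else:
            aln = center_star_align(recs)
            # relabel rows by genome (single copy per genome)
            relabel = {f"{r.genome_id}|{r.gene_id}": r.genome_id for r in recs}
            out[cid] = ClusterAlignment([relabel[i] for i in aln.ids], aln.rows)
    return out


def build_gene_trees(
    alignments: dict[str, ClusterAlignment],
    bootstrap: int = 0,
    seed: int = 0,
) -> dict[str, TreeNode]:
    """One NJ tree per cluster alignment (JC distances)."""
    trees = {}
    for cid, aln in alignments.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = jc_distance_matrix(aln)
        trees[cid] = build_nj(dm, bootstrap=bootstrap, alignment=aln if bootstrap else None, seed=seed)
    return trees


@dataclass
class PipelineResult:
    catalog: OrthologCatalog
    matrix: PresenceAbsenceMatrix
    partition: PangenomePartition
    report: PangenomeReport
    curves: AccumulationCurves
    heaps: HeapsFit
    ani: ANIMatrix
    reference_tree: TreeNode
    gene_trees: dict[str, TreeNode]
    tree_report: TreeDistanceReport | None
    snp_summary: "object"                    # per-cluster DataFrame
    snp_total: int
    hgt_candidates: list[HgtCandidate] = field(default_factory=list)


def run_pipeline(
    genomes: GenomeSet,
    groups: dict[str, str] | None = None,
    min_identity: float = 70.0,
    min_coverage: float = 75.0,
    n_perm: int = 10,
    top_frac: float = 0.05,
    bootstrap: int = 0,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on a genome-tagged gene collection.

    ``groups`` maps genome -> species; when omitted, species are inferred
    from ANI connected components at the 95% cutoff.
    """
    catalog = cluster_genes(genomes, min_identity=min_identity, min_coverage=min_coverage)
    matrix = build_presence_absence(catalog, genomes.genome_ids)
    partition = partition_clusters(matrix)
    report = pangenome_report(matrix, partition, genomes)
    curves = accumulation_curves(matrix, n_perm=n_perm, seed=seed)
    heaps = fit_heaps(curves)
    ani = ani_matrix(genomes, catalog)
    reference = build_upgma(ani.to_distance_matrix())
    if groups is None:
        comps = ani.species_components(95.0)
        groups = {g: f"group{k + 1}" for k, comp in enumerate(comps) for g in sorted(comp)}
    alignments = core_cluster_alignments(genomes, catalog)
    gene_trees = build_gene_trees(alignments, bootstrap=bootstrap, seed=seed)
    tree_report = None
    if gene_trees:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree_report = select_representatives(gene_trees, reference, top_frac=top_frac)
    records, snp_summary = call_snps_catalog(catalog, cluster_ids=sorted(alignments))
    del records
    snp_total = int(snp_summary["n_polymorphic"].sum()) if len(snp_summary) else 0
    hgt = detect_hgt(catalog, groups, gene_trees) if gene_trees else []
    return PipelineResult(
        catalog=catalog,
        matrix=matrix,
        partition=partition,
        report=report,
        curves=curves,
        heaps=heaps,
        ani=ani,
        reference_tree=reference,
        gene_trees=gene_trees,
        tree_report=tree_report,
        snp_summary=snp_summary,
        snp_total=snp_total,
        hgt_candidates=hgt,
    )
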