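# pankit

Bacterial pan-genome analysis in Python: ortholog clustering,
core/softcore/shell/cloud partitioning, Heaps'-law openness, ANI-based
species clustering, per-gene phylogenies ranked by tree distances,
consensus SNP calling, a simplified horizontal-gene-transfer screen, and
accessory-genome enrichment — together with a synthetic multi-species
pan-genome generator that carries full ground truth for validating every
stage.

## The problem

Comparative genomics of a bacterial genus (think *Geobacillus*-style
collections: a few species, several genomes each) routinely asks:

* How large is the **pan-genome** (the union of gene families across all
  genomes) and the **core genome** (families shared by all), and is the
  pan-genome *open* — does every new genome keep contributing genes?
* Do genomes cluster into species at the conventional **95% average
  nucleotide identity (ANI)** boundary?
* Which core genes build phylogenies most similar to the genome-level
  reference tree, and hence best represent the genus's history?
* How much single-nucleotide variation do core genes carry, and which
  gene copies look **horizontally transferred** between species?
* Which functional categories are enriched in the accessory genome of
  each species?

pankit implements this entire workflow on plain gene-level FASTA input,
and ships a simulator so every answer can be scored against a known
truth.

## Models and statistics

* **Ortholog clustering** — single-linkage connected components of the
  pairwise similarity graph; an edge joins two genes when their global
  alignment reaches ≥ 70% identity and ≥ 75% coverage (configurable).
  At scale, candidate pairs are screened by shared sampled 16-mers and
  every accepted edge is verified by alignment.
* **Partition** (occupancy of *n* genomes): core = *n*; softcore
  ≥ ⌈0.95 *n*⌉; cloud ≤ 2; shell = the rest.
* **Openness** — over randomized genome orderings (default 10), the
  median number of new gene clusters contributed by the *N*-th genome is
  fitted as n(N) = k·N^(−α) by least squares in log–log space; α < 1
  marks an open pan-genome.
* **ANI** — mean percent identity over ortholog clusters in which both
  genomes are single-copy; species are components of the ANI ≥ 95%
  graph, and the reference tree is UPGMA on 100 − ANI.
* **Gene trees** — Jukes–Cantor distances, d = −(3/4)·ln(1 − 4p/3), and
  Saitou–Nei neighbor joining (optional column-resampling bootstrap).
* **Tree distances** — Robinson–Foulds, matching split (exact Hungarian
  matching of bipartitions), and quartet distance (explicit enumeration
  of all C(n,4) subsets).  Gene trees are ranked against the reference
  by matching-split and quartet rank sum; the top 5% are selected.
* **SNPs** — per core cluster, a consensus of strict-majority bases; a
  SNP is a non-ambiguous column where ≥ 1 genome deviates.
* **HGT screen** — a gene copy is a candidate when its best identity to
  a foreign species group exceeds its own-group mean by > 2.5 points and
  the gene tree places it inside a clade dominated by that group.
* **Enrichment** — upper-tail hypergeometric test with
  Benjamini–Hochberg FDR; effect size is the rich factor (set hits /
  background hits per category).

## Worked example

Simulate 2 species × 4 genomes (60 core + 120 accessory families, one
planted cross-species transfer) and run the whole pipeline:

```python
from pankit import SimConfig, simulate_genomes, run_pipeline

cfg = SimConfig(n_species=2, genomes_per_species=4,
                n_core_families=60, n_accessory_families=120,
                accessory_presence_prob=0.3, gene_length=300,
                n_hgt_events=1, seed=11)
genomes, truth = simulate_genomes(cfg)
result = run_pipeline(genomes, groups=truth.genome_species, seed=0)

r = result.report
print(f"pan {r.n_pan}  core {r.n_core}  shell {r.n_shell}  cloud {r.n_cloud}")
print(f"Heaps: alpha={result.heaps.alpha:.3f}  open={result.heaps.open_flag}")
print(f"SNP columns: {result.snp_total}")
for c in result.hgt_candidates:
    print(f"HGT: {c.cluster_id} {c.recipient_genome} <- {c.best_foreign_group} "
          f"gap {c.identity_gap:.1f}%")
```

prints

```
pan 175  core 60  shell 51  cloud 64
Heaps: alpha=1.385  open=False
SNP columns: 2766
HGT: C00036 sp2_g1 <- sp1  gap 7.4%
```

All 60 simulated core families are recovered as core clusters; 175
clusters match the 175 families that ended up carried by at least one
genome.  The decay exponent α = 1.39 > 1 says this small
Bernoulli-accessory design behaves as a closed pan-genome (new genomes
quickly stop contributing genes).  The single flagged HGT copy is
exactly the planted one: genome `sp2_g1`'s copy of that family is 7.4
identity points closer to clade `sp1` than to its own species, and its
gene tree places it inside the `sp1` clade.

The same stages are available from the shell:

```bash
pankit simulate --species 4 --genomes-per-species 8 --core 600 \
    --accessory 1200 --hgt 5 --seed 1 --outdir sim/
pankit cluster --fasta sim/sp1_g1.fasta ... --outdir out/
pankit pangenome --matrix out/matrix.tsv --perms 10 --seed 1 --outdir out/
pankit ani --fasta ... --catalog out/catalog.tsv --out out/ani.tsv
pankit snps --fasta ... --catalog out/catalog.tsv --outdir out/
pankit hgt --fasta ... --catalog out/catalog.tsv --groups sim/groups.tsv --outdir out/
```

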