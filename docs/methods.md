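# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are validated on, the numerical conventions, and the design
choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Input model

The pipeline's universal input is a set of genome-tagged gene
nucleotide sequences (`GenomeSet` of `GeneRecord`s) read from FASTA with
headers `>{genome_id}|{family_id}|{gene_id}` (the family field is
ground-truth annotation written by the simulator; `>{genome}|{gene}` is
also accepted).  Gene calling, genome download and protein-level
annotation are upstream of this package.

## Ortholog clustering

Families are the connected components (single linkage) of the graph
whose edges join gene pairs whose global end-to-end alignment (match +1,
mismatch −1, gap −2, via Biopython's `PairwiseAligner`) reaches both
cutoffs — identity = matches / aligned columns ≥ 70% and coverage =
both-residue columns / shorter length ≥ 75%.  These defaults follow
common pan-genome clustering practice and are configurable; single
linkage replaces Markov-clustering-based orthology deliberately: it is
deterministic, dependency-free, and exact on the simulator's indel-free
families (verified by the adjusted-Rand-index = 1 recovery test).

Scaling: testing all O(n²) pairs is infeasible for tens of thousands of
genes, so candidate edges are nominated by shared sampled k-mers
(16-mers taken every 8 positions; two genes sharing one sampled 16-mer
become a candidate pair) and each candidate is verified by alignment
before linking; union–find skips candidates already connected.
Equal-length pairs take a gapless fast path (the gapless identity
decides clearly above or clearly below the cutoff; a ±10-point band
falls back to the full aligner).  The screen assumes homologous genes
retain at least one exact shared sampled 16-mer, comfortably true above
~75% identity at kilobase lengths; inputs of ≤ 64 genes use exhaustive
pairwise testing (the regime the brute-force transitive-closure oracle
test checks).

Paralogs (two genes of one genome in one cluster) are allowed; the
presence/absence matrix is binary regardless of copy number.

## Partition and openness

With *n* genomes, a cluster present in p genomes is labelled
core (p = n), softcore (p ≥ ⌈0.95 n⌉), cloud (p ≤ 2), else shell, with
precedence core > softcore > cloud > shell for the degenerate overlaps
at tiny n.  ⌈0.95 n⌉ is the integer-safe reading of "95–100%"; at
n ≤ 20 the softcore tier collapses onto the core, which is why
per-species tables at n = 8 satisfy core + shell + cloud = pan exactly.
Reports expose the *inclusive* softcore tier (core ⊆ softcore), so
softcore + shell + cloud = pan always holds.

Accumulation curves add one genome at a time over randomized orderings
(default 10 permutations).  The openness fit regresses
log(median new genes contributed by genome N) on log N for N = 2..n:
n(N) = k·N^(−α), α = −slope, k = exp(intercept), open ⇔ α < 1.  The
new-genes decay reading is used because printed exponents of ~0.2
combined with "open when α < 1" only cohere under it; fitting total pan
size against the same rule would declare every pan-genome open.  Zero
medians are replaced by a 0.5 pseudocount to keep the log defined
without discarding points; the median (not mean) across permutations
feeds the fit for robustness to ordering outliers.  N = 1 is excluded:
the first genome's "new genes" is its entire gene set, not a discovery
increment.

## ANI and trees

ANI(a, b) is the mean percent identity over clusters where both genomes
contribute exactly one gene — an orthoANI-flavoured, aligner-free
definition that differs from fragment-BLAST ANI in mechanics but uses
the same 95% species convention.  Pairs sharing no single-copy cluster
are reported missing with a warning.  Species delimitation takes the
connected components of the ANI ≥ 95% graph; the reference tree is
UPGMA (average linkage) on 100 − ANI.

Cluster alignments: equal-length clusters are aligned gaplessly
(positional homology — exact for the simulator's no-indel families and
the convention used consistently by ANI, SNP calling and gene trees);
mixed-length clusters go through a deterministic center-star procedure
(center = longest member, ties by smallest key; every member aligned to
the center pairwise and merged on the center's coordinates).

Distances are Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3) with p the mismatch
fraction over pairwise ungapped columns; p ≥ 3/4 is saturated and capped
at 5 substitutions/site with a warning.  Trees are Saitou–Nei neighbor
joining (scikit-bio's implementation, negative branches clamped to
zero; exact on additive matrices, which the test suite verifies against
randomly generated trees), with taxa sorted lexicographically first so
tie-breaks are deterministic.  Bootstrap support (off by default in the
library, 100 in the CLI for desk-scale runtime; the conventional 1000
is a flag away) is the percentage of column-resampled replicates whose
NJ tree contains each internal bipartition.

## Tree comparison and representative genes

Splits are stored as leaf bitmasks normalized to the side not
containing the first leaf.  Robinson–Foulds is the symmetric difference
of split sets.  Matching split solves the minimum-weight perfect
matching between the two split sets exactly (Hungarian algorithm;
pairing cost min(|A∩D|+|B∩C|, |A∩C|+|B∩D|), null-split cost
min(|A|,|B|)).  Quartet distance enumerates all C(n,4) subsets; a
quartet's topology comes from the four-point condition on topological
path lengths, unresolved quartets (multifurcations) differ from any
resolved quartet and match each other.  Both nontrivial metrics are
validated against factorial brute force / split-containment oracles.

Gene trees over the single-copy-in-every-genome core are ranked against
the reference by matching-split rank + quartet rank (average ranks on
ties).  Rank-sum was chosen because no canonical combination of the two
metrics exists; single-metric ranking is available by flag.  The
selected set is the top ⌈0.05·n⌉ by combined rank with boundary ties
included — ties may push the set above 5%, which is preferred to
dropping tied genes arbitrarily.

## SNP calling

Per core cluster, the consensus takes each column's strict-majority
base; columns with any gap or a plurality tie are ambiguous and never
yield calls (ambiguity is excluded rather than IUPAC-coded to keep
counts well-defined).  The primary statistic is the number of
polymorphic columns (≥ 1 genome deviating from consensus); per-genome
deviation counts are reported alongside.  Totals are invariant to row
order and genome relabelling, and per-cluster counts sum to the
pipeline total (both tested).

## HGT screen

The screen is an explicitly simplified best-match + tree-incongruence
analogue of contig-level transfer detectors, not a port of any of them.
For each single-copy cluster member: mean identity to same-group copies
and best identity to each foreign group come from the cluster
alignment; a copy is flagged when (i) best foreign identity − own-group
mean > 2.5 points and (ii) the smallest clade enclosing the copy in the
gene tree is majority-occupied by that foreign group.  The 2.5-point
margin is a noise floor: identity estimates on ~1 kb genes carry about
a 1-point sampling error, so the best of ~24 foreign identities can
exceed the own-group mean by ~2 points by chance, while genuine
cross-species transfers at a 95%/92% within/between split show gaps of
4 points and more.  Groups with a single genome are skipped (undefined
within-group mean).

Detectability limits: a transferred copy that is later overwritten by
an independent lineage at between-species divergence carries no donor
affinity and is (correctly) not flagged.  Conversely both copies of a
recent transfer — recipient (large gap) and donor (small gap, placed
beside the recipient's copy in the gene tree) — can be flagged, as in
any best-match scheme; event recovery is therefore scored at the gene
(cluster) level.

## Enrichment

Fold extension counts annotated clusters per category within pan,
softcore (inclusive tier) and core, and reports pan/subset ratios at
one display decimal (full precision kept internally; display rounding
never feeds back into computation).  Set enrichment uses the upper-tail
hypergeometric probability P(X ≥ k) with Benjamini–Hochberg FDR across
categories and the rich factor (set hits / background hits) as effect
size; the default background is the annotated pan-genome catalog.  The
test and background are stated as assumptions in the output rather than
inherited from any particular annotation service.

## Synthetic data generator

`simdata` emulates the statistical structure the analysis assumes:

* **Species tree** — ultrametric; each species clade is a random
  resolved subtree with its root at height within_div/2 (internal node
  heights drawn U(0.6, 0.95) × parent height, skewed deep so the mean
  within-species identity stays near the 95–96% band while the deepest
  same-species pairs sit at exactly within_div); the species-level
  topology is likewise a random resolved ultrametric with its deepest
  split at between_div/2 and shallower species splits kept above the
  clade roots.  Resolved structure at both levels matters: it gives
  long genes something real to recover and avoids the arbitrary
  polytomy resolutions that would otherwise dominate tree distances.
* **Sequences** — per family, a uniform-random ancestor of
  `gene_length` bp (default 900) evolves along the tree under
  Jukes–Cantor (per-site substitution probability
  (3/4)(1 − e^(−4t/3))).  No indels, no rate heterogeneity, equal base
  frequencies: alignments are trivially gap-free and the closed-form
  identity 1/4 + (3/4)e^(−4d/3) calibrates every divergence test.
* **Presence design** — core families in every genome; accessory
  families i.i.d. Bernoulli per genome (default p = 0.25), optionally
  restricted to one random species clade with probability
  `clade_restriction_prob` (default 0 — the i.i.d. baseline produces
  shell and cloud tiers; restriction produces species-specific sets).
* **Divergence defaults** — within_species 0.046 and between_species
  0.085 substitutions/site put the within/between identity split at
  ~95.5–96.5% vs ~92%, bracketing the 95% species cutoff the way
  multi-species genus collections do.
* **HGT planting** — a donor and recipient genome from different
  species; the recipient's copy of a core family is replaced by a fresh
  evolution of the donor's copy at within-species divergence; all
  events recorded in the truth object.

What the simulator does *not* emulate — indels, recombination within
genes, rate variation, paralogy, genome coordinates/synteny, annotation
noise — bounds what passing tests show: recovery results demonstrate
the pipeline's correctness under its stated model, not robustness to
real-data artifacts such as fragmented assemblies or domain shuffling.

## Validation studies and problem sizes

The standard end-to-end study (test suite and `scripts/acceptance.py`)
is 4 species × 8 genomes, 600 core + 1200 accessory families at 900 bp
and 5 planted transfers (~29k genes); it completes in a few minutes on
one CPU.  SNP totals are checked against the model expectation computed
two independent ways: exact pattern enumeration on ≤ 4-genome trees and
a 10⁶-column Monte-Carlo sample of the column process for the 32-genome
tree, with a 3-standard-error acceptance band combining site-level and
Monte-Carlo variance.  The representative-gene study contrasts 10
low-noise 1800 bp genes against 190 noisy 300 bp genes evolved on a
shared species tree and asserts only the direction (selected genes are
longer at the median).  Smaller configurations (2 × 4 genomes, tens of
families, 300–600 bp) back the per-module recovery tests.

## Known limitations

* Single-linkage clustering can chain families connected by a bridging
  gene; at the default cutoffs and simulator divergences this does not
  occur, but highly mosaic real genes could merge clusters.
* The k-mer screen is a recall heuristic; adversarial homolog pairs
  with ≥ 70% identity but no shared sampled 16-mer would be missed.
* ANI from single-copy ortholog identity tracks, but does not equal,
  fragment-based ANI on real genomes.
* The HGT screen detects recent, clade-discordant transfers of whole
  genes; ancient or within-species transfers and partial-gene
  recombination are out of reach by design.
* The openness exponent depends on the accessory presence model; the
  i.i.d. Bernoulli design decays geometrically and therefore reads as
  closed for most parameter choices — openness claims about real data
  require real accumulation curves.
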