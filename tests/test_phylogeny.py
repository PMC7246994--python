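"""ANI, center-star alignment, JC distances, NJ and UPGMA trees."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from helpers import (
    alignment_score,
    enumerate_global_alignments,
    frozenset_splits,
    random_ultrametric_tree,
    random_unrooted_tree,
    tree_distances,
)
from pankit import (
    ClusterAlignment,
    GeneRecord,
    SimConfig,
    ani_matrix,
    build_nj,
    build_upgma,
    center_star_align,
    cluster_genes,
    jc_distance_matrix,
    jc_expected_identity,
    simulate_genomes,
)
from pankit.phylogeny import JC_SATURATION_CAP


@pytest.fixture(scope="module")
def sim_ani(small_sim):
    genomes, truth = small_sim
    catalog = cluster_genes(genomes)
    return ani_matrix(genomes, catalog), truth


class TestANI:
    def test_self_identity_and_symmetry(self, sim_ani):
        ani, _ = sim_ani
        arr = ani.df.to_numpy()
        assert np.allclose(np.diag(arr), 100.0)
        assert np.allclose(arr, arr.T)

    def test_pairwise_ani_matches_jc_expectation(self, sim_ani):
        """Every pair's ANI sits near the JC identity implied by its tree
        path length, and within-species pairs stay above between-species."""
        ani, truth = sim_ani
        within, between, errors = [], [], []
        gids = ani.genome_ids
        for i, a in enumerate(gids):
            for b in gids[i + 1 :]:
                v = ani.value(a, b)
                exp = 100 * jc_expected_identity(truth.pairwise_divergence(a, b))
                errors.append(abs(v - exp))
                (within if truth.genome_species[a] == truth.genome_species[b] else between).append(v)
        # >= 60 shared 300-bp clusters per pair: 3 SE is ~0.5% identity
        assert max(errors) < 0.8
        assert np.mean(errors) < 0.2
        assert min(within) > max(between)

    def test_species_recovered_at_95_cutoff(self, sim_ani):
        ani, truth = sim_ani
        comps = ani.species_components(95.0)
        expected = {}
        for g, s in truth.genome_species.items():
            expected.setdefault(s, set()).add(g)
        assert sorted(map(sorted, comps)) == sorted(map(sorted, expected.values()))

def recs_genomeset(recs):
    from pankit import GenomeSet

    return GenomeSet(recs)


def test_ani_missing_pairs_warn():
    recs = [
        GeneRecord("g1", "a", "ACGTACGTACGTACGT"),
        GeneRecord("g2", "b", "ACGTACGTACGTACGT"),
        GeneRecord("g3", "c", "TTTTGGGGCCCCAAAA"),
    ]
    gs = recs_genomeset(recs)
    catalog = cluster_genes(recs, min_identity=90.0)
    with pytest.warns(UserWarning, match="no single-copy cluster"):
        ani = ani_matrix(gs, catalog)
    assert math.isnan(ani.value("g1", "g3"))
    assert ani.value("g1", "g2") == pytest.approx(100.0)


class TestCenterStar:
    def test_identical_members_unchanged(self):
        recs = [GeneRecord(f"g{i}", "x", "ACGTACGT") for i in range(3)]
        aln = center_star_align(recs)
        assert aln.rows == ["ACGTACGT"] * 3

    def test_simulator_families_align_gap_free(self, small_sim):
        genomes, truth = small_sim
        cat = cluster_genes(genomes)
        members = max(cat.clusters, key=len)
        aln = center_star_align(members)
        assert aln.n_columns == truth.config.gene_length
        assert all("-" not in r for r in aln.rows)

    def test_star_objective_matches_pairwise_optima(self):
        """Merged rows preserve each member's optimal score against the
        center (checked by exhaustive alignment enumeration)."""
        seqs = ["ACGTTACG", "ACGTACG", "ACTTTACG"]
        recs = [GeneRecord(f"g{i}", "x", s) for i, s in enumerate(seqs)]
        aln = center_star_align(recs)
        center_row = aln.rows[0]  # g0 holds the longest (8 bp, smallest key)
        for i, s in enumerate(seqs):
            if i == 0:
                continue
            best = max(
                alignment_score(ra, rb)
                for ra, rb in enumerate_global_alignments(seqs[0], s)
            )
            # score of the merged pair, skipping double-gap columns
            merged = sum(
                0 if (x == "-" and y == "-") else alignment_score(x, y)
                for x, y in zip(center_row, aln.rows[i])
            )
            assert merged == best

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            center_star_align([])


class TestJCDistance:
    def test_identical_rows_zero(self):
        aln = ClusterAlignment(["a", "b"], ["ACGT" * 25] * 2)
        assert jc_distance_matrix(aln)["a", "b"] == 0.0

    def test_p_ten_percent(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        d = jc_distance_matrix(ClusterAlignment(["a", "b"], [a, b]))["a", "b"]
        assert round(d, 4) == 0.1073

    def test_saturation_capped_with_warning(self):
        aln = ClusterAlignment(["a", "b"], ["AAAA" * 5, "CCCC" * 5])
        with pytest.warns(UserWarning, match="saturation"):
            d = jc_distance_matrix(aln)
        assert d["a", "b"] == JC_SATURATION_CAP

    def test_gap_columns_excluded_pairwise(self):
        aln = ClusterAlignment(["a", "b"], ["AC-T", "ACGT"])
        assert jc_distance_matrix(aln)["a", "b"] == 0.0

    def test_zero_comparable_columns_raise(self):
        aln = ClusterAlignment(["a", "b"], ["A--", "-AA"])
        with pytest.raises(ValueError):
            jc_distance_matrix(aln)


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ["a", "b", "c", "d"],
        )
        tree = build_nj(dm)
        splits = frozenset_splits(tree)
        assert splits == {frozenset({"c", "d"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})
        internal = [n for n in tree.non_tips(include_self=False)]
        assert internal[0].length == pytest.approx(1.0)

    def test_three_taxa_three_point_formula(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = build_nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3})

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            names = [f"t{i}" for i in range(n)]
            source = random_unrooted_tree(names, rng)
            ids, d = tree_distances(source)
            tree = build_nj(DistanceMatrix(d, ids))
            assert frozenset_splits(tree) == frozenset_splits(source)
            _, d2 = tree_distances(tree)
            assert np.allclose(d2, d, atol=1e-8)

    def test_asymmetric_matrix_raises(self):
        with pytest.raises(ValueError):
            build_nj(np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))

    def test_bootstrap_on_invariant_alignment_is_100(self):
        aln = ClusterAlignment(["a", "b", "c", "d"], ["ACGTACGTAC"] * 4)
        dm = jc_distance_matrix(aln)
        tree = build_nj(dm, bootstrap=25, alignment=aln, seed=3)
        supports = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_newick_roundtrip_preserves_everything(self, tmp_path, rng):
        names = [f"x{i}_y" for i in range(6)]
        tree = random_unrooted_tree(names, rng)
        path = tmp_path / "t.nwk"
        tree.write(str(path))
        back = TreeNode.read(str(path), convert_underscores=False)
        assert frozenset_splits(back) == frozenset_splits(tree)
        ids1, d1 = tree_distances(tree)
        ids2, d2 = tree_distances(back)
        assert ids1 == ids2 and np.allclose(d1, d2)


class TestUPGMA:
    def test_two_taxa_heights(self):
        tree = build_upgma(DistanceMatrix([[0, 4], [4, 0]], ["a", "b"]))
        assert {t.name: t.length for t in tree.tips()} == pytest.approx({"a": 2, "b": 2})

    def test_random_ultrametric_inputs_reconstructed(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            names = [f"t{i}" for i in range(n)]
            source = random_ultrametric_tree(names, rng)
            ids, d = tree_distances(source)
            tree = build_upgma(DistanceMatrix(d, ids))
            _, d2 = tree_distances(tree)
            assert np.allclose(d2, d, atol=1e-8)

    def test_heights_monotone_to_root(self, rng):
        names = [f"t{i}" for i in range(7)]
        source = random_ultrametric_tree(names, rng)
        ids, d = tree_distances(source)
        tree = build_upgma(DistanceMatrix(d, ids))
        # depth from node to any descendant tip is the node height;
        # parent height must be >= child height
        def height(node):
            tip = next(iter(node.tips())) if not node.is_tip() else node
            return node.distance(tip)
        for node in tree.non_tips(include_self=True):
            for child in node.children:
                assert height(node) >= height(child) - 1e-12

    def test_simulated_ani_clusters_into_four_clades(self):
        cfg = SimConfig(
            n_species=4, genomes_per_species=3, n_core_families=40,
            n_accessory_families=0, gene_length=400, seed=31,
        )
        genomes, truth = simulate_genomes(cfg)
        ani = ani_matrix(genomes, cluster_genes(genomes))
        tree = build_upgma(ani.to_distance_matrix())
        # the four species must be monophyletic in the UPGMA tree
        splits = frozenset_splits(tree)
        by_species = {}
        for g, s in truth.genome_species.items():
            by_species.setdefault(s, set()).add(g)
        leaves = sorted(truth.genome_species)
        ref = leaves[0]
        for members in by_species.values():
            want = frozenset(members) if ref not in members else frozenset(set(leaves) - members)
            assert want in splits
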