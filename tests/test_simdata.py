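"""Synthetic pan-genome generator: tree shape, divergence calibration,
carrier bookkeeping, determinism, HGT planting."""

import math

import numpy as np
import pytest

from pankit import (
    GenomeSet,
    SimConfig,
    jc_expected_identity,
    plant_hgt,
    simulate_genomes,
    simulate_species_tree,
    write_simulation,
)
from pankit.orthology import hamming_identity


class TestSpeciesTree:
    def test_single_species_zero_divergence_is_star(self):
        tree = simulate_species_tree(1, 3, 0.2, 0.0, seed=5)
        tips = list(tree.tips())
        assert len(tips) == 3
        assert all(t.length == 0.0 for t in tips)

    def test_four_by_eight_has_32_leaves_in_4_clades(self):
        tree = simulate_species_tree(4, 8, 0.085, 0.046, seed=1)
        tips = [t.name for t in tree.tips()]
        assert len(tips) == 32
        by_species = {}
        for name in tips:
            by_species.setdefault(name.split("_")[0], set()).add(name)
        assert len(by_species) == 4
        for members in by_species.values():  # each species is monophyletic
            assert len(members) == 8
            lca = tree.lca(sorted(members))
            assert {t.name for t in lca.tips()} == members

    def test_species_level_structure_bounded_by_between_divergence(self):
        tree = simulate_species_tree(4, 8, 0.085, 0.046, seed=1)
        cross = []
        tips = list(tree.tips())
        for i, a in enumerate(tips):
            for b in tips[i + 1 :]:
                if a.name.split("_")[0] != b.name.split("_")[0]:
                    cross.append(a.distance(b))
        assert max(cross) == pytest.approx(0.085)  # deepest split
        assert min(cross) > 0.046                  # species stay separable

    def test_pairwise_path_lengths_match_divergences(self):
        tree = simulate_species_tree(2, 2, 0.08, 0.04)
        d_within = tree.find("sp1_g1").distance(tree.find("sp1_g2"))
        d_between = tree.find("sp1_g1").distance(tree.find("sp2_g1"))
        assert d_within == pytest.approx(0.04)
        assert d_between == pytest.approx(0.08)

    def test_resolved_clades_bounded_by_within_divergence(self):
        tree = simulate_species_tree(1, 6, 0.1, 0.05, seed=2)
        tips = list(tree.tips())
        dists = [
            a.distance(b) for i, a in enumerate(tips) for b in tips[i + 1 :]
        ]
        assert max(dists) == pytest.approx(0.05)   # deepest split at clade root
        assert all(d <= 0.05 + 1e-12 for d in dists)
        assert min(dists) < 0.05                   # clades carry real structure

    def test_same_seed_identical_newick(self):
        t1 = simulate_species_tree(3, 4, 0.1, 0.05, seed=9)
        t2 = simulate_species_tree(3, 4, 0.1, 0.05, seed=9)
        assert str(t1) == str(t2)

    def test_bad_counts_raise(self):
        with pytest.raises(ValueError):
            simulate_species_tree(0, 3, 0.1, 0.05)
        with pytest.raises(ValueError):
            simulate_species_tree(2, 2, 0.01, 0.05)  # within > between


class TestSimulateGenomes:
    def test_zero_divergence_gives_identical_copies(self):
        cfg = SimConfig(
            n_species=2, genomes_per_species=3, n_core_families=5,
            n_accessory_families=0, gene_length=120,
            within_species_divergence=0.0, between_species_divergence=0.0, seed=3,
        )
        genomes, truth = simulate_genomes(cfg)
        by_fam = {}
        for rec in genomes:
            fam = truth.gene_family[rec.key]
            by_fam.setdefault(fam, set()).add(rec.sequence)
        assert all(len(seqs) == 1 for seqs in by_fam.values())

    def test_forced_presence_makes_accessory_universal(self):
        cfg = SimConfig(
            n_species=2, genomes_per_species=2, n_core_families=3,
            n_accessory_families=10, accessory_presence_prob=1.0,
            gene_length=100, seed=4,
        )
        genomes, truth = simulate_genomes(cfg)
        n = len(genomes.genome_ids)
        assert all(len(c) == n for c in truth.carriers.values())

    def test_carrier_bookkeeping_matches_output(self, small_sim):
        genomes, truth = small_sim
        observed = {}
        for rec in genomes:
            fam = truth.gene_family[rec.key]
            observed.setdefault(fam, set()).add(rec.genome_id)
        assert {f: frozenset(c) for f, c in observed.items()} == dict(truth.carriers)

    def test_core_families_carried_by_every_genome(self, small_sim):
        genomes, truth = small_sim
        n = len(genomes.genome_ids)
        assert len(truth.core_families) == truth.config.n_core_families
        for fam in truth.core_families:
            assert len(truth.carriers[fam]) == n

    def test_jc_divergence_calibration(self):
        """Mean observed identity between two genomes at path d = 0.05
        matches 1/4 + (3/4)e^(-4d/3) within 3 binomial SE."""
        d = 0.05
        cfg = SimConfig(
            n_species=1, genomes_per_species=2, n_core_families=50,
            n_accessory_families=0, gene_length=900,
            within_species_divergence=d, between_species_divergence=d, seed=7,
        )
        genomes, truth = simulate_genomes(cfg)
        by_genome = genomes.by_genome()
        g1, g2 = genomes.genome_ids
        fam_of = truth.gene_family
        seq2 = {fam_of[r.key]: r.sequence for r in by_genome[g2]}
        idents = [
            hamming_identity(r.sequence, seq2[fam_of[r.key]]) / 100.0
            for r in by_genome[g1]
        ]
        n_sites = 50 * 900
        expected = jc_expected_identity(d)
        assert expected == pytest.approx(0.9516, abs=1e-4)
        se = math.sqrt(expected * (1 - expected) / n_sites)
        assert abs(np.mean(idents) - expected) < 3 * se

    def test_determinism_byte_identical_fasta(self, tmp_path):
        cfg = SimConfig(
            n_species=2, genomes_per_species=2, n_core_families=8,
            n_accessory_families=12, gene_length=150, n_hgt_events=1, seed=99,
        )
        out = []
        for tag in ("a", "b"):
            genomes, truth = simulate_genomes(cfg)
            d = tmp_path / tag
            write_simulation(genomes, truth, d, combined=True)
            out.append((d / "genes.fasta").read_bytes())
        assert out[0] == out[1]

    def test_roundtrip_fasta(self, tmp_path, small_sim):
        genomes, truth = small_sim
        write_simulation(genomes, truth, tmp_path, combined=True)
        back = GenomeSet.from_fasta(tmp_path / "genes.fasta")
        assert {(r.genome_id, r.gene_id, r.sequence) for r in back} == {
            (r.genome_id, r.gene_id, r.sequence) for r in genomes
        }

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(accessory_presence_prob=1.5)
        with pytest.raises(ValueError):
            SimConfig(within_species_divergence=0.1, between_species_divergence=0.05)
        with pytest.raises(ValueError):
            SimConfig(n_core_families=0)


class TestPlantHgt:
    def test_zero_events_is_identity(self, small_sim):
        genomes, truth = small_sim
        out, out_truth = plant_hgt(genomes, truth, 0, seed=1)
        assert out is genomes and out_truth is truth

    def test_event_moves_recipient_toward_donor_clade(self, hgt_sim):
        genomes, truth = hgt_sim
        seqs = {r.key: r.sequence for r in genomes}
        gene_of = {(g, f): gid for (g, gid), f in truth.gene_family.items()}
        for ev in truth.hgt_events:
            recip_seq = seqs[(ev.recipient_genome, gene_of[(ev.recipient_genome, ev.family_id)])]
            donor_clade = [g for g, s in truth.genome_species.items() if s == ev.donor_species]
            own_clade = [
                g for g, s in truth.genome_species.items()
                if s == ev.recipient_species and g != ev.recipient_genome
            ]
            to_donor = min(
                hamming_identity(recip_seq, seqs[(g, gene_of[(g, ev.family_id)])])
                for g in donor_clade
            )
            to_own = max(
                hamming_identity(recip_seq, seqs[(g, gene_of[(g, ev.family_id)])])
                for g in own_clade
            )
            assert to_donor > to_own

    def test_same_seed_same_events(self, small_sim):
        genomes, truth = small_sim
        _, t1 = plant_hgt(genomes, truth, 3, seed=5)
        _, t2 = plant_hgt(genomes, truth, 3, seed=5)
        assert t1.hgt_events == t2.hgt_events

    def test_too_many_events_raise(self, small_sim):
        genomes, truth = small_sim
        with pytest.raises(ValueError):
            plant_hgt(genomes, truth, truth.config.n_core_families + 1, seed=0)

    def test_events_cross_species(self, hgt_sim):
        _, truth = hgt_sim
        assert len(truth.hgt_events) == 2
        for ev in truth.hgt_events:
            assert ev.donor_species != ev.recipient_species
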