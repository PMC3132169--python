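"""Planted-truth genome, library and read simulation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from oakbes._util import revcomp
from oakbes.synthetic_data import (
    CapacityError,
    GenomeSpec,
    LibrarySimSpec,
    RepeatFamilySpec,
    SsrPlantSpec,
    build_genome,
    sample_clones,
    simulate_bes_reads,
    simulate_marker_screen,
)


class TestBuildGenome:
    def test_zero_divergence_copies_are_identical(self):
        spec = GenomeSpec(
            genome_len=50_000,
            repeat_families=[RepeatFamilySpec("F1", 150, 5, 0.0)],
            cp_seq_len=0,
        )
        genome, truth = build_genome(spec, seed=1)
        assert len(genome) == 50_000
        assert len(truth.repeats) == 5
        for s, e, label in truth.repeats:
            assert label == "F1"
            assert e - s + 1 == 150
            assert genome[s - 1 : e] == truth.consensus["F1"]

    def test_divergent_copies_have_expected_pairwise_identity(self):
        # two copies each mutated at 5% diverge at ~2*0.05*(1-0.05) of sites
        spec = GenomeSpec(
            genome_len=200_000,
            repeat_families=[RepeatFamilySpec("F1", 2_000, 10, 0.05)],
            cp_seq_len=0,
        )
        genome, truth = build_genome(spec, seed=2)
        copies = [genome[s - 1 : e] for s, e, _ in truth.repeats]
        idents = [
            np.mean([a == b for a, b in zip(copies[i], copies[j])])
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        expected = (1 - 0.05) ** 2 + 0.05**2 / 3  # same sub hit by chance 1/3
        assert np.mean(idents) == pytest.approx(expected, abs=0.005)

    def test_deterministic_given_seed(self):
        spec = GenomeSpec(
            genome_len=30_000,
            repeat_families=[RepeatFamilySpec("F1", 100, 3, 0.1)],
            ssr_plants=[SsrPlantSpec("AG", 10, 2)],
            n_genes=2,
            cp_seq_len=1_000,
        )
        g1, t1 = build_genome(spec, seed=9)
        g2, t2 = build_genome(spec, seed=9)
        assert g1 == g2
        assert t1.repeats == t2.repeats and t1.ssrs == t2.ssrs and t1.genes == t2.genes

    def test_truth_intervals_never_overlap(self):
        spec = GenomeSpec(
            genome_len=40_000,
            repeat_families=[RepeatFamilySpec("F1", 200, 20, 0.0)],
            ssr_plants=[SsrPlantSpec("AT", 12, 10)],
            n_genes=5,
            gene_len=1_000,
            cp_seq_len=0,
        )
        _, truth = build_genome(spec, seed=3)
        ivals = truth.all_intervals()
        assert all(ivals[i][1] < ivals[i + 1][0] for i in range(len(ivals) - 1))
        assert ivals[0][0] >= 1 and ivals[-1][1] <= 40_000

    def test_overfull_genome_raises_capacity_error(self):
        spec = GenomeSpec(
            genome_len=1_000,
            repeat_families=[RepeatFamilySpec("F1", 300, 5, 0.0)],
            cp_seq_len=0,
        )
        with pytest.raises(CapacityError):
            build_genome(spec, seed=1)


class TestSampleClones:
    def test_all_empty_when_rate_one(self):
        spec = LibrarySimSpec(n_clones=50, insert_mean=1_000, insert_sd=0,
                              insert_min=1_000, insert_max=1_000, empty_rate=1.0, seed=4)
        assert all(c.is_empty for c in sample_clones(10_000, spec))

    def test_fixed_insert_length(self):
        spec = LibrarySimSpec(n_clones=20, insert_mean=500, insert_sd=0,
                              insert_min=500, insert_max=500, empty_rate=0.0, seed=4)
        assert all(c.length == 500 for c in sample_clones(10_000, spec))

    def test_empty_fraction_within_binomial_error(self):
        spec = LibrarySimSpec(n_clones=10_000, insert_mean=500, insert_sd=50,
                              insert_min=300, insert_max=700, empty_rate=0.07, seed=4)
        clones = sample_clones(10_000_000, spec)
        frac = sum(c.is_empty for c in clones) / len(clones)
        # 0.07 +- 4 binomial sigmas (sigma ~ 0.0026)
        assert abs(frac - 0.07) < 0.011

    def test_insert_bounds_respected(self):
        spec = LibrarySimSpec(n_clones=500, insert_mean=1_000, insert_sd=400,
                              insert_min=600, insert_max=1_500, seed=6)
        clones = sample_clones(100_000, spec)
        assert all(600 <= c.length <= 1_500 for c in clones)
        assert all(1 <= c.start and c.end <= 100_000 for c in clones)


class TestSimulateReads:
    def _spec(self, **kw):
        defaults = dict(n_clones=1, insert_mean=600, insert_sd=0, insert_min=600,
                        insert_max=600, empty_rate=0.0, cp_rate=0.0,
                        read_len_mean=100, read_retention=1.0, seed=0)
        defaults.update(kw)
        return LibrarySimSpec(**defaults)

    def test_read_coordinates_and_strands(self, rng):
        from oakbes.synthetic_data import CloneInterval

        genome = "".join(rng.choice(list("ACGT"), 2_000))
        clone = CloneInterval("C000001", 1001, 1600, False, False)
        reads, truth = simulate_bes_reads([clone], self._spec(), genome)
        by_end = {r.end_label: r for r in reads}
        assert by_end["F"].sequence == genome[1000:1100]
        assert by_end["R"].sequence == revcomp(genome[1500:1600])
        assert truth[by_end["F"].read_id] == (1001, 1100, "+")
        assert truth[by_end["R"].read_id] == (1501, 1600, "-")

    def test_full_retention_gives_full_pairing(self, rng):
        from oakbes.bes_io import pair_reads

        genome = "".join(rng.choice(list("ACGT"), 50_000))
        spec = self._spec(n_clones=30, insert_mean=1_000, insert_min=1_000, insert_max=1_000)
        clones = sample_clones(50_000, spec)
        reads, _ = simulate_bes_reads(clones, spec, genome)
        mates = pair_reads(reads)
        assert mates.paired_fraction == 1.0
        assert len(reads) == 60

    def test_study_retention_rate_recovered(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 200_000))
        spec = self._spec(n_clones=5_000, insert_mean=1_000, insert_min=1_000,
                          insert_max=1_000, read_retention=0.6696, seed=13)
        clones = sample_clones(200_000, spec)
        reads, _ = simulate_bes_reads(clones, spec, genome)
        frac = len(reads) / (2 * len(clones))
        # binomial sigma ~ 0.0047; allow 4 sigmas
        assert abs(frac - 0.6696) < 0.019

    def test_cp_reads_come_from_organelle_molecule(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 20_000))
        cp = "".join(rng.choice(list("ACGT"), 5_000))
        spec = self._spec(n_clones=40, insert_mean=1_000, insert_min=1_000,
                          insert_max=1_000, cp_rate=1.0, seed=7)
        clones = sample_clones(20_000, spec)
        reads, truth = simulate_bes_reads(clones, spec, genome, cp_sequence=cp)
        assert reads
        for r in reads:
            s, e, strand = truth[r.read_id]
            assert strand in ("cp+", "cp-")
            segment = cp[s - 1 : e]
            assert r.sequence == (segment if strand == "cp+" else revcomp(segment))


class TestMarkerScreen:
    def test_whole_genome_clone_hits_every_marker(self):
        from oakbes.synthetic_data import CloneInterval

        clone = CloneInterval("C1", 1, 10_000, False, False)
        hits = simulate_marker_screen([clone], 100, 10_000, seed=1)
        assert (hits >= 1).all()

    def test_mean_hits_tracks_depth_and_zero_class_is_poissonian(self):
        genome_len = 1_000_000
        spec = LibrarySimSpec(n_clones=200, insert_mean=10_000, insert_sd=0,
                              insert_min=10_000, insert_max=10_000,
                              empty_rate=0.0, cp_rate=0.0, seed=21)
        clones = sample_clones(genome_len, spec)
        hits = simulate_marker_screen(clones, 3_000, genome_len, seed=22)
        assert np.mean(hits) == pytest.approx(2.0, abs=0.15)
        assert np.mean(hits == 0) == pytest.approx(math.exp(-2.0), abs=0.035)
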