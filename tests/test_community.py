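"""Community simulation: genomes, profiles, reads, provenance."""

import numpy as np
import pytest

from metaseval.community import (AbundanceProfile, SimulationConfig,
                                 generate_genomes, make_community,
                                 make_profile, parse_read_id,
                                 plant_conserved_segments, simulate_paired,
                                 simulate_reads, total_megabases)
from metaseval.io import write_reads
from metaseval.seq import hamming, revcomp


class TestGenerateGenomes:
    def test_single_genome_construction(self):
        (g,) = generate_genomes(1, (5000, 6000), seed=3)
        assert 5000 <= len(g) <= 6000
        assert set(g.sequence) <= set("ACGT")
        assert all([g.taxonomy.strain, g.taxonomy.species,
                    g.taxonomy.genus, g.taxonomy.phylum])

    def test_zero_divergence_family_is_identical(self):
        a, b = generate_genomes(2, (2000, 2000), n_strain_families=1,
                                strain_divergence=0.0, seed=5)
        assert a.sequence == b.sequence
        assert a.taxonomy.strain != b.taxonomy.strain
        assert a.taxonomy.species == b.taxonomy.species

    def test_strain_divergence_matches_requested_rate(self):
        # binomial concentration: at L=100000 and rate 0.01 the observed
        # Hamming fraction lies in [0.008, 0.012] except with tiny probability
        a, b = generate_genomes(2, (100_000, 100_000), n_strain_families=1,
                                strain_divergence=0.01, seed=7)
        frac = hamming(a.sequence, b.sequence) / len(a)
        assert 0.008 <= frac <= 0.012

    def test_family_shares_higher_taxonomy_only(self):
        gs = generate_genomes(4, (2000, 2000), n_strain_families=1,
                              strain_divergence=0.05, seed=1)
        fam, singles = gs[:2], gs[2:]
        assert fam[0].taxonomy.genus == fam[1].taxonomy.genus
        assert singles[0].taxonomy.species != singles[1].taxonomy.species

    def test_unique_ids_and_bad_args(self):
        gs = generate_genomes(6, (1500, 2500), seed=0)
        assert len({g.genome_id for g in gs}) == 6
        with pytest.raises(ValueError):
            generate_genomes(0, (2000, 2000))
        with pytest.raises(ValueError):
            generate_genomes(2, (2000, 2000), strain_divergence=0.5)


class TestConservedSegments:
    def test_segments_are_shared_across_genomes(self, two_genomes):
        out = plant_conserved_segments(two_genomes, n_segments=1,
                                       segment_length=300,
                                       copies_per_segment=2, divergence=0.0,
                                       seed=9)
        a, b = out[0].sequence, out[1].sequence
        assert len(a) == 5000 and len(b) == 5000
        # zero divergence: an identical 300-mer occurs in both genomes
        shared = any(a[i:i + 300] in b for i in range(len(a) - 299))
        assert shared


class TestMakeProfile:
    def test_uniform_and_simhc(self):
        gs = generate_genomes(4, (2000, 2000), seed=6)
        prof = make_profile("simHC", gs)
        assert all(abs(w - 0.25) < 1e-12 for w in prof.weights.values())

    def test_simlc_dominant_split(self):
        gs = generate_genomes(5, (1500, 1500), seed=2)
        prof = make_profile("simLC", gs)
        w = [prof.weights[g.genome_id] for g in gs]
        assert w[0] == 0.5
        assert all(abs(x - 0.125) < 1e-12 for x in w[1:])

    def test_uniform_thirty_strains(self):
        gs = generate_genomes(30, (1500, 1500), n_strain_families=1,
                              family_size=30, strain_divergence=0.01, seed=4)
        prof = make_profile("uniform", gs)
        assert all(abs(w - 1 / 30) < 1e-12 for w in prof.weights.values())

    def test_simmc_structure_and_errors(self):
        gs = generate_genomes(6, (1500, 1500), seed=2)
        prof = make_profile("simMC", gs)
        w = [prof.weights[g.genome_id] for g in gs]
        assert all(abs(x - 0.15) < 1e-12 for x in w[:3])
        assert abs(sum(w) - 1) < 1e-9
        with pytest.raises(ValueError):
            make_profile("simMC", gs[:2])
        with pytest.raises(ValueError):
            make_profile("weird", gs)


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, small_genome):
        prof = make_profile("uniform", [small_genome])
        reads = simulate_reads([small_genome], prof,
                               SimulationConfig(n_reads=100, error_model="none",
                                                seed=1))
        g = small_genome.sequence
        assert len(reads) == 100
        for r in reads:
            assert r.bases in g or revcomp(r.bases) in g

    def test_provenance_round_trip_recovers_coordinates(self, small_genome):
        prof = make_profile("uniform", [small_genome])
        reads = simulate_reads([small_genome], prof,
                               SimulationConfig(n_reads=50, error_model="none",
                                                seed=3))
        g = small_genome.sequence
        for r in reads:
            gid, start, strand, mate = parse_read_id(r.read_id)
            assert gid == r.true_source == "gA"
            frag = g[start:start + 36]
            assert r.bases == (frag if strand == "+" else revcomp(frag))

    def test_two_genome_counts_near_binomial(self, two_genomes):
        prof = AbundanceProfile({"gA": 0.5, "gB": 0.5})
        reads = simulate_reads(two_genomes, prof,
                               SimulationConfig(n_reads=10_000,
                                                error_model="none", seed=11))
        n_a = sum(r.true_source == "gA" for r in reads)
        assert 4700 <= n_a <= 5300  # 99.99% binomial interval

    def test_multinomial_consistency_three_sigma(self):
        gs = generate_genomes(4, (2000, 2000), seed=8)
        prof = make_profile("simLC", gs)
        n = 100_000
        reads = simulate_reads(gs, prof, SimulationConfig(
            n_reads=n, error_model="none", seed=13))
        counts = {g.genome_id: 0 for g in gs}
        for r in reads:
            counts[r.true_source] += 1
        for gid, w in prof.weights.items():
            se = (w * (1 - w) / n) ** 0.5
            assert abs(counts[gid] / n - w) <= 3 * se

    def test_error_model_substitution_rate(self, small_genome):
        prof = make_profile("uniform", [small_genome])
        reads = simulate_reads([small_genome], prof,
                               SimulationConfig(n_reads=20_000, seed=5))
        g = small_genome.sequence
        mism = pos_total = 0
        for r in reads[:5000]:
            _, start, strand, _ = parse_read_id(r.read_id)
            frag = g[start:start + 36]
            truth = frag if strand == "+" else revcomp(frag)
            mism += sum(a != b for a, b in zip(r.bases, truth))
            pos_total += 36
        rate = mism / pos_total
        assert 0.003 < rate < 0.009  # ramp mean is 0.0055

    def test_determinism_byte_identical_output(self, two_genomes, tmp_path):
        prof = make_profile("uniform", two_genomes)
        cfg = SimulationConfig(n_reads=500, seed=21)
        for name in ("a.fastq", "b.fastq"):
            write_reads(tmp_path / name,
                        simulate_reads(two_genomes, prof, cfg))
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_short_genome_excluded_all_excluded_errors(self, small_genome):
        prof = make_profile("uniform", [small_genome])
        with pytest.raises(ValueError):
            simulate_reads([small_genome], prof,
                           SimulationConfig(n_reads=10, read_length=9000,
                                            error_model="none", seed=0))

    def test_dataset_scale_arithmetic(self):
        assert total_megabases(36_000_000, 36) == 1296.0


class TestSimulatePaired:
    def cfg(self, n, **kw):
        kw.setdefault("error_model", "none")
        return SimulationConfig(n_reads=n, paired=True, insert_length=500,
                                seed=2, **kw)

    def test_pair_count_and_geometry(self, small_genome):
        prof = make_profile("uniform", [small_genome])
        pairs = simulate_paired([small_genome], prof, self.cfg(40))
        assert len(pairs) == 40
        g = small_genome.sequence
        for m1, m2 in pairs:
            gid1, start, strand, mi1 = parse_read_id(m1.read_id)
            gid2, start2, strand2, mi2 = parse_read_id(m2.read_id)
            assert (gid1, start, strand) == (gid2, start2, strand2)
            assert (mi1, mi2) == (1, 2)
            frag = g[start:start + 500]
            if strand == "-":
                frag = revcomp(frag)
            assert m1.bases == frag[:36]
            assert m2.bases == revcomp(frag[-36:])
            # implied mate-2 start on fragment coordinates
            assert 500 - 36 == len(frag) - 36

    def test_insert_too_small_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_reads=5, paired=True, insert_length=70)
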