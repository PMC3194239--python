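"""De Bruijn graph construction, cleaning, unitig extraction, paired merging."""

import numpy as np
import pytest

from metaseval.assembler import (Contig, assemble, build_graph, clean_graph,
                                 clip_tips, decode_kmer, encode_kmer,
                                 extract_unitigs, filter_contigs, k_sweep,
                                 merge_with_pairs, pop_bubbles, revcomp_kmer)
from metaseval.community import (SimulatedRead, SimulationConfig,
                                 format_read_id, generate_genomes,
                                 make_profile, simulate_reads)
from metaseval.seq import canonical, random_sequence, revcomp


def read(bases, rid="r|0|+|0"):
    return SimulatedRead(rid, bases, "r")


class TestKmerCoding:
    @pytest.mark.parametrize("kmer", ["ACGTA", "TTTTT", "GATTACA"])
    def test_round_trip_and_revcomp(self, kmer):
        k = len(kmer)
        v = encode_kmer(kmer)
        assert decode_kmer(v, k) == kmer
        assert decode_kmer(revcomp_kmer(v, k), k) == revcomp(kmer)


class TestBuildGraph:
    def test_single_read_enumerates_kmers(self):
        g = build_graph([read("AACCGAT")], k=5)
        expect = {encode_kmer(canonical(s)) for s in ("AACCG", "ACCGA", "CCGAT")}
        assert len(expect) == 3 and set(g.data) == expect

    def test_multiplicity_filter_drops_singletons(self):
        g = build_graph([read("AACCGAT"), read("AACCG")], k=5,
                        min_multiplicity=2)
        assert set(g.data) == {encode_kmer(canonical("AACCG"))}

    def test_reverse_complement_reads_give_identical_structure(self, rng):
        seqs = [random_sequence(rng, 36) for _ in range(50)]
        g1 = build_graph(seqs, k=21)
        g2 = build_graph(seqs + [revcomp(s) for s in seqs], k=21)
        assert set(g1.data) == set(g2.data)
        for key in g1.data:
            assert g1.data[key] >> 32 == g2.data[key] >> 32  # same edge bits

    def test_k_validation(self):
        with pytest.raises(ValueError):
            build_graph([read("ACGT" * 9)], k=22)
        with pytest.raises(ValueError):
            build_graph([read("ACGTACG")], k=9)


class TestExtractUnitigs:
    def test_linear_path_spells_one_contig(self, rng):
        s = random_sequence(rng, 60)
        g = build_graph([s], k=21)
        tigs = extract_unitigs(g)
        assert len(tigs) == 1
        assert tigs[0].sequence in (s, revcomp(s))
        assert len(tigs[0]) == len(g) + 20  # m + k - 1

    def test_branch_node_breaks_unitigs(self):
        # two sequences sharing an interior k-1 overlap create a branch
        core = "ACGTACGTACGTACGTACGTG"  # 21-mer
        s1 = "A" * 8 + core + "C" * 8
        s2 = "G" * 8 + core + "T" * 8
        g = build_graph([s1, s2], k=21)
        tigs = extract_unitigs(g)
        assert len(tigs) > 1
        joined = {t.sequence for t in tigs}
        assert not any(s1 in t or revcomp(s1) in t for t in joined)

    def test_unitig_kmers_are_graph_nodes(self, rng):
        reads = [random_sequence(rng, 36) for _ in range(200)]
        g = build_graph(reads, k=25)
        tigs = extract_unitigs(g)
        seen = set()
        for t in tigs:
            for i in range(len(t) - 24):
                key = encode_kmer(canonical(t.sequence[i:i + 25]))
                assert key in g.data
                seen.add(key)
        assert seen == set(g.data)  # every node in exactly one unitig

    def test_error_free_coverage_recovers_genome(self, rng):
        genome = random_sequence(rng, 5000)
        reads = []
        for i in range(0, 5000 - 36, 7):  # ~5x tiling
            for off in (0, 2, 4):
                if i + off + 36 <= 5000:
                    reads.append(genome[i + off:i + off + 36])
        tigs = filter_contigs(extract_unitigs(build_graph(reads, k=25)), 50)
        covered = sum(len(t) for t in tigs)
        assert covered >= 0.99 * 5000
        for t in tigs:
            assert t.sequence in genome or revcomp(t.sequence) in genome

    def test_strand_symmetry_of_assembly(self, rng):
        reads = [random_sequence(rng, 36) for _ in range(300)]
        a = [t.sequence for t in assemble(reads, 21, min_length=21)]
        b = [t.sequence for t in assemble([revcomp(r) for r in reads], 21,
                                          min_length=21)]
        assert a == b

    def test_determinism(self, rng):
        reads = [random_sequence(rng, 36) for _ in range(100)]
        t1 = assemble(reads, 21, min_length=21)
        t2 = assemble(list(reads), 21, min_length=21)
        assert [(t.contig_id, t.sequence) for t in t1] == \
               [(t.contig_id, t.sequence) for t in t2]


class TestGraphCleaning:
    def test_tip_is_clipped(self, rng):
        s = random_sequence(rng, 200)
        tip = s[:40] + "T" if s[40] != "T" else s[:40] + "A"
        g = build_graph([s, s, tip], k=21)
        before = len(g)
        removed = clip_tips(g)
        assert removed > 0
        tigs = extract_unitigs(g)
        assert any(t.sequence in (s, revcomp(s)) for t in tigs)
        assert len(g) < before

    def test_weaker_bubble_side_is_popped(self, rng):
        s = random_sequence(rng, 200)
        pos = 100
        alt_base = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
        variant = s[:pos] + alt_base + s[pos + 1:]
        g = build_graph([s, s, s, variant, variant], k=21)
        pop_bubbles(g)
        tigs = extract_unitigs(g)
        assert any(t.sequence in (s, revcomp(s)) for t in tigs)
        assert not any(t.sequence in (variant, revcomp(variant)) for t in tigs)

    def test_clean_graph_preserves_clean_linear_path(self, rng):
        s = random_sequence(rng, 300)
        g = build_graph([s], k=21)
        clean_graph(g)
        tigs = extract_unitigs(g)
        assert len(tigs) == 1 and tigs[0].sequence in (s, revcomp(s))


class TestFilterContigs:
    def test_length_threshold(self):
        tigs = [Contig(f"c{i}", "A" * n + "C", 25) for i, n in
                enumerate([48, 49, 50])]
        kept = filter_contigs(tigs, 50)
        assert [len(t) for t in kept] == [50, 51]

    def test_empty_and_identity(self):
        assert filter_contigs([], 50) == []
        tigs = [Contig("c", "ACGT" * 20, 25)]
        assert filter_contigs(tigs, 50) == tigs


class TestKSweep:
    def test_single_k_equals_direct_assembly(self, rng):
        reads = [random_sequence(rng, 36) for _ in range(200)]
        sweep = k_sweep(reads, ks=[25], min_length=25)
        direct = assemble(reads, 25, min_length=25)
        assert [t.sequence for t in sweep[25]] == [t.sequence for t in direct]

    def test_default_sweep_has_seven_runs_and_tags(self, rng):
        genome = random_sequence(rng, 3000)
        reads = [genome[i:i + 36] for i in range(0, 3000 - 36, 3)]
        sweep = k_sweep(reads)
        assert sorted(sweep) == [21, 23, 25, 27, 29, 31, 33]
        for k, tigs in sweep.items():
            assert all(t.k_source == k for t in tigs)

    def test_high_coverage_error_free_n50_increases_with_k(self):
        # with 36 bp reads a k of 33 leaves 4 sampling positions per k-mer,
        # so "high coverage" here means deep enough that even k=33 k-mer
        # coverage (read coverage / 9) leaves no gaps
        from metaseval.evaluation import n50
        gs = generate_genomes(1, (20_000, 20_000), seed=31)
        prof = make_profile("uniform", gs)
        reads = simulate_reads(gs, prof, SimulationConfig(
            n_reads=int(20_000 * 150 / 36), error_model="none", seed=32))
        sweep = k_sweep(reads, ks=[21, 33])
        assert n50([len(t) for t in sweep[33]]) >= n50([len(t) for t in sweep[21]])


class TestMergeWithPairs:
    @pytest.fixture
    def merge_fixture(self, rng):
        genome = random_sequence(rng, 1000)
        contig_a = Contig("a", genome[:500], 25)

        def pairs_for(b_start, n, insert=600):
            out = []
            for i in range(n):
                p1 = 10 + i * 30
                m1 = genome[p1:p1 + 36]
                m2 = revcomp(genome[p1 + insert - 36:p1 + insert])
                out.append((
                    SimulatedRead(format_read_id("g", p1, "+", 1), m1, "g"),
                    SimulatedRead(format_read_id("g", p1, "+", 2), m2, "g")))
            return out

        return genome, contig_a, pairs_for

    def test_below_min_pairs_no_merge(self, merge_fixture):
        genome, a, pairs_for = merge_fixture
        b = Contig("b", genome[480:], 25)
        merged = merge_with_pairs([a, b], pairs_for(480, 9), insert_length=600)
        assert sorted(len(c) for c in merged) == [500, 520]

    def test_positive_gap_stays_split(self, merge_fixture):
        genome, a, pairs_for = merge_fixture
        b = Contig("b", genome[550:], 25)  # implied gap +50
        merged = merge_with_pairs([a, b], pairs_for(550, 12), insert_length=600)
        assert sorted(len(c) for c in merged) == [450, 500]

    def test_exact_overlap_merges_to_genome(self, merge_fixture):
        genome, a, pairs_for = merge_fixture
        b = Contig("b", genome[480:], 25)  # 20 bp exact overlap
        merged = merge_with_pairs([a, b], pairs_for(480, 12), insert_length=600)
        assert len(merged) == 1
        assert merged[0].sequence in (genome, revcomp(genome))
        assert len(merged[0]) == 500 + 520 - 20
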