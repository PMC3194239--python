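"""Seed-and-extend alignment: anchors, chaining, banded extension, oracle."""

import numpy as np
import pytest

from metaseval.aligner import (AnchorMatch, ReferenceIndex, align_contig,
                               chain_anchors, extend_chain,
                               smith_waterman_score)
from metaseval.assembler import Contig
from metaseval.seq import random_sequence, revcomp
from tests.conftest import ref


def mutate_with_indels(rng, s, rate):
    out = []
    for ch in s:
        r = rng.random()
        if r < rate:
            kind = rng.random()
            if kind < 1 / 3:
                out.append("ACGT"[("ACGT".index(ch) + int(rng.integers(1, 4))) % 4])
            elif kind < 2 / 3:
                continue
            else:
                out.append("ACGT"[int(rng.integers(0, 4))])
                out.append(ch)
        else:
            out.append(ch)
    return "".join(out)


class TestAnchors:
    def test_planted_fifteen_mer_found(self, rng):
        seq = random_sequence(rng, 400)
        index = ReferenceIndex([ref("r1", "A" + seq + "C" * 800)])
        query = seq[3:18]
        hits = index.anchors(query, "+")
        assert any(a.ref_start == 4 and a.contig_start == 0 for a in hits)

    def test_absent_query_has_no_anchors(self, rng):
        index = ReferenceIndex([ref("r1", random_sequence(rng, 2000))])
        probe = random_sequence(np.random.default_rng(1234), 40)
        assert index.anchors(probe, "+") == [] or all(
            a.length < 40 for a in index.anchors(probe, "+"))

    def test_maximal_match_merges_seed_runs(self, rng):
        genome = random_sequence(rng, 2000)
        index = ReferenceIndex([ref("r1", genome)])
        query = genome[100:180]
        hits = [a for a in index.anchors(query, "+") if a.ref_start == 100]
        assert len(hits) == 1 and hits[0].length == 80

    def test_reverse_strand_anchor(self, rng):
        genome = random_sequence(rng, 2000)
        index = ReferenceIndex([ref("r1", genome)])
        query = revcomp(genome[500:520])
        hits = index.anchors(revcomp(query), "-")
        assert any(a.ref_start == 500 and a.length >= 20 for a in hits)


class TestChaining:
    def mk(self, q, r, ln):
        return AnchorMatch(q, "r1", r, ln, "+")

    def test_colinear_anchors_chain_and_pass_cluster_size(self):
        chains = chain_anchors([self.mk(0, 100, 15), self.mk(25, 125, 16)])
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_single_short_anchor_discarded(self):
        assert chain_anchors([self.mk(0, 100, 15)]) == []

    def test_far_diagonals_split_chains(self):
        a = self.mk(0, 100, 20)
        b = self.mk(30, 1000, 20)  # diagonal drift 870 >> max_gap
        chains = chain_anchors([a, b], min_cluster_size=15)
        assert len(chains) == 2

    def test_brute_force_linkage_on_small_sets(self, rng):
        # pairwise linkage rule cross-checked against the chainer's grouping
        for _ in range(20):
            anchors = [self.mk(int(rng.integers(0, 300)),
                               int(rng.integers(0, 300)),
                               int(rng.integers(15, 30))) for _ in range(6)]
            chains = chain_anchors(anchors, min_cluster_size=1, max_gap=50)
            got = sorted(tuple(sorted((a.contig_start, a.ref_start)
                                      for a in ch)) for ch in chains)
            # every returned chain must be internally linkable step by step
            for ch in chains:
                for prev, nxt in zip(ch, ch[1:]):
                    assert nxt.contig_start >= prev.contig_start
                    assert nxt.ref_start >= prev.ref_start
                    assert nxt.contig_start - prev.contig_end <= 50
                    assert nxt.ref_start - prev.ref_end <= 50
                    assert abs(nxt.diagonal - prev.diagonal) <= 50
            # and all anchors are preserved across chains
            assert sum(len(c) for c in chains) == 6


class TestExtension:
    def test_exact_substring_is_perfect(self, rng):
        genome = random_sequence(rng, 1000)
        index = ReferenceIndex([ref("r1", genome)])
        contig = Contig("c", genome[200:400], 25)
        (aln,) = align_contig(contig, index)
        assert aln.local_acc == 1.0
        assert aln.align_len == 200
        assert (aln.insertions, aln.deletions) == (0, 0)
        assert (aln.ref_start, aln.ref_end) == (200, 400)

    def test_single_substitution_counts(self, rng):
        genome = random_sequence(rng, 1200)
        piece = list(genome[100:200])
        piece[50] = "ACGT"[("ACGT".index(piece[50]) + 1) % 4]
        contig = Contig("c", "".join(piece), 25)
        index = ReferenceIndex([ref("r1", genome)])
        alns = align_contig(contig, index)
        best = max(alns, key=lambda a: a.score)
        assert (best.matches, best.mismatches) == (99, 1)
        assert best.local_acc == pytest.approx(0.99)

    def test_oracle_equivalence_sample(self, rng):
        # banded seed-and-extend must reach the unbanded local optimum
        for _ in range(30):
            genome = random_sequence(rng, 1000)
            lo = int(rng.integers(0, 500))
            ln = int(rng.integers(80, 300))
            q = mutate_with_indels(rng, genome[lo:lo + ln], rng.random() * 0.1)
            if len(q) < 60:
                continue
            if rng.random() < 0.5:
                q = revcomp(q)
            alns = align_contig(Contig("c", q, 25),
                                ReferenceIndex([ref("r1", genome)]))
            if not alns:
                continue  # below anchor sensitivity; covered elsewhere
            sw = max(smith_waterman_score(q, genome),
                     smith_waterman_score(revcomp(q), genome))
            assert max(a.score for a in alns) == sw

    def test_counts_span_both_intervals(self, rng):
        genome = random_sequence(rng, 1000)
        q = mutate_with_indels(rng, genome[100:400], 0.05)
        alns = align_contig(Contig("c", q, 25),
                            ReferenceIndex([ref("r1", genome)]))
        for a in alns:
            a.validate(len(q), len(genome))


class TestAlignContig:
    def test_contig_in_two_references_reported_twice(self, rng):
        shared = random_sequence(rng, 300)
        r1 = ref("r1", random_sequence(rng, 800) + shared)
        r2 = ref("r2", shared + random_sequence(rng, 800))
        index = ReferenceIndex([r1, r2])
        alns = align_contig(Contig("c", shared[50:250], 25), index)
        assert {a.ref_id for a in alns} >= {"r1", "r2"}

    def test_unrelated_contig_unaligned(self, rng):
        index = ReferenceIndex([ref("r1", random_sequence(rng, 2000))])
        probe = random_sequence(np.random.default_rng(77), 120)
        assert align_contig(Contig("c", probe, 25), index) == []

    def test_internal_repeat_yields_two_alignments(self, rng):
        unit = random_sequence(rng, 250)
        genome = (random_sequence(rng, 300) + unit
                  + random_sequence(rng, 300) + unit
                  + random_sequence(rng, 300))
        index = ReferenceIndex([ref("r1", genome)])
        alns = align_contig(Contig("c", unit[20:230], 25), index)
        assert len([a for a in alns if a.ref_id == "r1"]) >= 2

    def test_strand_consistency(self, rng):
        genome = random_sequence(rng, 1200)
        q = genome[300:600]
        index = ReferenceIndex([ref("r1", genome)])
        fwd = align_contig(Contig("c", q, 25), index)
        rev = align_contig(Contig("c", revcomp(q), 25), index)
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert a.strand != b.strand
            assert (a.ref_start, a.ref_end) == (b.ref_start, b.ref_end)
            assert a.contig_start == len(q) - b.contig_end
            assert (a.matches, a.mismatches) == (b.matches, b.mismatches)
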