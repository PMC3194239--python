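"""Seed-and-extend local alignment of contigs to reference genomes.

Exact-match anchors of at least ``min_anchor_length`` bases are found on
both strands through a reference seed index, grouped into co-linear chains
(anchor clusters shorter than ``min_cluster_size`` summed bases are
discarded), and every surviving chain is extended with a banded local
dynamic-programming alignment around the chain's diagonals.  All alignments
are reported, not just the best one.

Scoring is match +1, mismatch -1, gap -2 (linear).  Within its band the
extension computes the optimal local (Smith-Waterman) alignment, so inter-
anchor gaps are closed optimally and chain ends are extended outward as far
as they improve the score; the band is widened once if the optimal in-band
path presses against the band boundary.

Reference coordinates are always reported on the forward strand, 0-based
half-open; contig coordinates are on the contig's own forward strand, with
the strand flag carrying orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembler import Contig
from .community import ReferenceGenome
from .seq import revcomp

MATCH, MISMATCH, GAP = 1, -1, -2
NEG = -(10 ** 9)


@dataclass(frozen=True)
class AnchorMatch:
    """A maximal exact match between a contig (query orientation) and a reference."""

    contig_start: int
    ref_id: str
    ref_start: int
    length: int
    strand: str

    @property
    def contig_end(self) -> int:
        return self.contig_start + self.length

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.contig_start


@dataclass(frozen=True)
class LocalAlignment:
    """A contig-to-reference local alignment with exact edit counts.

    ``local_acc`` is the alignment identity: matches over all alignment
    columns.  ``align_len`` is the aligned span on the contig — the two
    ingredients of the per-contig accuracy score.
    """

    contig_id: str
    ref_id: str
    contig_start: int
    contig_end: int
    ref_start: int
    ref_end: int
    strand: str
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    band_capped: bool = False

    @property
    def local_acc(self) -> float:
        cols = self.matches + self.mismatches + self.insertions + self.deletions
        return self.matches / cols if cols else 0.0

    @property
    def align_len(self) -> int:
        return self.contig_end - self.contig_start

    @property
    def score(self) -> int:
        return (MATCH * self.matches + MISMATCH * self.mismatches
                + GAP * (self.insertions + self.deletions))

    def validate(self, contig_len: int, ref_len: int) -> None:
        if not (0 <= self.contig_start < self.contig_end <= contig_len):
            raise ValueError("contig interval out of bounds")
        if not (0 <= self.ref_start < self.ref_end <= ref_len):
            raise ValueError("reference interval out of bounds")
        if self.matches + self.mismatches + self.insertions != self.align_len:
            raise ValueError("edit counts do not span the contig interval")
        if self.matches + self.mismatches + self.deletions != self.ref_end - self.ref_start:
            raise ValueError("edit counts do not span the reference interval")


class ReferenceIndex:
    """Exact-match seed index over a set of reference genomes."""

    def __init__(self, refs: list[ReferenceGenome], min_anchor_length: int = 15):
        if not refs:
            raise ValueError("no reference genomes")
        self.refs = list(refs)
        self.min_anchor_length = min_anchor_length
        self.seed_len = min_anchor_length
        self.seeds: dict[str, list[tuple[int, int]]] = {}
        w = self.seed_len
        for ri, ref in enumerate(self.refs):
            s = ref.sequence
            for pos in range(len(s) - w + 1):
                self.seeds.setdefault(s[pos:pos + w], []).append((ri, pos))

    def anchors(self, query: str, strand: str) -> list[AnchorMatch]:
        """Maximal exact matches of length >= min_anchor_length.

        Seed hits on the same (reference, diagonal) at consecutive query
        offsets are runs of a single maximal exact match and are merged.
        """
        w = self.seed_len
        hits: dict[tuple[int, int], list[int]] = {}
        for q in range(len(query) - w + 1):
            for ri, pos in self.seeds.get(query[q:q + w], ()):
                hits.setdefault((ri, pos - q), []).append(q)
        out = []
        for (ri, diag), qs_list in hits.items():
            qs_list.sort()
            run_start = prev = qs_list[0]
            for q in qs_list[1:] + [None]:
                if q is not None and q == prev + 1:
                    prev = q
                    continue
                out.append(AnchorMatch(run_start, self.refs[ri].genome_id,
                                       run_start + diag, prev - run_start + w, strand))
                if q is not None:
                    run_start = prev = q
        return out


def chain_anchors(anchors: list[AnchorMatch], min_cluster_size: int = 30,
                  max_gap: int = 90) -> list[list[AnchorMatch]]:
    """Group co-linear anchors of one (contig, reference, strand) into chains.

    Anchors are taken in query order; an anchor joins the open chain whose
    tail it follows with both-coordinate gaps and diagonal drift at most
    ``max_gap`` (the closest diagonal wins), else it opens a new chain.
    Chains whose summed anchor length falls below ``min_cluster_size`` are
    discarded.
    """
    chains: list[list[AnchorMatch]] = []
    for a in sorted(anchors, key=lambda x: (x.contig_start, x.ref_start)):
        best, best_drift = None, None
        for chain in chains:
            tail = chain[-1]
            if a.contig_start < tail.contig_start or a.ref_start < tail.ref_start:
                continue
            if (a.contig_start - tail.contig_end > max_gap
                    or a.ref_start - tail.ref_end > max_gap):
                continue
            drift = abs(a.diagonal - tail.diagonal)
            if drift > max_gap:
                continue
            if best is None or drift < best_drift:
                best, best_drift = chain, drift
        if best is None:
            chains.append([a])
        else:
            best.append(a)
    return [ch for ch in chains
            if sum(a.length for a in ch) >= min_cluster_size]


def _banded_local(query: str, ref: str, dlo: int, dhi: int,
                  ) -> tuple[int, tuple, np.ndarray] | None:
    """Optimal local alignment restricted to diagonals ``dlo..dhi``.

    Returns (best score, best cell (i, o), H matrix) where cell (i, o) maps
    to query prefix i and reference position ``j = i + dlo + o``.
    """
    Lq, Lr = len(query), len(ref)
    W = dhi - dlo + 2  # one slack column simplifies the up-move shift
    H = np.zeros((Lq + 1, W), dtype=np.int32)
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    ra = np.frombuffer(ref.encode(), dtype=np.uint8)
    offs = np.arange(W)
    pen = 2 * offs
    best, best_cell = 0, None
    for i in range(1, Lq + 1):
        j = i + dlo + offs  # ref position (1-based) per band offset
        valid = (j >= 1) & (j <= Lr)
        sub = np.full(W, NEG, dtype=np.int32)
        jv = j[valid] - 1
        sub[valid] = np.where(ra[jv] == qa[i - 1], MATCH, MISMATCH)
        prev = H[i - 1]
        diag = prev + sub  # diagonal move keeps the same offset
        up = np.full(W, NEG, dtype=np.int32)
        up[:-1] = prev[1:] + GAP  # query-consuming gap shifts offset down
        m = np.maximum(np.maximum(diag, up), 0)
        m[~valid] = NEG
        # left (ref-consuming) gaps via running maximum over offsets
        row = np.maximum.accumulate(m + pen) - pen
        row[~valid] = 0
        np.maximum(row, 0, out=row)
        H[i] = row
        rb = int(row.max())
        if rb > best:
            best = rb
            best_cell = (i, int(row.argmax()))
    if best_cell is None:
        return None
    return best, best_cell, H


def _traceback(query: str, ref: str, dlo: int, H: np.ndarray,
               cell: tuple[int, int]) -> tuple[dict, bool]:
    """Recover the path ending at ``cell``; returns counts/intervals and
    whether the path touched the band boundary."""
    i, o = cell
    W = H.shape[1]
    matches = mismatches = ins = dels = 0
    touched = False
    qe = i
    re_ = i + dlo + o
    while H[i, o] > 0:
        if o <= 0 or o >= W - 2:
            touched = True
        j = i + dlo + o
        sub = MATCH if query[i - 1] == ref[j - 1] else MISMATCH
        if i > 0 and H[i, o] == H[i - 1, o] + sub:
            if sub == MATCH:
                matches += 1
            else:
                mismatches += 1
            i -= 1
        elif o > 0 and H[i, o] == H[i, o - 1] + GAP:
            dels += 1
            o -= 1
        elif i > 0 and o + 1 < W and H[i, o] == H[i - 1, o + 1] + GAP:
            ins += 1
            i -= 1
            o += 1
        else:  # pragma: no cover - would indicate a filling bug
            raise AssertionError("inconsistent traceback")
    qs = i
    rs = i + dlo + o
    return (dict(matches=matches, mismatches=mismatches, insertions=ins,
                 deletions=dels, q_interval=(qs, qe), r_interval=(rs, re_)),
            touched)


def extend_chain(chain: list[AnchorMatch], query: str, ref: str,
                 band_pad: int = 40) -> LocalAlignment | None:
    """Extend a chain into a full local alignment via banded DP.

    The band covers the chain's diagonal range padded by ``band_pad`` on each
    side; if the optimal in-band path touches the band boundary the band is
    widened once, and a still-capped alignment is flagged.
    """
    diags = [a.diagonal for a in chain]
    dlo, dhi = min(diags) - band_pad, max(diags) + band_pad
    capped = False
    for attempt in range(2):
        res = _banded_local(query, ref, dlo, dhi)
        if res is None:
            return None
        score, cell, H = res
        info, touched = _traceback(query, ref, dlo, H, cell)
        if not touched:
            break
        if attempt == 0:
            dlo -= 3 * band_pad
            dhi += 3 * band_pad
        else:
            capped = True
    qs, qe = info["q_interval"]
    rs, re_ = info["r_interval"]
    first = chain[0]
    return LocalAlignment(
        contig_id="", ref_id=first.ref_id,
        contig_start=qs, contig_end=qe, ref_start=rs, ref_end=re_,
        strand=first.strand,
        matches=info["matches"], mismatches=info["mismatches"],
        insertions=info["insertions"], deletions=info["deletions"],
        band_capped=capped)


def align_contig(contig: Contig, index: ReferenceIndex,
                 min_cluster_size: int = 30, max_gap: int = 90,
                 band_pad: int = 40) -> list[LocalAlignment]:
    """All local alignments of one contig against the indexed references.

    Every chain on every reference and strand is extended and reported;
    byte-identical records are deduplicated and output is sorted by
    (ref_id, ref_start, contig_start, strand).
    """
    seq = contig.sequence
    Lc = len(seq)
    if Lc < index.min_anchor_length:
        return []
    ref_by_id = {r.genome_id: r.sequence for r in index.refs}
    results: list[LocalAlignment] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        anchors = index.anchors(query, strand)
        grouped: dict[str, list[AnchorMatch]] = {}
        for a in anchors:
            grouped.setdefault(a.ref_id, []).append(a)
        for ref_id, group in grouped.items():
            ref = ref_by_id[ref_id]
            for chain in chain_anchors(group, min_cluster_size, max_gap):
                aln = _extend_or_exact(chain, query, ref, band_pad)
                if aln is None:
                    continue
                if strand == "-":
                    qs, qe = aln.contig_start, aln.contig_end
                    aln = LocalAlignment(
                        contig.contig_id, ref_id, Lc - qe, Lc - qs,
                        aln.ref_start, aln.ref_end, "-",
                        aln.matches, aln.mismatches, aln.insertions,
                        aln.deletions, aln.band_capped)
                else:
                    aln = LocalAlignment(
                        contig.contig_id, ref_id, aln.contig_start,
                        aln.contig_end, aln.ref_start, aln.ref_end, "+",
                        aln.matches, aln.mismatches, aln.insertions,
                        aln.deletions, aln.band_capped)
                results.append(aln)
    uniq = sorted(set(results),
                  key=lambda a: (a.ref_id, a.ref_start, a.contig_start, a.strand))
    return uniq


def _extend_or_exact(chain: list[AnchorMatch], query: str, ref: str,
                     band_pad: int) -> LocalAlignment | None:
    # fast path: a single anchor spanning the whole query is a perfect alignment
    if len(chain) == 1 and chain[0].length == len(query):
        a = chain[0]
        return LocalAlignment("", a.ref_id, 0, len(query), a.ref_start,
                              a.ref_end, a.strand, len(query), 0, 0, 0)
    return extend_chain(chain, query, ref, band_pad)


def align_contigs(contigs: list[Contig], index: ReferenceIndex,
                  min_cluster_size: int = 30, max_gap: int = 90,
                  band_pad: int = 40) -> dict[str, list[LocalAlignment]]:
    """Align every contig; contigs with no alignment map to an empty list."""
    return {c.contig_id: align_contig(c, index, min_cluster_size, max_gap, band_pad)
            for c in contigs}


def smith_waterman_score(a: str, b: str) -> int:
    """Unbanded Smith-Waterman score under the package scoring scheme.

    Independent full-matrix reference used to validate the banded
    seed-and-extend path; O(len(a) * len(b)).
    """
    la, lb = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(lb + 1, dtype=np.int32)
    best = 0
    pen = 2 * np.arange(lb + 1)
    for i in range(1, la + 1):
        sub = np.where(bb == aa[i - 1], MATCH, MISMATCH)
        cur = np.zeros(lb + 1, dtype=np.int32)
        cand = np.maximum(prev[:-1] + sub, prev[1:] + GAP)
        cur[1:] = np.maximum(cand, 0)
        # left gaps via running max
        cur = np.maximum.accumulate(cur + pen) - pen
        np.maximum(cur, 0, out=cur)
        best = max(best, int(cur.max()))
        prev = cur
    return best
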