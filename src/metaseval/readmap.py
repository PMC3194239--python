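"""Ungapped best-match short-read mapping onto contigs.

Plays the short-read-aligner role for contig homogeneity and mate-pair
linkage: each read is placed, on either strand, at the contig position with
the fewest mismatches (ungapped), using a pigeonhole seed index — a read
with at most ``max_mismatches`` mismatches must contain at least one exact
seed of length ``read_length // (max_mismatches + 1)``.

Ties are broken deterministically: fewest mismatches, then lowest contig id,
then lowest position, then '+' strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembler import Contig
from .community import SimulatedRead
from .seq import revcomp


@dataclass(frozen=True)
class Assignment:
    """Best placement of one read on the contig set."""

    contig_id: str
    pos: int
    strand: str
    mismatches: int
    unique: bool  # exactly one placement achieves the minimum


class ContigIndex:
    """Seed-position index over a contig set for a fixed read length."""

    def __init__(self, contigs: list[Contig], read_length: int,
                 max_mismatches: int = 2):
        if not contigs:
            raise ValueError("no contigs to index")
        self.contigs = sorted(contigs, key=lambda c: c.contig_id)
        self.read_length = read_length
        self.max_mismatches = max_mismatches
        self.seed_len = max(1, read_length // (max_mismatches + 1))
        self.n_seeds = read_length // self.seed_len
        self.index: dict[str, list[tuple[int, int]]] = {}
        w = self.seed_len
        for ci, contig in enumerate(self.contigs):
            s = contig.sequence
            for pos in range(len(s) - w + 1):
                self.index.setdefault(s[pos:pos + w], []).append((ci, pos))

    def map_read(self, bases: str) -> Assignment | None:
        L = self.read_length
        if len(bases) != L:
            raise ValueError("read length does not match the index")
        w = self.seed_len
        best: tuple[int, str, int, str] | None = None
        n_best = 0
        seen: set[tuple[int, int, str]] = set()
        for strand, query in (("+", bases), ("-", revcomp(bases))):
            for j in range(self.n_seeds):
                off = j * w
                for ci, pos in self.index.get(query[off:off + w], ()):
                    start = pos - off
                    key = (ci, start, strand)
                    if start < 0 or key in seen:
                        continue
                    seen.add(key)
                    contig = self.contigs[ci]
                    if start + L > len(contig):
                        continue
                    window = contig.sequence[start:start + L]
                    if window == query:
                        mm = 0
                    else:
                        mm = 0
                        limit = self.max_mismatches
                        for a, b in zip(query, window):
                            if a != b:
                                mm += 1
                                if mm > limit:
                                    break
                        if mm > limit:
                            continue
                    cand = (mm, contig.contig_id, start, strand)
                    if best is None or mm < best[0]:
                        best, n_best = cand, 1
                    elif mm == best[0]:
                        n_best += 1
                        if cand < best:
                            best = cand
        if best is None:
            return None
        return Assignment(best[1], best[2], best[3], best[0], n_best == 1)


def map_reads(reads: list[SimulatedRead], contigs: list[Contig],
              max_mismatches: int = 2) -> dict[str, Assignment]:
    """Map every read; unmapped reads are absent from the result."""
    if not reads:
        return {}
    if not contigs:
        return {}
    index = ContigIndex(contigs, len(reads[0].bases), max_mismatches)
    out: dict[str, Assignment] = {}
    for r in reads:
        a = index.map_read(r.bases)
        if a is not None:
            out[r.read_id] = a
    return out
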