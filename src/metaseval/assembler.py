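"""Desk-scale de Bruijn graph unitig assembler.

Nodes are canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, k odd so no k-mer is its own reverse complement); edges are the
(k-1)-base overlaps actually observed between adjacent k-mers in the reads.
Contigs are unitigs: maximal non-branching paths in the bidirected graph.
Graph cleaning is the standard minimum for short-read de Bruijn assembly:
the node multiplicity filter, clipping of short dead-end tips, and popping
of simple two-path bubbles (the weaker side by coverage is removed).  Dense
polymorphism between co-assembled strains produces entangled, non-simple
bubble structures that popping cannot resolve, so strain co-assembly still
fragments the assembly — as it should.

k-mers are packed into integers two bits per base (A=0, C=1, G=2, T=3, most
significant bits first); the per-node value packs the multiplicity in the low
32 bits and eight observed-extension bits (four right, four left, in the
canonical orientation) above them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

from .community import SimulatedRead
from .seq import BASES, revcomp

logger = logging.getLogger(__name__)

_CODE = {b: i for i, b in enumerate(BASES)}
_COUNT_MASK = (1 << 32) - 1
#: 4-bit bit-reversal table: maps a right-extension nibble seen from the
#: reverse strand onto the canonical strand's left-extension nibble.
_REVNIB = [int(f"{x:04b}"[::-1], 2) for x in range(16)]
_RC_BYTE = [
    ((3 - (x & 3)) << 6) | ((3 - ((x >> 2) & 3)) << 4)
    | ((3 - ((x >> 4) & 3)) << 2) | (3 - ((x >> 6) & 3))
    for x in range(256)
]


def encode_kmer(seq: str) -> int:
    v = 0
    for ch in seq:
        v = (v << 2) | _CODE[ch]
    return v


def decode_kmer(v: int, k: int) -> str:
    return "".join(BASES[(v >> (2 * (k - i - 1))) & 3] for i in range(k))


def revcomp_kmer(v: int, k: int) -> int:
    """Reverse complement of a 2-bit-packed k-mer, byte-table accelerated."""
    nbytes = (2 * k + 7) // 8
    r = 0
    for _ in range(nbytes):
        r = (r << 8) | _RC_BYTE[v & 0xFF]
        v >>= 8
    return r >> (8 * nbytes - 2 * k)


@dataclass(frozen=True)
class Contig:
    """An assembled sequence tagged with the k that produced it (or "clustered")."""

    contig_id: str
    sequence: str
    k_source: int | str

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("contig alphabet is strictly {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.sequence)


class KmerGraph:
    """Bidirected de Bruijn graph over canonical k-mers."""

    def __init__(self, k: int, data: dict[int, int]):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self.data = data

    def __contains__(self, canon: int) -> bool:
        return canon in self.data

    def __len__(self) -> int:
        return len(self.data)

    def multiplicity(self, canon: int) -> int:
        return self.data[canon] & _COUNT_MASK

    def canon(self, v: int) -> int:
        r = revcomp_kmer(v, self.k)
        return v if v <= r else r

    def successors(self, v: int) -> list[int]:
        """Oriented successors of the oriented k-mer ``v`` along observed edges."""
        k = self.k
        mask = (1 << (2 * k)) - 1
        c = self.canon(v)
        val = self.data.get(c)
        if val is None:
            return []
        if v == c:
            bits = (val >> 32) & 0xF
        else:
            bits = _REVNIB[(val >> 36) & 0xF]
        out = []
        for b in range(4):
            if bits & (1 << b):
                nv = ((v << 2) | b) & mask
                if self.canon(nv) in self.data:
                    out.append(nv)
        return out

    def in_degree(self, v: int) -> int:
        return len(self.successors(revcomp_kmer(v, self.k)))

    def _ext_bits(self, v: int, right: bool) -> int:
        c = self.canon(v)
        val = self.data.get(c)
        if val is None:
            return 0
        if v == c:
            return (val >> (32 if right else 36)) & 0xF
        return _REVNIB[(val >> (36 if right else 32)) & 0xF]

    def out_degree_at_least(self, v: int, n: int) -> bool:
        """Early-exit test: does ``v`` have at least ``n`` present successors?"""
        k, mask = self.k, (1 << (2 * self.k)) - 1
        bits = self._ext_bits(v, right=True)
        found = 0
        for b in range(4):
            if bits & (1 << b) and self.canon(((v << 2) | b) & mask) in self.data:
                found += 1
                if found >= n:
                    return True
        return False

    def has_pred(self, v: int) -> bool:
        return self.out_degree_at_least(revcomp_kmer(v, self.k), 1)

    def in_degree_at_least(self, v: int, n: int) -> bool:
        return self.out_degree_at_least(revcomp_kmer(v, self.k), n)


def build_graph(reads: list[SimulatedRead] | list[str], k: int,
                min_multiplicity: int = 1) -> KmerGraph:
    """Count canonical k-mers and observed extensions, then apply the
    multiplicity filter.

    Accepts reads or raw sequences.  k must be odd and no longer than the
    reads; reads shorter than k contribute nothing.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not reads:
        raise ValueError("no reads")
    seqs = [r.bases if isinstance(r, SimulatedRead) else r for r in reads]
    if k > max(len(s) for s in seqs):
        raise ValueError(f"k={k} exceeds the read length")

    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    code = _CODE
    data: dict[int, int] = {}
    get = data.get
    for s in seqs:
        n = len(s)
        if n < k:
            continue
        codes = [code[ch] for ch in s]
        f = r = 0
        i = 0
        for c in codes:
            f = ((f << 2) | c) & mask
            r = (r >> 2) | ((3 - c) << shift)
            if i >= k - 1:
                if f <= r:
                    key, fwd = f, True
                else:
                    key, fwd = r, False
                val = get(key, 0) + 1
                if i >= k:  # base preceding this k-mer in the read
                    pb = codes[i - k]
                    val |= (1 << (36 + pb)) if fwd else (1 << (32 + (3 - pb)))
                if i + 1 < n:  # base following this k-mer in the read
                    nb = codes[i + 1]
                    val |= (1 << (32 + nb)) if fwd else (1 << (36 + (3 - nb)))
                data[key] = val
            i += 1
    if min_multiplicity > 1:
        data = {key: val for key, val in data.items()
                if (val & _COUNT_MASK) >= min_multiplicity}
    return KmerGraph(k, data)


class _Cleaner:
    """Shared machinery for tip clipping and bubble popping.

    Keeps a presence set holding *both* orientations of every node so that
    neighbour probes are single set lookups, and a dirty frontier so that
    after the first full sweep only the neighbourhoods of removed nodes are
    re-examined.
    """

    def __init__(self, graph: KmerGraph):
        self.g = graph
        self.k = graph.k
        self.mask = (1 << (2 * self.k)) - 1
        self.shift = 2 * (self.k - 1)
        self.present: set[int] = set()
        for c in graph.data:
            self.present.add(c)
            self.present.add(revcomp_kmer(c, self.k))
        self.frontier: set[int] = set()

    def bits(self, v: int) -> tuple[int, int]:
        """(right, left) observed-extension nibbles in orientation ``v``."""
        val = self.g.data.get(v)
        if val is not None:
            return (val >> 32) & 0xF, (val >> 36) & 0xF
        val = self.g.data.get(revcomp_kmer(v, self.k))
        if val is None:
            return 0, 0
        return _REVNIB[(val >> 36) & 0xF], _REVNIB[(val >> 32) & 0xF]

    def succs(self, v: int) -> list[int]:
        right, _ = self.bits(v)
        out = []
        for b in range(4):
            if right & (1 << b):
                nv = ((v << 2) | b) & self.mask
                if nv in self.present:
                    out.append(nv)
        return out

    def preds(self, v: int) -> list[int]:
        _, left = self.bits(v)
        out = []
        for b in range(4):
            if left & (1 << b):
                pv = (b << self.shift) | (v >> 2)
                if pv in self.present:
                    out.append(pv)
        return out

    def remove(self, canon: int) -> None:
        r = revcomp_kmer(canon, self.k)
        for v in (canon, r):
            for nb in self.succs(v) + self.preds(v):
                self.frontier.add(nb if nb in self.g.data else revcomp_kmer(nb, self.k))
        self.g.data.pop(canon, None)
        self.present.discard(canon)
        self.present.discard(r)
        self.frontier.discard(canon)

    def canon(self, v: int) -> int:
        return v if v in self.g.data else revcomp_kmer(v, self.k)

    # -- tips ---------------------------------------------------------------

    def clip_tip_at(self, c: int, limit: int) -> int:
        """Clip the tip starting at node ``c`` (either orientation), if any."""
        for v in (c, revcomp_kmer(c, self.k)):
            if v not in self.present:
                return 0
            if self.preds(v):
                continue
            path = [v]
            cur = v
            ok = False
            while len(path) <= limit:
                ss = self.succs(cur)
                if len(ss) != 1:
                    break
                nxt = ss[0]
                if len(self.preds(nxt)) > 1:
                    ok = True  # rejoins a through-path: clip up to here
                    break
                if self.canon(nxt) == self.canon(cur):
                    break
                path.append(nxt)
                cur = nxt
            if ok and len(path) <= limit:
                for node in path:
                    self.remove(self.canon(node))
                return len(path)
        return 0

    # -- bubbles ------------------------------------------------------------

    def walk_to_merge(self, start: int, limit: int):
        interior = []
        cur = start
        for _ in range(limit + 1):
            if len(self.preds(cur)) > 1:
                return cur, interior
            ss = self.succs(cur)
            if len(ss) != 1:
                return None
            interior.append(cur)
            cur = ss[0]
        return None

    def pop_bubble_at(self, c: int, limit: int) -> int:
        removed = 0
        for v in (c, revcomp_kmer(c, self.k)):
            if v not in self.present:
                return removed
            right, _ = self.bits(v)
            if right.bit_count() < 2:
                continue
            ss = self.succs(v)
            if len(ss) != 2:
                continue
            walks = [self.walk_to_merge(s, limit) for s in sorted(ss)]
            if walks[0] is None or walks[1] is None:
                continue
            (m0, int0), (m1, int1) = walks
            if m0 != m1 or not int0 or not int1:
                continue
            set0 = {self.canon(x) for x in int0}
            set1 = {self.canon(x) for x in int1}
            vm = {self.canon(v), self.canon(m0)}
            if set0 & set1 or vm & set0 or vm & set1:
                continue
            cov0 = sum(self.g.multiplicity(x) for x in set0) / len(set0)
            cov1 = sum(self.g.multiplicity(x) for x in set1) / len(set1)
            loser = set0 if (cov0, sorted(set1)) < (cov1, sorted(set0)) else set1
            for node in loser:
                self.remove(node)
            removed += len(loser)
        return removed


def clip_tips(graph: KmerGraph, max_tip_nodes: int | None = None,
              _cleaner: "_Cleaner | None" = None,
              _candidates=None) -> int:
    """Remove short dead-end paths (tips); returns the number of nodes removed.

    A tip is a path of at most ``max_tip_nodes`` nodes (default 2k) with no
    predecessors at one end that rejoins the rest of the graph at the other.
    Tips are the dominant artifact of unrepeated sequencing errors.
    """
    limit = 2 * graph.k if max_tip_nodes is None else max_tip_nodes
    cl = _cleaner or _Cleaner(graph)
    removed = 0
    for c in (sorted(graph.data) if _candidates is None else sorted(_candidates)):
        if c in graph.data:
            removed += cl.clip_tip_at(c, limit)
    return removed


def pop_bubbles(graph: KmerGraph, max_bubble_nodes: int | None = None,
                _cleaner: "_Cleaner | None" = None,
                _candidates=None) -> int:
    """Pop simple two-path bubbles, removing the weaker side by coverage.

    At each node with exactly two successors, both branches are followed
    while non-branching; if they reconverge at the same oriented node within
    ``max_bubble_nodes`` (default 3k) interior nodes, the side with the lower
    mean multiplicity is deleted (ties break toward keeping the
    lexicographically smaller interior).  Single-substitution differences
    between co-assembled sequences form exactly such bubbles.
    """
    limit = 3 * graph.k if max_bubble_nodes is None else max_bubble_nodes
    cl = _cleaner or _Cleaner(graph)
    removed = 0
    for c in (sorted(graph.data) if _candidates is None else sorted(_candidates)):
        if c in graph.data:
            removed += cl.pop_bubble_at(c, limit)
    return removed


def clean_graph(graph: KmerGraph, rounds: int = 4,
                max_tip_nodes: int | None = None,
                max_bubble_nodes: int | None = None) -> KmerGraph:
    """Alternate tip clipping and bubble popping until stable (or ``rounds``).

    The first round sweeps every node; later rounds only revisit the
    neighbourhoods disturbed by removals.
    """
    cl = _Cleaner(graph)
    candidates = None
    for _ in range(rounds):
        n = clip_tips(graph, max_tip_nodes, _cleaner=cl, _candidates=candidates)
        n += pop_bubbles(graph, max_bubble_nodes, _cleaner=cl, _candidates=candidates)
        if n == 0 or not cl.frontier:
            break
        candidates, cl.frontier = cl.frontier, set()
    return graph


def extract_unitigs(graph: KmerGraph) -> list[Contig]:
    """Spell the maximal non-branching paths of the graph.

    Interior nodes of a unitig have exactly one observed successor and one
    observed predecessor in the bidirected sense.  Every node lands in exactly
    one unitig; cycles are linearized at their smallest canonical k-mer.
    Output is deterministic: contigs in canonical form, sorted.
    """
    k = graph.k
    visited: set[int] = set()
    seqs: list[str] = []

    def walk(start: int, pset: set[int]) -> list[int]:
        path = []
        cur = start
        while True:
            ss = graph.successors(cur)
            if len(ss) != 1:
                break
            nxt = ss[0]
            if len(graph.successors(revcomp_kmer(nxt, k))) != 1:
                break
            nc = graph.canon(nxt)
            if nc in pset or nc in visited:
                break
            path.append(nxt)
            pset.add(nc)
            cur = nxt
        return path

    for c in sorted(graph.data):
        if c in visited:
            continue
        pset = {c}
        fwd = walk(c, pset)
        bwd = walk(revcomp_kmer(c, k), pset)
        path = [revcomp_kmer(x, k) for x in reversed(bwd)] + [c] + fwd
        visited |= pset
        seq = decode_kmer(path[0], k) + "".join(BASES[x & 3] for x in path[1:])
        rc = revcomp(seq)
        seqs.append(seq if seq <= rc else rc)
    seqs.sort()
    return [Contig(f"{k}_{i:06d}", s, k) for i, s in enumerate(seqs)]


def filter_contigs(contigs: list[Contig], min_length: int = 50) -> list[Contig]:
    """Drop contigs shorter than ``min_length`` (default 50 bp), keeping order."""
    return [c for c in contigs if len(c) >= min_length]


def assemble(reads, k: int, min_multiplicity: int = 1,
             min_length: int = 50, clean: bool = True) -> list[Contig]:
    """Build the graph, clean it, extract unitigs and apply the length filter."""
    graph = build_graph(reads, k, min_multiplicity)
    if clean:
        clean_graph(graph)
    return filter_contigs(extract_unitigs(graph), min_length)


DEFAULT_KS = (21, 23, 25, 27, 29, 31, 33)


def k_sweep(reads, ks=DEFAULT_KS, min_multiplicity: int = 1,
            min_length: int = 50) -> dict[int, list[Contig]]:
    """Assemble independently at each k; contigs carry their k in ``k_source``."""
    out = {}
    for k in ks:
        out[k] = assemble(reads, k, min_multiplicity, min_length)
        logger.info("k=%d: %d contigs, %d bases", k, len(out[k]),
                    sum(len(c) for c in out[k]))
    return out


# ---------------------------------------------------------------------------
# paired-end contig merging
# ---------------------------------------------------------------------------

def _oriented(contig: Contig, flip: bool) -> str:
    return revcomp(contig.sequence) if flip else contig.sequence


def merge_with_pairs(contigs: list[Contig], pairs, insert_length: int = 2000,
                     read_length: int = 36, min_pairs: int = 10,
                     max_mismatches: int = 2,
                     gap_tolerance: float = 0.3) -> list[Contig]:
    """Join contigs supported by at least ``min_pairs`` uniquely mapped mate
    pairs in a consistent orientation.

    Joins whose estimated gap is positive are *not* bridged: the two parts are
    emitted separately (gapped joins are broken rather than padded).  Joins
    with a non-positive estimated gap are merged when the implied overlap
    agrees exactly between the two contigs.  Contradictory orientations for
    the same contig pair discard the whole link with a warning.
    """
    from .readmap import map_reads as _map_reads

    flat = [m for p in pairs for m in p]
    assign = _map_reads(flat, contigs, max_mismatches=max_mismatches)
    by_id = {c.contig_id: c for c in contigs}

    # collect links: (idA, flipA, idB, flipB) -> list of gap estimates,
    # normalized so idA <= idB
    links: dict[tuple[str, bool, str, bool], list[int]] = {}
    for m1, m2 in pairs:
        a1, a2 = assign.get(m1.read_id), assign.get(m2.read_id)
        if a1 is None or a2 is None or not (a1.unique and a2.unique):
            continue
        if a1.contig_id == a2.contig_id:
            continue
        A, B = by_id[a1.contig_id], by_id[a2.contig_id]
        # orient A so mate1 reads left-to-right, B so mate2 reads right-to-left
        flip_a = a1.strand == "-"
        p1 = a1.pos if not flip_a else len(A) - (a1.pos + read_length)
        flip_b = a2.strand == "+"
        q2 = a2.pos if not flip_b else len(B) - (a2.pos + read_length)
        gap = insert_length - (len(A) - p1) - (q2 + read_length)
        key = (A.contig_id, flip_a, B.contig_id, flip_b)
        if A.contig_id > B.contig_id:
            key = (B.contig_id, not flip_b, A.contig_id, not flip_a)
        links.setdefault(key, []).append(gap)

    # orientation consistency per unordered contig pair
    by_pair: dict[tuple[str, str], list[tuple]] = {}
    for key, gaps in links.items():
        by_pair.setdefault((key[0], key[2]), []).append((key, gaps))
    accepted = []
    for pair_key, variants in sorted(by_pair.items()):
        strong = [(key, gaps) for key, gaps in variants if len(gaps) >= min_pairs]
        if not strong:
            continue
        if len(strong) > 1:
            logger.warning("contradictory mate-pair orientations for %s/%s; "
                           "link discarded", *pair_key)
            continue
        key, gaps = strong[0]
        est_gap = int(median(gaps))
        if abs(est_gap) > gap_tolerance * insert_length:
            logger.warning("mate-pair link %s implies gap %d outside insert "
                           "tolerance; discarded", key, est_gap)
            continue
        accepted.append((len(gaps), key, est_gap))
    accepted.sort(key=lambda t: (-t[0], t[1]))

    merged_away: set[str] = set()
    new_contigs: list[Contig] = []
    serial = 0
    for _count, (ida, flip_a, idb, flip_b), est_gap in accepted:
        if ida in merged_away or idb in merged_away:
            continue  # each contig participates in at most one merge
        if est_gap > 0:
            continue  # positive gap: parts stay separate
        A, B = by_id[ida], by_id[idb]
        sa, sb = _oriented(A, flip_a), _oriented(B, flip_b)
        ov = _find_overlap(sa, sb, -est_gap)
        if ov is None:
            continue  # no sequence agreement: treat as gapped, keep parts
        serial += 1
        new_contigs.append(Contig(f"pe_{serial:04d}", sa + sb[ov:], A.k_source))
        merged_away.update((ida, idb))

    out = new_contigs + [c for c in contigs if c.contig_id not in merged_away]
    out.sort(key=lambda c: (-len(c), c.sequence))
    return out


def _find_overlap(sa: str, sb: str, expected: int, slack: int = 50) -> int | None:
    """Exact suffix(sa)/prefix(sb) overlap length near the mate-implied value."""
    lo = max(1, expected - slack)
    hi = min(len(sa), len(sb), expected + slack)
    best = None
    for o in range(hi, lo - 1, -1):
        if sa[-o:] == sb[:o]:
            best = o
            break
    return best
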