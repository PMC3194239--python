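"""Greedy incremental contig clustering and k-run pooling.

Contigs from the k-mer sweep are pooled and deduplicated with a greedy,
longest-first clustering: the longest sequence founds the first cluster, each
following sequence (in decreasing length) joins the first representative it
matches with containment identity at or above the threshold, and otherwise
founds its own cluster.  Candidate/representative pairs are screened with a
short-word filter before any alignment is attempted: a candidate of length L
at identity p must share at least ``L - w + 1 - w * ceil((1 - p) * L)``
w-mers with the representative, so a lower count rejects without aligning.

Containment identity is the number of matching alignment columns divided by
the candidate (shorter) length, checked on both strands; verification uses an
optimal infix edit-distance alignment (edlib).  The procedure deliberately
retains every sequence that matches no representative, so mis-assembled
contigs accumulate in the pooled set — that error accumulation is a property
of the method, not a defect of the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import edlib

from .assembler import Contig
from .seq import revcomp


def word_filter_threshold(length: int, word_size: int, identity: float) -> int:
    """Minimum shared-word count implied by the identity threshold.

    Each of the up-to ``ceil((1 - p) * L)`` tolerated edits can destroy at
    most ``word_size`` of the candidate's ``L - word_size + 1`` words.
    """
    # round before ceil: (1 - 0.95) * 100 is 5.000000000000004 in binary
    max_edits = math.ceil(round((1 - identity) * length, 9))
    return length - word_size + 1 - word_size * max_edits


def word_filter(candidate: str, representative: str, word_size: int = 8,
                identity_threshold: float = 0.95) -> bool:
    """Screen a candidate against a representative by shared-word counting.

    Counts candidate words (with multiplicity) present anywhere in the
    representative or its reverse complement.  Failing is definitive; passing
    still requires alignment verification.
    """
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    if len(candidate) > len(representative):
        raise ValueError("candidate must not be longer than the representative")
    if word_size > len(candidate):
        return False
    w = word_size
    rep_words = set()
    for s in (representative, revcomp(representative)):
        for i in range(len(s) - w + 1):
            rep_words.add(s[i:i + w])
    shared = sum(1 for i in range(len(candidate) - w + 1)
                 if candidate[i:i + w] in rep_words)
    return shared >= word_filter_threshold(len(candidate), w, identity_threshold)


def containment_identity(candidate: str, representative: str) -> tuple[float, str]:
    """Best containment identity of the candidate in the representative.

    Aligns the full candidate (either strand) to the best-matching infix of
    the representative; identity is matching columns over candidate length,
    lower-bounded by ``(L - edit_distance) / L``.
    """
    L = len(candidate)
    best, strand = -1.0, "+"
    for st, query in (("+", candidate), ("-", revcomp(candidate))):
        d = edlib.align(query, representative, mode="HW", task="distance")["editDistance"]
        ident = (L - d) / L
        if ident > best:
            best, strand = ident, st
    return best, strand


@dataclass(frozen=True)
class ClusterSet:
    """Clusters as (representative, members); members include the representative."""

    clusters: list[tuple[Contig, list[tuple[Contig, float, str]]]]
    provenance: tuple

    def representatives(self) -> list[Contig]:
        """The clustered contig set, tagged k_source='clustered'."""
        return [replace(rep, k_source="clustered") for rep, _ in self.clusters]

    def membership_rows(self) -> list[tuple[str, str, float, str]]:
        return [(rep.contig_id, m.contig_id, round(ident, 4), strand)
                for rep, members in self.clusters
                for m, ident, strand in members]

    def __len__(self) -> int:
        return len(self.clusters)


def greedy_cluster(contigs: list[Contig], identity_threshold: float = 0.95,
                   word_size: int = 8, provenance: tuple = ()) -> ClusterSet:
    """Longest-first greedy clustering at the given containment identity."""
    if not contigs:
        raise ValueError("no contigs to cluster")
    ordered = sorted(contigs, key=lambda c: (-len(c), c.sequence))
    w = word_size
    reps: list[Contig] = []
    members: list[list[tuple[Contig, float, str]]] = []
    # inverted index: word -> indices of representatives containing it (either strand)
    word_reps: dict[str, list[int]] = {}

    def register(rep: Contig) -> None:
        ri = len(reps)
        reps.append(rep)
        members.append([(rep, 1.0, "+")])
        seen = set()
        for s in (rep.sequence, revcomp(rep.sequence)):
            for i in range(len(s) - w + 1):
                word = s[i:i + w]
                if word not in seen:
                    seen.add(word)
                    word_reps.setdefault(word, []).append(ri)

    register(ordered[0])
    for contig in ordered[1:]:
        seq = contig.sequence
        L = len(seq)
        placed = False
        if L >= w:
            need = word_filter_threshold(L, w, identity_threshold)
            shared: dict[int, int] = {}
            for i in range(L - w + 1):
                for ri in word_reps.get(seq[i:i + w], ()):
                    shared[ri] = shared.get(ri, 0) + 1
            # first representative (creation order) passing filter + verification
            for ri in sorted(ri for ri, n in shared.items() if n >= need):
                ident, strand = containment_identity(seq, reps[ri].sequence)
                if ident >= identity_threshold:
                    members[ri].append((contig, ident, strand))
                    placed = True
                    break
        if not placed:
            register(contig)
    return ClusterSet(list(zip(reps, members)), provenance)


def pool_k_runs(k_to_contigs: dict[int, list[Contig]],
                exclude_ks: list[int] | tuple[int, ...] = (),
                identity_threshold: float = 0.95,
                word_size: int = 8) -> ClusterSet:
    """Pool the contig sets of a k sweep (minus ``exclude_ks``) and cluster.

    With ``exclude_ks=[21]`` this produces the "C-21" variant of the pooled
    set; with no exclusions, the "C" set.
    """
    included = [k for k in sorted(k_to_contigs) if k not in set(exclude_ks)]
    if not included:
        raise ValueError("exclude_ks leaves no assembly runs to pool")
    pooled = [c for k in included for c in k_to_contigs[k]]
    return greedy_cluster(pooled, identity_threshold, word_size,
                          provenance=tuple(included))
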