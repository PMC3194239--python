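"""Contig-level assembly metrics.

The central quantity is the per-contig accuracy

    accuracy = localAcc * alignLen / contigLen

the identity of a local alignment normalized by the fraction of the contig
it spans.  A contig's accuracy is the best over all its alignments; a contig
is counted *accurate* when its accuracy reaches the 95% threshold.  Around it
sit the breadth-of-coverage of the source genomes by accurately aligning
contigs, N50, and the per-assembly summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .aligner import LocalAlignment
from .assembler import Contig
from .community import ReferenceGenome

ACCURACY_THRESHOLD = 0.95


def eq1_accuracy(local_acc: float, align_len: int, contig_len: int) -> float:
    """Alignment identity normalized by the aligned fraction of the contig."""
    if not (0 <= local_acc <= 1):
        raise ValueError("local_acc must be in [0, 1]")
    if align_len <= 0 or contig_len <= 0:
        raise ValueError("lengths must be positive")
    if align_len > contig_len:
        raise ValueError("align_len cannot exceed contig_len")
    return local_acc * align_len / contig_len


@dataclass(frozen=True)
class ContigAccuracy:
    """Best-alignment accuracy of one contig; unaligned contigs score 0."""

    contig_id: str
    contig_len: int
    best_alignment: LocalAlignment | None
    accuracy: float

    @property
    def accurate(self) -> bool:
        return self.accuracy >= ACCURACY_THRESHOLD


def score_contigs(contigs: list[Contig],
                  alignments: dict[str, list[LocalAlignment]],
                  ) -> list[ContigAccuracy]:
    """Score every contig by its best alignment accuracy."""
    out = []
    for c in contigs:
        best_aln, best_acc = None, 0.0
        for aln in alignments.get(c.contig_id, ()):
            acc = eq1_accuracy(aln.local_acc, aln.align_len, len(c))
            if acc > best_acc:
                best_aln, best_acc = aln, acc
        out.append(ContigAccuracy(c.contig_id, len(c), best_aln, best_acc))
    return out


@dataclass
class CoverageMask:
    """Per-position coverage flags of one reference genome."""

    ref_id: str
    covered: np.ndarray  # bool per position

    @property
    def length(self) -> int:
        return self.covered.size

    @property
    def ratio(self) -> float:
        return float(self.covered.sum()) / self.covered.size


def source_coverage(refs: list[ReferenceGenome],
                    contigs: list[Contig],
                    alignments: dict[str, list[LocalAlignment]],
                    contig_cover_threshold: float = ACCURACY_THRESHOLD,
                    ) -> dict[str, CoverageMask]:
    """Breadth of coverage of each source genome by accurate alignments.

    An alignment qualifies when its *own* accuracy (identity times aligned
    contig fraction) reaches the threshold; all qualifying alignments of a
    contig mark their reference intervals, so multi-mapping contigs
    contribute everywhere they align.  Positions are flags, not counters, so
    the ratio never exceeds 1.
    """
    lens = {c.contig_id: len(c) for c in contigs}
    masks = {r.genome_id: CoverageMask(r.genome_id, np.zeros(len(r), dtype=bool))
             for r in refs}
    for cid, alns in alignments.items():
        clen = lens.get(cid)
        if clen is None:
            continue
        for aln in alns:
            if eq1_accuracy(aln.local_acc, aln.align_len, clen) >= contig_cover_threshold:
                masks[aln.ref_id].covered[aln.ref_start:aln.ref_end] = True
    return masks


def n50(lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L hold at least half the bases."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")  # pragma: no cover


def _pct(numer: float, denom: float) -> float:
    """Percentage rounded half-up to 2 decimals (summary-table convention)."""
    if denom == 0:
        return 0.0
    return float(Decimal(100 * numer / denom).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssemblyStats:
    """One row of the per-assembly summary table."""

    label: str
    total_contigs: int
    accurate_contigs: int
    pct_accurate: float
    n50: int
    total_bases: int
    bases_in_accurate: int
    pct_bases_accurate: float


def summarize(label: str, contigs: list[Contig],
              accuracies: list[ContigAccuracy]) -> AssemblyStats:
    """Summary statistics of one assembly (one k run or a pooled set)."""
    acc_by_id = {a.contig_id: a for a in accuracies}
    missing = [c.contig_id for c in contigs if c.contig_id not in acc_by_id]
    if missing:
        raise ValueError(f"accuracies missing for contigs: {missing[:3]}...")
    lengths = [len(c) for c in contigs]
    total_bases = sum(lengths)
    accurate = [c for c in contigs if acc_by_id[c.contig_id].accurate]
    bases_acc = sum(len(c) for c in accurate)
    return AssemblyStats(
        label=label,
        total_contigs=len(contigs),
        accurate_contigs=len(accurate),
        pct_accurate=_pct(len(accurate), len(contigs)),
        n50=n50(lengths) if lengths else 0,
        total_bases=total_bases,
        bases_in_accurate=bases_acc,
        pct_bases_accurate=_pct(bases_acc, total_bases),
    )


def stats_table(stats: list[AssemblyStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def length_distributions(contig_sets: dict[str, list[Contig]],
                         cutoffs: list[int]) -> pd.DataFrame:
    """Cumulative contig counts and bases below each length cutoff.

    For each set and cutoff: the number of contigs strictly shorter than the
    cutoff and the bases they contain; both are monotone in the cutoff.
    """
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    rows = []
    for label, contigs in contig_sets.items():
        lengths = np.array(sorted(len(c) for c in contigs), dtype=np.int64)
        csum = np.concatenate(([0], np.cumsum(lengths)))
        for cut in cutoffs:
            i = int(np.searchsorted(lengths, cut, side="left"))
            rows.append((label, cut, i, int(csum[i])))
    return pd.DataFrame(rows, columns=["label", "cutoff", "n_contigs", "total_bases"])
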