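"""Read-composition entropy of contigs at four taxonomic levels.

A perfectly assembled contig contains reads from a single source sequence; a
chimeric contig mixes sources.  Chimerism is quantified by assigning each
read to its best-matching contig (ungapped, both strands, at most two
mismatches) and computing, per contig, the Shannon entropy of the source
composition of its reads:

    H = -sum_i p_i * log2(p_i)

where p_i is the fraction of the contig's mapped reads whose true source
falls in group i.  Groups are taken at the sequence (per source sequence),
species, genus, or phylum level, so entropy can only decrease as labels are
coarsened up the taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assembler import Contig
from .community import ReferenceGenome, SimulatedRead, Taxonomy
from .readmap import Assignment, map_reads

LEVELS = ("sequence", "species", "genus", "phylum")


def entropy(p) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0 or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("entropy requires a probability vector summing to 1")
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def source_fractions(assignment: dict[str, Assignment],
                     provenance: dict[str, str],
                     taxonomy: dict[str, Taxonomy],
                     level: str) -> dict[str, dict[str, float]]:
    """Per-contig fractions of mapped reads by taxonomy group at one level.

    ``provenance`` maps read_id -> true source genome_id.  Contigs with no
    mapped reads are absent from the result.
    """
    counts: dict[str, dict[str, int]] = {}
    for read_id, a in assignment.items():
        source = provenance[read_id]
        group = taxonomy[source].level(level)
        per = counts.setdefault(a.contig_id, {})
        per[group] = per.get(group, 0) + 1
    out = {}
    for cid, per in counts.items():
        total = sum(per.values())
        out[cid] = {g: n / total for g, n in per.items()}
    return out


@dataclass(frozen=True)
class EntropyRecord:
    """Read-composition entropy of one contig at one taxonomic level."""

    contig_id: str
    contig_len: int
    level: str
    n_reads: int
    entropy: float


def entropy_by_level(contigs: list[Contig],
                     assignment: dict[str, Assignment],
                     provenance: dict[str, str],
                     taxonomy: dict[str, Taxonomy],
                     levels=LEVELS) -> list[EntropyRecord]:
    """One entropy record per (contig, level), for contigs with mapped reads."""
    lens = {c.contig_id: len(c) for c in contigs}
    n_reads: dict[str, int] = {}
    for a in assignment.values():
        n_reads[a.contig_id] = n_reads.get(a.contig_id, 0) + 1
    records = []
    for level in levels:
        fracs = source_fractions(assignment, provenance, taxonomy, level)
        for cid in sorted(fracs):
            records.append(EntropyRecord(
                cid, lens[cid], level, n_reads[cid],
                entropy(list(fracs[cid].values()))))
    return records


def contig_entropy(reads: list[SimulatedRead], contigs: list[Contig],
                   taxonomy: dict[str, Taxonomy],
                   max_mismatches: int = 2,
                   levels=LEVELS) -> tuple[list[EntropyRecord], dict[str, Assignment]]:
    """Map reads to contigs and compute entropy records; provenance comes
    from the reads' own ground-truth source labels."""
    assignment = map_reads(reads, contigs, max_mismatches=max_mismatches)
    provenance = {r.read_id: r.true_source for r in reads}
    return entropy_by_level(contigs, assignment, provenance, taxonomy, levels), assignment


def taxonomy_of(genomes: list[ReferenceGenome]) -> dict[str, Taxonomy]:
    return {g.genome_id: g.taxonomy for g in genomes}


def entropy_table(records: list[EntropyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def mean_entropy(records: list[EntropyRecord], level: str,
                 weight: str = "bases") -> float:
    """Mean contig entropy at one level, over contigs with mapped reads.

    ``weight="bases"`` (default) weights each contig by its length, i.e. the
    average chimerism of an assembled base — long contigs matter as much as
    they do in the assembly.  ``weight="contigs"`` is the unweighted
    per-contig mean.
    """
    recs = [r for r in records if r.level == level]
    if not recs:
        raise ValueError(f"no entropy records at level {level!r}")
    if weight == "contigs":
        return float(np.mean([r.entropy for r in recs]))
    if weight == "bases":
        w = np.array([r.contig_len for r in recs], dtype=float)
        e = np.array([r.entropy for r in recs])
        return float((w * e).sum() / w.sum())
    raise ValueError(f"unknown weighting: {weight!r}")
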