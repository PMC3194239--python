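"""FASTA/FASTQ/TSV input and output.

Sequence I/O goes through Biopython's SeqIO; tables through pandas.
FASTQ quality strings are constant 'I' — downstream stages ignore quality.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import ReferenceGenome, SimulatedRead, Taxonomy, parse_read_id


def _records(pairs: Iterable[tuple[str, str]], quality: bool):
    for name, seq in pairs:
        rec = SeqRecord(Seq(seq), id=name, description="")
        if quality:
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
        yield rec


def write_fasta(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(_records(pairs, quality=False), str(path), "fasta")


def write_fastq(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(_records(pairs, quality=True), str(path), "fastq")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


def write_genomes_fasta(path: str | Path, genomes: list[ReferenceGenome]) -> None:
    write_fasta(path, ((g.genome_id, g.sequence) for g in genomes))


def write_reads(path: str | Path, reads: list[SimulatedRead], fmt: str = "fastq") -> None:
    pairs = ((r.read_id, r.bases) for r in reads)
    if fmt == "fastq":
        write_fastq(path, pairs)
    elif fmt == "fasta":
        write_fasta(path, pairs)
    else:
        raise ValueError(f"unknown read format: {fmt!r}")


def read_reads(path: str | Path) -> list[SimulatedRead]:
    """Load reads written by :func:`write_reads`, re-parsing provenance ids."""
    p = str(path)
    pairs = read_fastq(p) if p.endswith("q") else read_fasta(p)
    out = []
    for name, seq in pairs:
        genome_id, _, _, _ = parse_read_id(name)
        out.append(SimulatedRead(name, seq, genome_id))
    return out


def write_provenance_tsv(path: str | Path, reads: list[SimulatedRead],
                         read_length: int | None = None) -> None:
    rows = []
    for r in reads:
        gid, start, strand, mate = parse_read_id(r.read_id)
        end = start + (read_length if read_length is not None else len(r.bases))
        rows.append((r.read_id, gid, start, end, strand, mate))
    pd.DataFrame(rows, columns=["read_id", "genome_id", "start", "end", "strand", "mate"]) \
        .to_csv(path, sep="\t", index=False)


def write_taxonomy_tsv(path: str | Path, genomes: list[ReferenceGenome]) -> None:
    rows = [(g.genome_id, g.taxonomy.strain, g.taxonomy.species,
             g.taxonomy.genus, g.taxonomy.phylum) for g in genomes]
    pd.DataFrame(rows, columns=["genome_id", "strain", "species", "genus", "phylum"]) \
        .to_csv(path, sep="\t", index=False)


def read_taxonomy_tsv(path: str | Path) -> dict[str, Taxonomy]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.genome_id: Taxonomy(row.strain, row.species, row.genus, row.phylum)
            for row in df.itertuples()}
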