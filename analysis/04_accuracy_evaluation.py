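#!/usr/bin/env python
"""Score every assembly against its source genomes.

Aligns each dataset's per-k and pooled contig sets to the reference genomes
(seed-and-extend, exact-match anchor 15, cluster 30), scores every contig by
its best alignment accuracy (identity x aligned fraction, accurate at 95%),
and writes a summary table of the usual columns — contig counts, percent
accurate, N50, total bases — plus cumulative length distributions, under
results/evaluation/.  Expected pattern: percent accurate falls as k falls,
and the pooled set C is the least accurate of all.
"""

from pathlib import Path

import pandas as pd

from metaseval import io as mio
from metaseval.aligner import ReferenceIndex, align_contigs
from metaseval.assembler import Contig, DEFAULT_KS
from metaseval.community import ReferenceGenome
from metaseval.evaluation import (length_distributions, score_contigs,
                                  stats_table, summarize)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATASETS = ("simLC", "simMC", "simHC", "strains", "isolate")
CUTOFFS = [50, 100, 200, 400, 800, 1600, 3200, 6400, 12800, 10 ** 9]


def load_genomes(name):
    tax = mio.read_taxonomy_tsv(ROOT / "data" / name / "taxonomy.tsv")
    return [ReferenceGenome(n, s, tax[n])
            for n, s in mio.read_fasta(ROOT / "data" / name / "genomes.fa")]


def load_sets(name):
    sets = {}
    for label in ("C", "C-21"):
        sets[label] = [Contig(n, s, "clustered") for n, s in
                       mio.read_fasta(ROOT / "clustered" / name / f"{label}.fa")]
    for k in DEFAULT_KS:
        sets[str(k)] = [Contig(n, s, k) for n, s in
                        mio.read_fasta(ROOT / "assembly" / name / f"contigs_k{k}.fa")]
    return sets


def main():
    for name in DATASETS:
        genomes = load_genomes(name)
        sets = load_sets(name)
        index = ReferenceIndex(genomes)
        seen: dict[str, list] = {}
        stats = []
        for label, contigs in sets.items():
            if not contigs:
                continue
            todo = [c for c in contigs if c.contig_id not in seen]
            seen.update(align_contigs(todo, index))
            stats.append(summarize(label, contigs,
                                   score_contigs(contigs, seen)))
        out = ROOT / "evaluation" / name
        out.mkdir(parents=True, exist_ok=True)
        table = stats_table(stats)
        table.to_csv(out / "summary.tsv", sep="\t", index=False)
        length_distributions(sets, CUTOFFS) \
            .to_csv(out / "length_distribution.tsv", sep="\t", index=False)
        print(f"== {name}")
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
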