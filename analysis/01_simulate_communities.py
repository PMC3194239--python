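#!/usr/bin/env python
"""Simulate the study datasets.

Builds the three communities (simLC: one dominant organism, simMC: a few
dominant organisms including a congeneric pair, simHC: strain-rich with no
dominant), draws 200k 36 bp reads from each under the matching abundance
profile, and writes genomes, taxonomy, reads and read provenance under
results/data/<dataset>/.  Also simulates the five-strain mixture and its
single-strain isolate counterpart.
"""

from pathlib import Path

from metaseval import io as mio
from metaseval.community import (SimulationConfig, make_community,
                                 make_profile, simulate_reads)
from metaseval.pipeline import derive_seed
from metaseval.study import (STRAIN_N_READS, strain_genomes, trend_configs)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def write_dataset(name, genomes, reads):
    d = OUT / name
    d.mkdir(parents=True, exist_ok=True)
    mio.write_genomes_fasta(d / "genomes.fa", genomes)
    mio.write_taxonomy_tsv(d / "taxonomy.tsv", genomes)
    mio.write_reads(d / "reads.fastq", reads)
    mio.write_provenance_tsv(d / "provenance.tsv", reads)
    print(f"{name}: {len(genomes)} genomes "
          f"({sum(len(g) for g in genomes)} bases), {len(reads)} reads")


def main():
    for name, cfg in trend_configs(SEED).items():
        genomes = make_community(cfg.community,
                                 seed=derive_seed(cfg.seed, "community"))
        profile = make_profile(cfg.profile, genomes)
        reads = simulate_reads(genomes, profile, SimulationConfig(
            n_reads=cfg.n_reads, seed=derive_seed(cfg.seed, "reads")))
        write_dataset(name, genomes, reads)

    genomes = strain_genomes(SEED)
    reads = simulate_reads(genomes, make_profile("uniform", genomes),
                           SimulationConfig(n_reads=STRAIN_N_READS,
                                            seed=derive_seed(SEED, "reads")))
    write_dataset("strains", genomes, reads)
    iso = genomes[:1]
    reads = simulate_reads(iso, make_profile("uniform", iso),
                           SimulationConfig(
                               n_reads=STRAIN_N_READS,
                               seed=derive_seed(derive_seed(SEED, "isolate-run"),
                                                "reads")))
    write_dataset("isolate", iso, reads)


if __name__ == "__main__":
    main()
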