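#!/usr/bin/env python
"""Pool the per-k contig sets by greedy incremental clustering.

For each dataset, pools all k runs into the clustered set "C" and all runs
except k=21 into "C-21" (containment identity 95%, word size 8), writing the
representative FASTA and cluster membership TSVs under results/clustered/.
Pooling keeps the longest version of every sequence and every unique
sequence — including mis-assembled ones, which is why C accumulates errors.
"""

from pathlib import Path

import pandas as pd

from metaseval import io as mio
from metaseval.assembler import Contig, DEFAULT_KS
from metaseval.pooling import pool_k_runs

ROOT = Path(__file__).resolve().parent.parent / "results"
DATASETS = ("simLC", "simMC", "simHC", "strains", "isolate")


def load_runs(name):
    runs = {}
    for k in DEFAULT_KS:
        path = ROOT / "assembly" / name / f"contigs_k{k}.fa"
        runs[k] = [Contig(n, s, k) for n, s in mio.read_fasta(path)]
    return runs


def main():
    for name in DATASETS:
        runs = load_runs(name)
        out = ROOT / "clustered" / name
        out.mkdir(parents=True, exist_ok=True)
        for label, exclude in (("C", ()), ("C-21", (21,))):
            cs = pool_k_runs(runs, exclude)
            reps = cs.representatives()
            mio.write_fasta(out / f"{label}.fa",
                            ((c.contig_id, c.sequence) for c in reps))
            pd.DataFrame(cs.membership_rows(),
                         columns=["representative_id", "member_id",
                                  "identity", "strand"]) \
                .to_csv(out / f"{label}.clusters.tsv", sep="\t", index=False)
            print(f"{name} {label}: {sum(len(v) for k, v in runs.items() if k not in exclude)}"
                  f" contigs -> {len(reps)} representatives")


if __name__ == "__main__":
    main()
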