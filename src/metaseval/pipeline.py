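"""End-to-end study pipeline: simulate -> assemble -> pool -> align -> score.

One :class:`PipelineConfig` fully determines a run; a single seed drives
independent per-stage generators derived from stable stage labels, so any
stage re-run in isolation reproduces its outputs.  ``run_pipeline`` returns
an in-memory :class:`ReportBundle` and (optionally) writes every intermediate
artifact in a standard text format (FASTA/FASTQ/TSV) under an output
directory, so the pipeline is resumable and inspectable per stage.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .aligner import LocalAlignment, ReferenceIndex, align_contigs
from .assembler import DEFAULT_KS, Contig, assemble, k_sweep
from .community import (CommunityDesign, ReferenceGenome, SimulationConfig,
                        make_community, make_profile, simulate_reads)
from .evaluation import (AssemblyStats, score_contigs, source_coverage,
                         length_distributions, stats_table, summarize)
from .homogeneity import contig_entropy, entropy_table, taxonomy_of
from .pooling import ClusterSet, pool_k_runs

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31 derived from the run seed and a label."""
    return (base_seed * 1_000_003 + zlib.crc32(label.encode())) % (2 ** 31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one dataset's full analysis."""

    profile: str = "simHC"
    n_reads: int = 200_000
    read_length: int = 36
    error_model: str = "solexa_like"
    ks: tuple = DEFAULT_KS
    min_multiplicity: int | None = None  # default: 2 with errors on, else 1
    min_contig_length: int = 50
    identity_threshold: float = 0.95
    word_size: int = 8
    min_anchor_length: int = 15
    min_cluster_size: int = 30
    max_gap: int = 90
    accuracy_threshold: float = 0.95
    max_mismatches: int = 2
    isolate: bool = False  # partition reads by true source before assembling
    community: CommunityDesign = field(default_factory=CommunityDesign)
    seed: int = 0

    @property
    def effective_min_multiplicity(self) -> int:
        if self.min_multiplicity is not None:
            return self.min_multiplicity
        return 2 if self.error_model == "solexa_like" else 1

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["community"] = dataclasses.asdict(self.community)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        comm = d.pop("community", None)
        cfg = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        if comm is not None:
            comm = {k: tuple(v) if isinstance(v, list) else v for k, v in comm.items()}
            cfg["community"] = CommunityDesign(**comm)
        return cls(**cfg)


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run, kept in memory."""

    config: PipelineConfig
    genomes: list[ReferenceGenome]
    reads: list
    k_to_contigs: dict[int, list[Contig]]
    clustered: ClusterSet
    clustered_no21: ClusterSet | None
    alignments: dict[str, list[LocalAlignment]]
    stats: list[AssemblyStats]
    coverage: dict[str, float]          # clustered-set source coverage ratios
    entropy_records: list
    length_dist: pd.DataFrame

    def stats_by_label(self) -> dict[str, AssemblyStats]:
        return {s.label: s for s in self.stats}


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 genomes: list[ReferenceGenome] | None = None) -> ReportBundle:
    """Run the full study for one dataset.

    A pre-built community can be passed so several abundance profiles share
    the same genomes (as the source datasets of the study do).
    """
    if genomes is None:
        genomes = make_community(config.community,
                                 seed=derive_seed(config.seed, "community"))
    profile = make_profile(config.profile, genomes)
    sim = SimulationConfig(n_reads=config.n_reads, read_length=config.read_length,
                           error_model=config.error_model,
                           seed=derive_seed(config.seed, "reads"))
    reads = simulate_reads(genomes, profile, sim)
    logger.info("stage simulate: %d genomes, %d reads", len(genomes), len(reads))

    mm = config.effective_min_multiplicity
    if config.isolate:
        k_to_contigs = _isolate_sweep(reads, config, mm)
    else:
        k_to_contigs = k_sweep(reads, config.ks, mm, config.min_contig_length)
    logger.info("stage assemble: %s",
                {k: len(v) for k, v in k_to_contigs.items()})

    clustered = pool_k_runs(k_to_contigs, (), config.identity_threshold,
                            config.word_size)
    smallest_k = min(config.ks)
    clustered_no21 = None
    if len(config.ks) > 1:
        clustered_no21 = pool_k_runs(k_to_contigs, (smallest_k,),
                                     config.identity_threshold, config.word_size)
    logger.info("stage cluster: C=%d C-%d=%d", len(clustered), smallest_k,
                len(clustered_no21) if clustered_no21 else 0)

    # contig ids are unique across k runs and the clustered sets reuse the
    # member contigs unchanged, so one alignment pass covers every set
    all_contigs = [c for k in sorted(k_to_contigs) for c in k_to_contigs[k]]
    index = ReferenceIndex(genomes, config.min_anchor_length)
    alignments = align_contigs(all_contigs, index, config.min_cluster_size,
                               config.max_gap)
    logger.info("stage align: %d contigs aligned",
                sum(1 for v in alignments.values() if v))

    sets: dict[str, list[Contig]] = {"C": clustered.representatives()}
    if clustered_no21 is not None:
        sets[f"C-{smallest_k}"] = clustered_no21.representatives()
    for k in sorted(k_to_contigs):
        sets[str(k)] = k_to_contigs[k]

    stats, accuracies = [], {}
    for label, contigs in sets.items():
        accs = score_contigs(contigs, alignments)
        accuracies[label] = accs
        if contigs:
            stats.append(summarize(label, contigs, accs))

    cov_masks = source_coverage(genomes, sets["C"], alignments,
                                config.accuracy_threshold)
    coverage = {rid: m.ratio for rid, m in sorted(cov_masks.items())}

    records, assignment = contig_entropy(reads, sets["C"], taxonomy_of(genomes),
                                         config.max_mismatches)
    cutoffs = [50, 100, 200, 400, 800, 1600, 3200, 6400, 12800, 10 ** 9]
    ldist = length_distributions(sets, cutoffs)

    bundle = ReportBundle(config, genomes, reads, k_to_contigs, clustered,
                          clustered_no21, alignments, stats, coverage,
                          records, ldist)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), assignment)
    return bundle


def _isolate_sweep(reads, config: PipelineConfig, mm: int) -> dict[int, list[Contig]]:
    """Isolate-assembly baseline: assemble reads of each true source
    separately and combine the contigs of each k run."""
    by_source: dict[str, list] = {}
    for r in reads:
        by_source.setdefault(r.true_source, []).append(r)
    out: dict[int, list[Contig]] = {k: [] for k in config.ks}
    for si, src in enumerate(sorted(by_source)):
        sub = by_source[src]
        for k in config.ks:
            if not sub or max(len(r.bases) for r in sub) < k:
                continue
            for c in assemble(sub, k, mm, config.min_contig_length):
                out[k].append(Contig(f"{k}_i{si:02d}_{c.contig_id}",
                                     c.sequence, k))
    return out


def _write_bundle(bundle: ReportBundle, out: Path, assignment) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    (out / "config.yaml").write_text(cfg.to_yaml())
    mio.write_genomes_fasta(out / "genomes.fa", bundle.genomes)
    mio.write_taxonomy_tsv(out / "taxonomy.tsv", bundle.genomes)
    mio.write_reads(out / "reads.fastq", bundle.reads)
    mio.write_provenance_tsv(out / "provenance.tsv", bundle.reads)
    log_rows = []
    for k, contigs in sorted(bundle.k_to_contigs.items()):
        mio.write_fasta(out / f"contigs_k{k}.fa",
                        ((f"{c.contig_id} len={len(c)}", c.sequence) for c in contigs))
        log_rows.append((k, len(contigs), sum(len(c) for c in contigs)))
    pd.DataFrame(log_rows, columns=["k", "n_contigs", "total_bases"]) \
        .to_csv(out / "assembly_log.tsv", sep="\t", index=False)
    for name, cs in (("C", bundle.clustered), ("C-min", bundle.clustered_no21)):
        if cs is None:
            continue
        mio.write_fasta(out / f"clustered_{name}.fa",
                        ((c.contig_id, c.sequence) for c in cs.representatives()))
        pd.DataFrame(cs.membership_rows(),
                     columns=["representative_id", "member_id", "identity", "strand"]) \
            .to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
    aln_rows = [(a.contig_id, a.ref_id, a.contig_start, a.contig_end,
                 a.ref_start, a.ref_end, a.strand, a.matches, a.mismatches,
                 a.insertions, a.deletions, round(a.local_acc, 6), a.align_len)
                for alns in bundle.alignments.values() for a in alns]
    pd.DataFrame(aln_rows, columns=["contig_id", "ref_id", "c_start", "c_end",
                                    "r_start", "r_end", "strand", "matches",
                                    "mismatches", "ins", "del", "localAcc",
                                    "alignLen"]) \
        .to_csv(out / "alignments.tsv", sep="\t", index=False)
    stats_table(bundle.stats).to_csv(out / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(bundle.coverage.items()), columns=["ref_id", "coverage_ratio"]) \
        .to_csv(out / "source_coverage.tsv", sep="\t", index=False)
    entropy_table(bundle.entropy_records).to_csv(out / "entropy.tsv", sep="\t",
                                                 index=False)
    bundle.length_dist.to_csv(out / "length_distribution.tsv", sep="\t", index=False)
    rows = [(rid, a.contig_id, a.pos, a.strand, a.mismatches)
            for rid, a in sorted(assignment.items())]
    pd.DataFrame(rows, columns=["read_id", "contig_id", "pos", "strand",
                                "mismatches"]) \
        .to_csv(out / "read_mapping.tsv", sep="\t", index=False)


def compare_runs(bundle_a: ReportBundle, bundle_b: ReportBundle,
                 labels=("a", "b")) -> pd.DataFrame:
    """Side-by-side summary of two runs over the same community.

    A run over a subset of the other's genomes is allowed: the isolate
    baseline assembles reads from a member of the same community.
    """
    ga = {(g.genome_id, g.sequence) for g in bundle_a.genomes}
    gb = {(g.genome_id, g.sequence) for g in bundle_b.genomes}
    if not (ga <= gb or gb <= ga):
        raise ValueError("bundles were produced from different communities")
    from .homogeneity import mean_entropy

    rows = []
    for name, b in zip(labels, (bundle_a, bundle_b)):
        by = b.stats_by_label()
        c = by.get("C")
        seq = [r for r in b.entropy_records if r.level == "sequence"]
        rows.append({
            "run": name,
            "profile": b.config.profile,
            "isolate": b.config.isolate,
            "clustered_n50": c.n50 if c else 0,
            "clustered_pct_accurate": c.pct_accurate if c else 0.0,
            "clustered_total_bases": c.total_bases if c else 0,
            "mean_coverage_ratio": (sum(b.coverage.values()) / len(b.coverage))
            if b.coverage else 0.0,
            "mean_sequence_entropy": mean_entropy(b.entropy_records, "sequence")
            if seq else 0.0,
        })
    return pd.DataFrame(rows)
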