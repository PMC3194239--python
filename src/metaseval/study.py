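"""Preset study configurations: the datasets the evaluation is run on.

Three community datasets of graded complexity (one dominant organism, a few
dominant organisms, no dominant organism over a strain-rich flora), each of
200k 36 bp reads, plus a uniform five-strain mixture with its single-strain
isolate counterpart.  These presets define the study conditions used by the
analysis scripts and the end-to-end tests; their numbers are the package's
scaled-down stand-ins for full sequencing-run datasets.
"""

from __future__ import annotations

from .community import (HIGH_COMPLEXITY_DESIGN, LOW_COMPLEXITY_DESIGN,
                        MEDIUM_COMPLEXITY_DESIGN, generate_genomes)
from .pipeline import PipelineConfig, ReportBundle, derive_seed, run_pipeline

#: reads per community dataset (~7 Mb of sequence against 2-3 Mb of genomes)
TREND_N_READS = 200_000
#: reads in the strain-mixture dataset: ~2.3x depth per strain, the depth of
#: the uniform strain mixture this emulates
STRAIN_N_READS = 32_000
STRAIN_COUNT = 5
STRAIN_DIVERGENCE = 0.01
STRAIN_GENOME_LENGTH = 100_000


def trend_configs(seed: int) -> dict[str, PipelineConfig]:
    """The three community datasets.

    Each complexity class pairs its abundance profile with a community
    composition of matching character, as the mock metagenomes this emulates
    did: a lone large dominant over a mildly related tail (simLC), related
    co-dominant species (simMC), and a strain-rich flora with no dominant
    (simHC).
    """
    return {
        "simLC": PipelineConfig(profile="simLC", n_reads=TREND_N_READS,
                                community=LOW_COMPLEXITY_DESIGN, seed=seed),
        "simMC": PipelineConfig(profile="simMC", n_reads=TREND_N_READS,
                                community=MEDIUM_COMPLEXITY_DESIGN, seed=seed),
        "simHC": PipelineConfig(profile="simHC", n_reads=TREND_N_READS,
                                community=HIGH_COMPLEXITY_DESIGN, seed=seed),
    }


def run_trend_study(seed: int, out_dir=None) -> dict[str, ReportBundle]:
    """Run the three community datasets end to end."""
    bundles = {}
    for name, cfg in trend_configs(seed).items():
        sub = None if out_dir is None else f"{out_dir}/{name}"
        bundles[name] = run_pipeline(cfg, out_dir=sub)
    return bundles


def strain_genomes(seed: int):
    """One five-strain family at 1% divergence."""
    return generate_genomes(
        STRAIN_COUNT, (STRAIN_GENOME_LENGTH, STRAIN_GENOME_LENGTH),
        n_strain_families=1, family_size=STRAIN_COUNT,
        strain_divergence=STRAIN_DIVERGENCE,
        seed=derive_seed(seed, "strain-genomes"))


def run_strain_study(seed: int, out_dir=None) -> dict[str, ReportBundle]:
    """Strain-mixture co-assembly versus its isolate counterpart.

    The mixture draws reads uniformly from five strains of one species; the
    isolate draws the same number of reads from the first strain alone, so
    the two assemblies see identical data volumes.
    """
    genomes = strain_genomes(seed)
    mix_cfg = PipelineConfig(profile="uniform", n_reads=STRAIN_N_READS, seed=seed)
    iso_cfg = PipelineConfig(profile="uniform", n_reads=STRAIN_N_READS,
                             seed=derive_seed(seed, "isolate-run"))
    mixture = run_pipeline(mix_cfg, genomes=genomes,
                           out_dir=None if out_dir is None else f"{out_dir}/strains")
    isolate = run_pipeline(iso_cfg, genomes=genomes[:1],
                           out_dir=None if out_dir is None else f"{out_dir}/isolate")
    return {"strains": mixture, "isolate": isolate}
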