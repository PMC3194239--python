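"""Simulated metagenomic communities with ground-truth read provenance.

This module builds the synthetic study material: reference genomes with a
four-level taxonomy (strain/sequence, species, genus, phylum), abundance
profiles of three community complexities (simLC: one dominant organism,
simMC: a few dominant organisms, simHC: no dominant organism) plus uniform
strain mixtures, and 36 bp Illumina-like reads whose identifiers encode the
generating genome, position, strand and mate so that every downstream metric
can be computed against ground truth.

Real metagenomes contain organisms related at every taxonomic distance, and
that relatedness — near-identical strains, congeneric species, short
conserved segments shared across genera — is what makes co-assembly and
chimerism possible.  ``make_community`` therefore plants all three kinds of
homology into an otherwise random genome set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .seq import point_mutate, random_sequence, revcomp

logger = logging.getLogger(__name__)

READ_ID_SEP = "|"


@dataclass(frozen=True)
class Taxonomy:
    """Four-level taxonomic label of a source sequence."""

    strain: str
    species: str
    genus: str
    phylum: str

    def level(self, name: str) -> str:
        if name in ("strain", "sequence"):
            return self.strain
        if name in ("species", "genus", "phylum"):
            return getattr(self, name)
        raise ValueError(f"unknown taxonomic level: {name!r}")


@dataclass(frozen=True)
class ReferenceGenome:
    """A source sequence together with its taxonomy; ground truth for all metrics."""

    genome_id: str
    sequence: str
    taxonomy: Taxonomy

    def __post_init__(self) -> None:
        if len(self.sequence) < 1000:
            raise ValueError("reference sequences must be at least 1000 bp")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet is strictly {A,C,G,T}")
        if READ_ID_SEP in self.genome_id:
            raise ValueError(f"genome_id must not contain {READ_ID_SEP!r}")
        for f in (self.taxonomy.strain, self.taxonomy.species,
                  self.taxonomy.genus, self.taxonomy.phylum):
            if not f:
                raise ValueError("every taxonomy field must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative read abundances per genome; weights are fractions summing to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("profile must contain at least one genome")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all abundance weights must be positive")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance weights must sum to 1 (got {total})")

    def validate_against(self, genomes: list[ReferenceGenome]) -> None:
        ids = {g.genome_id for g in genomes}
        if set(self.weights) != ids:
            raise ValueError("profile keys must exactly match the community genome_ids")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one read-simulation run.

    ``error_model`` is ``"none"`` (reads are exact substrings) or
    ``"solexa_like"`` (per-base substitution probability rising linearly from
    0.001 at the 5' end to 0.01 at the 3' end, no indels).
    """

    n_reads: int
    read_length: int = 36
    error_model: str = "solexa_like"
    paired: bool = False
    insert_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.error_model not in ("none", "solexa_like"):
            raise ValueError(f"unknown error model: {self.error_model!r}")
        if self.paired and self.insert_length <= 2 * self.read_length:
            raise ValueError("insert_length must exceed 2 x read_length for paired reads")


@dataclass(frozen=True)
class SimulatedRead:
    """A read whose id encodes its provenance: genome_id|start|strand|mate."""

    read_id: str
    bases: str
    true_source: str


def format_read_id(genome_id: str, start: int, strand: str, mate: int) -> str:
    return READ_ID_SEP.join((genome_id, str(start), strand, str(mate)))


def parse_read_id(read_id: str) -> tuple[str, int, str, int]:
    """Recover (genome_id, 0-based start, strand, mate index) from a read id."""
    genome_id, start, strand, mate = read_id.rsplit(READ_ID_SEP, 3)
    if strand not in "+-":
        raise ValueError(f"malformed read id: {read_id!r}")
    return genome_id, int(start), strand, int(mate)


def total_megabases(n_reads: int, read_length: int = 36) -> float:
    """Total sequence data of a dataset in Mb (1 Mb = 1e6 bases)."""
    return n_reads * read_length / 1e6


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _phylum_name(i: int) -> str:
    return f"phylum{i % 3:02d}"


def generate_genomes(
    n_genomes: int,
    length_range: tuple[int, int],
    n_strain_families: int = 0,
    strain_divergence: float = 0.0,
    seed: int = 0,
    family_size: int = 2,
    gc: float = 0.5,
) -> list[ReferenceGenome]:
    """Generate a community of random reference genomes.

    ``n_strain_families`` families of ``family_size`` near-identical strains
    are built by copying a base genome and applying i.i.d. point substitutions
    at rate ``strain_divergence``; family members share species, genus and
    phylum but carry distinct strain labels.  The remaining genomes are
    unrelated (i.i.d. uniform sequence), each its own species and genus.
    ``n_genomes`` counts all sequences, family members included.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not (0 <= strain_divergence < 0.2):
        raise ValueError("strain_divergence must be in [0, 0.2)")
    lo, hi = length_range
    if lo < 1000 or hi < lo:
        raise ValueError("length_range must satisfy 1000 <= min <= max")
    if n_strain_families * family_size > n_genomes:
        raise ValueError("strain families exceed n_genomes")

    rng = np.random.default_rng(seed)
    genomes: list[ReferenceGenome] = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"g{serial:03d}"

    for fam in range(n_strain_families):
        length = int(rng.integers(lo, hi + 1))
        base = random_sequence(rng, length, gc=gc)
        species = f"species_fam{fam:02d}"
        genus = f"genus_fam{fam:02d}"
        phylum = _phylum_name(fam)
        for member in range(family_size):
            gid = next_id()
            seqv = base if member == 0 else point_mutate(rng, base, strain_divergence)
            genomes.append(ReferenceGenome(
                gid, seqv,
                Taxonomy(strain=gid, species=species, genus=genus, phylum=phylum)))

    singleton = 0
    while len(genomes) < n_genomes:
        length = int(rng.integers(lo, hi + 1))
        gid = next_id()
        genomes.append(ReferenceGenome(
            gid, random_sequence(rng, length, gc=gc),
            Taxonomy(strain=gid,
                     species=f"species_s{singleton:02d}",
                     genus=f"genus_s{singleton:02d}",
                     phylum=_phylum_name(n_strain_families + singleton))))
        singleton += 1
    return genomes


def plant_conserved_segments(
    genomes: list[ReferenceGenome],
    n_segments: int,
    segment_length: int,
    copies_per_segment: int,
    divergence: float,
    seed: int = 0,
) -> list[ReferenceGenome]:
    """Plant diverged copies of shared segments across genomes.

    Emulates conserved genes and mobile elements: each segment is a random
    sequence written (with per-copy point substitutions at ``divergence``)
    over a uniformly chosen interval of each of ``copies_per_segment``
    distinct genomes.  Returns new genome objects; taxonomy is unchanged.
    """
    if copies_per_segment > len(genomes):
        raise ValueError("copies_per_segment exceeds the number of genomes")
    rng = np.random.default_rng(seed)
    seqs = {g.genome_id: g.sequence for g in genomes}
    order = [g.genome_id for g in genomes]
    for _ in range(n_segments):
        segment = random_sequence(rng, segment_length)
        chosen = rng.choice(len(order), size=copies_per_segment, replace=False)
        for gi in sorted(int(i) for i in chosen):
            gid = order[gi]
            s = seqs[gid]
            if len(s) <= segment_length:
                continue
            pos = int(rng.integers(0, len(s) - segment_length + 1))
            copy = point_mutate(rng, segment, divergence)
            seqs[gid] = s[:pos] + copy + s[pos + segment_length:]
    return [replace(g, sequence=seqs[g.genome_id]) for g in genomes]


@dataclass(frozen=True)
class CommunityDesign:
    """Relatedness structure of a desk-scale community.

    The community mixes the kinds of homology found in real metagenomes:
    strain families (near-identical, shared species), congeneric species
    pairs (diverged ~10%, shared genus), unrelated singletons, short
    conserved segments (diverged ~8%, like inter-species homologous genes)
    shared across genomes, and within-genome repeat families (diverged ~10%,
    like insertion-sequence elements).  Genome order matters to the abundance
    profiles, which assign dominance to the first ids: the lead singleton
    (optionally drawn at a fixed larger ``dominant_length``) comes first,
    then the first congeneric pair, the remaining singletons, the remaining
    congener pairs, and the strain families last.  A medium-complexity
    profile over this order therefore places one unrelated organism and one
    congeneric species pair at dominant abundance — related co-dominants
    being a realistic feature of bloom-like communities.
    """

    n_strain_families: int = 2
    strain_family_size: int = 2
    strain_divergence: float = 0.01
    n_congener_pairs: int = 2
    congener_divergence: float = 0.10
    n_singletons: int = 4
    length_range: tuple[int, int] = (60_000, 100_000)
    dominant_length: int | None = 100_000
    n_conserved_segments: int = 20
    conserved_segment_length: int = 500
    conserved_copies: int = 4
    conserved_divergence: float = 0.08
    repeat_families_per_genome: int = 2
    repeat_copies: int = 3
    repeat_length: int = 400
    repeat_divergence: float = 0.10

    @property
    def n_genomes(self) -> int:
        return (self.strain_family_size * self.n_strain_families
                + 2 * self.n_congener_pairs + self.n_singletons)


#: low-complexity community: one large deeply-sequenced dominant organism
#: over a mildly related low-abundance tail
LOW_COMPLEXITY_DESIGN = CommunityDesign(
    n_singletons=6, n_congener_pairs=1, congener_divergence=0.10,
    n_strain_families=2, dominant_length=200_000)

#: medium-complexity community: a few dominant organisms, two of them
#: congeneric species — related co-dominants as in bloom-like communities
MEDIUM_COMPLEXITY_DESIGN = CommunityDesign(
    n_singletons=4, n_congener_pairs=2, congener_divergence=0.06,
    n_strain_families=2, dominant_length=100_000)

#: strain-rich, no-dominant community in the spirit of high-complexity mock
#: datasets, whose defining difficulty is many closely related strains
HIGH_COMPLEXITY_DESIGN = CommunityDesign(
    n_strain_families=4, strain_family_size=3, strain_divergence=0.02,
    n_congener_pairs=2, n_singletons=4, dominant_length=None,
    n_conserved_segments=30, conserved_copies=4)


def make_community(design: CommunityDesign = CommunityDesign(), seed: int = 0,
                   ) -> list[ReferenceGenome]:
    """Build a community with strain, species, segment and repeat homology."""
    rng = np.random.default_rng(seed)
    lo, hi = design.length_range
    genomes: list[ReferenceGenome] = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"g{serial:03d}"

    def add_singleton(s: int, length: int) -> None:
        gid = next_id()
        genomes.append(ReferenceGenome(
            gid, random_sequence(rng, length),
            Taxonomy(gid, f"species_s{s:02d}", f"genus_s{s:02d}", _phylum_name(s))))

    def add_congener_pair(fam: int) -> None:
        base = random_sequence(rng, int(rng.integers(lo, hi + 1)))
        genus = f"genus_cg{fam:02d}"
        phylum = _phylum_name(design.n_singletons + fam)
        for member in range(2):
            gid = next_id()
            seqv = base if member == 0 else point_mutate(rng, base,
                                                         design.congener_divergence)
            genomes.append(ReferenceGenome(
                gid, seqv,
                Taxonomy(gid, f"species_cg{fam:02d}{'ab'[member]}", genus, phylum)))

    n_single = design.n_singletons
    if n_single:
        add_singleton(0, design.dominant_length
                      or int(rng.integers(lo, hi + 1)))
    if design.n_congener_pairs:
        add_congener_pair(0)
    for s in range(1, n_single):
        add_singleton(s, int(rng.integers(lo, hi + 1)))
    for fam in range(1, design.n_congener_pairs):
        add_congener_pair(fam)

    for fam in range(design.n_strain_families):
        base = random_sequence(rng, int(rng.integers(lo, hi + 1)))
        species, genus = f"species_st{fam:02d}", f"genus_st{fam:02d}"
        phylum = _phylum_name(design.n_singletons + design.n_congener_pairs + fam)
        for member in range(design.strain_family_size):
            gid = next_id()
            seqv = base if member == 0 else point_mutate(rng, base,
                                                         design.strain_divergence)
            genomes.append(ReferenceGenome(
                gid, seqv, Taxonomy(gid, species, genus, phylum)))

    if design.n_conserved_segments > 0:
        genomes = plant_conserved_segments(
            genomes,
            n_segments=design.n_conserved_segments,
            segment_length=design.conserved_segment_length,
            copies_per_segment=design.conserved_copies,
            divergence=design.conserved_divergence,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    if design.repeat_families_per_genome > 0:
        genomes = plant_repeat_families(
            genomes,
            families_per_genome=design.repeat_families_per_genome,
            copies=design.repeat_copies,
            repeat_length=design.repeat_length,
            divergence=design.repeat_divergence,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return genomes


def plant_repeat_families(
    genomes: list[ReferenceGenome],
    families_per_genome: int,
    copies: int,
    repeat_length: int,
    divergence: float,
    seed: int = 0,
) -> list[ReferenceGenome]:
    """Plant within-genome repeat families (insertion-sequence-like elements).

    Per genome, ``families_per_genome`` random elements are each written at
    ``copies`` random positions with per-copy point substitutions at
    ``divergence``.  Returns new genome objects; taxonomy is unchanged.
    """
    rng = np.random.default_rng(seed)
    out = []
    for g in genomes:
        s = g.sequence
        for _ in range(families_per_genome):
            element = random_sequence(rng, repeat_length)
            for _ in range(copies):
                if len(s) <= repeat_length:
                    continue
                pos = int(rng.integers(0, len(s) - repeat_length + 1))
                copy = point_mutate(rng, element, divergence)
                s = s[:pos] + copy + s[pos + repeat_length:]
        out.append(replace(g, sequence=s))
    return out


# ---------------------------------------------------------------------------
# abundance profiles
# ---------------------------------------------------------------------------

def make_profile(kind: str, genomes: list[ReferenceGenome],
                 dominant_fraction: float | None = None,
                 n_dom: int = 3) -> AbundanceProfile:
    """Build an abundance profile of the requested community complexity.

    simLC: one genome holds ``dominant_fraction`` (default 0.5) of the reads,
    the rest share the remainder equally.  simMC: ``n_dom`` genomes (default 3)
    share ``dominant_fraction`` (default 0.45) equally, the rest equal.
    simHC and uniform: all genomes equal.
    """
    ids = [g.genome_id for g in genomes]
    n = len(ids)
    if n < 1:
        raise ValueError("need at least one genome")
    if kind == "simLC":
        f = 0.5 if dominant_fraction is None else dominant_fraction
        if n == 1:
            return AbundanceProfile({ids[0]: 1.0})
        rest = (1 - f) / (n - 1)
        return AbundanceProfile({gid: (f if i == 0 else rest) for i, gid in enumerate(ids)})
    if kind == "simMC":
        if n < 3:
            raise ValueError("simMC needs at least 3 genomes")
        f = 0.45 if dominant_fraction is None else dominant_fraction
        if n_dom >= n:
            raise ValueError("n_dom must be smaller than the number of genomes")
        dom = f / n_dom
        rest = (1 - f) / (n - n_dom)
        return AbundanceProfile({gid: (dom if i < n_dom else rest) for i, gid in enumerate(ids)})
    if kind in ("simHC", "uniform"):
        return AbundanceProfile({gid: 1.0 / n for gid in ids})
    raise ValueError(f"unknown profile kind: {kind!r}")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_ERROR_P5, _ERROR_P3 = 0.001, 0.01


def error_ramp(read_length: int) -> np.ndarray:
    """Per-position substitution probabilities of the Solexa-like error model."""
    if read_length == 1:
        return np.array([_ERROR_P5])
    return np.linspace(_ERROR_P5, _ERROR_P3, read_length)


def _apply_errors(bases_list: list[str], rng: np.random.Generator,
                  read_length: int) -> list[str]:
    """Apply the substitution ramp to a list of equal-length reads in place."""
    n = len(bases_list)
    if n == 0:
        return bases_list
    p = error_ramp(read_length)
    hit = rng.random((n, read_length)) < p
    # draw the substitution offsets up front so the RNG stream is stable
    rows = np.nonzero(hit.any(axis=1))[0]
    out = list(bases_list)
    lut = "ACGT"
    code = {b: i for i, b in enumerate(lut)}
    for r in rows:
        cols = np.nonzero(hit[r])[0]
        offs = rng.integers(1, 4, size=cols.size)
        chars = list(out[r])
        for c, o in zip(cols, offs):
            chars[c] = lut[(code[chars[c]] + o) % 4]
        out[r] = "".join(chars)
    return out


def _eligible(genomes: list[ReferenceGenome], min_length: int,
              profile: AbundanceProfile) -> tuple[list[ReferenceGenome], np.ndarray]:
    kept = []
    for g in genomes:
        if len(g) < min_length:
            logger.warning("excluding genome %s: length %d < %d",
                           g.genome_id, len(g), min_length)
        else:
            kept.append(g)
    if not kept:
        raise ValueError("all genomes are shorter than the required fragment length")
    w = np.array([profile.weights[g.genome_id] for g in kept], dtype=float)
    return kept, w / w.sum()


def simulate_reads(genomes: list[ReferenceGenome], profile: AbundanceProfile,
                   config: SimulationConfig) -> list[SimulatedRead]:
    """Simulate single-end reads with ground-truth provenance.

    Source genomes are drawn multinomially from the profile, start positions
    uniformly over [0, L - read_length], strands uniformly.  A minus-strand
    read's bases are the reverse complement of the forward-strand substring at
    its recorded coordinates.
    """
    profile.validate_against(genomes)
    L = config.read_length
    kept, w = _eligible(genomes, L, profile)
    rng = np.random.default_rng(config.seed)
    src = rng.choice(len(kept), size=config.n_reads, p=w)
    strands = rng.integers(0, 2, size=config.n_reads)
    u = rng.random(config.n_reads)
    reads: list[SimulatedRead] = []
    bases_list: list[str] = []
    for i in range(config.n_reads):
        g = kept[src[i]]
        start = int(u[i] * (len(g) - L + 1))
        frag = g.sequence[start:start + L]
        strand = "+" if strands[i] == 0 else "-"
        bases = frag if strand == "+" else revcomp(frag)
        bases_list.append(bases)
        reads.append(SimulatedRead(
            format_read_id(g.genome_id, start, strand, 0), bases, g.genome_id))
    if config.error_model == "solexa_like":
        bases_list = _apply_errors(bases_list, rng, L)
        reads = [replace(r, bases=b) for r, b in zip(reads, bases_list)]
    return reads


def simulate_paired(genomes: list[ReferenceGenome], profile: AbundanceProfile,
                    config: SimulationConfig) -> list[tuple[SimulatedRead, SimulatedRead]]:
    """Simulate mate pairs: the two ends of an insert-length fragment.

    Mate 1 is the first ``read_length`` bases of the fragment on its sampled
    strand; mate 2 is the reverse complement of the last ``read_length``
    bases (innies).  Both mates carry the same fragment start in their ids
    with mate indices 1 and 2; coordinates are fragment-forward.
    """
    if not config.paired:
        raise ValueError("config.paired must be true for simulate_paired")
    profile.validate_against(genomes)
    L, ins = config.read_length, config.insert_length
    kept, w = _eligible(genomes, ins, profile)
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_reads
    src = rng.choice(len(kept), size=n_pairs, p=w)
    strands = rng.integers(0, 2, size=n_pairs)
    u = rng.random(n_pairs)
    pairs: list[tuple[SimulatedRead, SimulatedRead]] = []
    bases_list: list[str] = []
    for i in range(n_pairs):
        g = kept[src[i]]
        start = int(u[i] * (len(g) - ins + 1))
        frag = g.sequence[start:start + ins]
        if strands[i] == 1:
            frag = revcomp(frag)
        strand = "+" if strands[i] == 0 else "-"
        m1 = frag[:L]
        m2 = revcomp(frag[-L:])
        bases_list.extend((m1, m2))
        pairs.append((
            SimulatedRead(format_read_id(g.genome_id, start, strand, 1), m1, g.genome_id),
            SimulatedRead(format_read_id(g.genome_id, start, strand, 2), m2, g.genome_id),
        ))
    if config.error_model == "solexa_like":
        bases_list = _apply_errors(bases_list, rng, L)
        pairs = [
            (replace(p1, bases=bases_list[2 * i]), replace(p2, bases=bases_list[2 * i + 1]))
            for i, (p1, p2) in enumerate(pairs)
        ]
    return pairs
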