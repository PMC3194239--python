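# Methods

`metaseval` evaluates short-read metagenomic assembly end to end on
simulated communities with known ground truth.  This note records the models,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic data does and does not show about
real metagenomes.

## Read simulation

Reads are 36 bp single-end (optionally paired with a 2 kb insert), drawn in
three steps: the source genome multinomially from the abundance profile, the
start uniformly over `[0, L - 36]`, the strand uniformly.  Coordinates are
0-based, half-open, forward-strand; genomes are linear and reads never span
an end.

The sequencing-error model is a Solexa-like substitution ramp: the per-base
substitution probability rises linearly from 0.001 at the 5' end to 0.01 at
the 3' end (mean 0.55%), substituting uniformly among the other three bases,
with no indels.  Short-read substitution errors dominate this platform and
3'-heavy error growth is its signature; indel errors are rare enough to
ignore at this read length.

Every read id encodes its provenance as `genome_id|start|strand|mate`, so
ground truth survives FASTA/FASTQ round trips without a sidecar (a
provenance TSV is written as well).  Quality strings are constant `I`;
nothing downstream reads quality.

Abundance profiles follow fixed shapes: `simLC` gives one genome half of
the reads and splits the rest equally; `simMC` gives three genomes 45%
combined; `simHC`/`uniform` are flat.  Dataset scale: 200k reads (~7.2 Mb)
per community dataset against communities of roughly 1 Mb of genomes
(50-200 kb per genome) keeps full-study runtime in minutes while placing the
datasets in the coverage regimes that drive the phenomena of interest: the
simLC dominant near 18x, tail and simHC organisms near 1-5x.

## Community designs

Real communities contain organisms related at every distance, and that
relatedness — not read errors — is what makes metagenomic assembly hard.
Each complexity class therefore pairs its profile with a community of
matching composition:

- **Low complexity**: one large (200 kb) dominant singleton over a tail of
  mildly related organisms (two strain pairs at 1% divergence, one
  congeneric pair at 10%, singletons).
- **Medium complexity**: three dominants, two of them congeneric species at
  6% divergence — related co-dominants, as in bloom-like communities.
- **High complexity**: no dominant; a strain-rich flora (four families of
  three strains at 2% divergence plus congener pairs and singletons), the
  composition whose defining difficulty is many closely related strains.

All communities additionally carry short conserved segments (500 bp, ~8%
divergence, copied into several genomes — homologous genes and mobile
elements) and within-genome repeat families (400 bp, 3 copies, ~10%
divergence — insertion-sequence-like elements).  These shared words at
assembly scale are what allow chimeric joins; without them a desk-scale
community of independent random genomes is unrealistically easy to assemble
(genuine chimeras essentially never form, and every trend involving
mis-assembly disappears).

What the generator does *not* emulate: genome-scale gene content and
synteny, GC heterogeneity, coverage biases, quality-correlated errors, and
the sheer sequence volume (hundreds of Mb) of a real run.  Absolute contig
statistics are therefore not comparable to real studies; what the tests pin
down is the *relative* behaviour across k, datasets and pooled sets.

## Assembly

The assembler is a bidirected de Bruijn unitig assembler over canonical
k-mers (k odd, so no k-mer equals its own reverse complement), with edges
restricted to (k-1)-overlaps actually observed between adjacent k-mers in
reads.  Contigs are maximal non-branching paths; output is deterministic
(canonical sequence form, sorted).

Cleaning is the standard minimum for this graph family:

- multiplicity filter: nodes seen fewer than 2 times are dropped when the
  error model is on (error k-mers dominate singletons at study coverages),
  1 otherwise;
- tip clipping: dead-end paths of at most 2k nodes that rejoin a through
  path are removed;
- bubble popping: simple two-path bubbles reconverging within 3k interior
  nodes lose their weaker side (mean multiplicity; ties resolved
  lexicographically for reproducibility).

Tip clipping and bubble popping are load-bearing: without them, coincident
duplicated errors at 20-40x fragment even a deeply covered genome every few
hundred bases, masking every coverage- and k-dependent effect the study
measures.  Popping simple bubbles does *not* erase strain co-assembly
fragmentation: dense polymorphism between strains produces entangled,
non-simple structures that popping cannot resolve.  Contigs shorter than
50 bp are discarded.  The k sweep assembles independently at
k = 21, 23, ..., 33.

Paired-end merging joins two contigs when at least 10 uniquely mapped mate
pairs link them in a consistent orientation; links implying a positive gap
are *not* bridged with N's — the parts are kept separate — and non-positive
gaps are merged only on exact sequence agreement at the implied overlap.

## Pooling

Pooled sets `C` (all k runs) and `C-21` (all but k=21) are built by greedy
incremental clustering: longest sequence first, each next sequence joins the
first representative it matches at containment identity >= 95%, else founds
its own cluster.  A short-word filter (word size 8) screens candidates: a
candidate of length L at identity p must share at least
`L - w + 1 - w * ceil((1-p) * L)` 8-mers with the representative, so failing
the count rejects without alignment.  Containment identity is matching
columns over candidate length, both strands, computed with an optimal infix
edit-distance alignment (edlib); the unbanded optimum is at least as
accurate as a banded heuristic.  Because every unmatched sequence is
retained, mis-assembled contigs accumulate in the pooled sets by
construction — the error-accumulation effect the evaluation quantifies.

## Alignment and scoring

Contigs are aligned to the source genomes by seed-and-extend local
alignment: maximal exact matches of >= 15 bp on both strands (seed index on
the reference), greedy co-linear chaining (anchor clusters under 30 summed
bases discarded, gaps and diagonal drift capped at 90 bp), and banded local
dynamic programming around each chain's diagonals (match +1, mismatch -1,
gap -2 linear; band pad 40, widened once if the optimal in-band path touches
the boundary).  Within its band the extension is an exact local optimum, so
inter-anchor gaps close optimally and ends extend as far as they help. All
alignments are reported, not just the best.  On homologous pairs long
enough for anchoring, the best reported score equals the unbanded
Smith-Waterman optimum; pairs below the anchor/cluster sensitivity (a short
fragment at ~10% divergence with no two anchors within 90 bp) are missed
entirely — that sensitivity floor is a property of the anchoring
parameters, and the test suite pins both behaviours.

Per-contig accuracy is `localAcc * alignLen / contigLen` — alignment
identity scaled by the aligned fraction of the contig — maximised over the
contig's alignments; unaligned contigs score 0, and a contig is *accurate*
at >= 0.95 (`>=`, not `>`).  Source coverage marks reference positions under
every alignment whose own accuracy reaches 0.95 (multi-mapping contigs count
everywhere; positions are flags so the ratio cannot exceed 1).  N50 is the
largest L such that contigs of length >= L hold at least half the assembled
bases.  Report percentages are rounded half-up to two decimals.

## Homogeneity

Each read is assigned to the contig position (either strand) with the
fewest mismatches, ungapped, at most 2 mismatches over 36 bp — the regime of
short-read aligners at this read length, and small enough that a brute-force
oracle stays feasible.  Ties break deterministically (fewest mismatches,
lowest contig id, lowest position, then '+' strand); unmapped reads are
excluded.  Per contig, the entropy of the true-source composition of its
reads is `-sum p_i log2 p_i` (bits), computed at sequence, species, genus
and phylum levels; coarsening the labels can only lower it.

The headline "mean contig entropy" of a contig set is length-weighted — the
average chimerism of an assembled base — because an unweighted mean is
dominated by whichever dataset produces more tiny fragments, regardless of
how much sequence they represent; the per-contig mean is reported alongside
it in the homogeneity tables.

## Pipeline, seeds, determinism

A `PipelineConfig` fully determines a run.  Stage seeds derive from the run
seed and a stable stage label (`derive_seed`), so stages re-run in isolation
reproduce their outputs; identical config and seed give byte-identical
artifacts.  All intermediates are written as FASTA/FASTQ/TSV and are
re-loadable, making the pipeline resumable per stage.

## Study presets and problem sizes

The preset study (used by the analysis scripts and `scripts/acceptance.py`)
runs the three 200k-read community datasets, a five-strain 1%-divergence
mixture of 32k reads (~2.3x per strain) with a same-sized single-strain
isolate counterpart, and an error-free 30x isolate recovery control
(50 kb genome, k=25) in which every contig must be an exact genome
substring, coverage breadth >= 0.99 and all entropies zero.  These sizes are
the package's scaled-down stand-ins for full sequencing-run datasets
(36M reads, ~1300 Mb); the full pipeline over all presets completes in
roughly ten minutes on one core.

## Known limitations

- Contig statistics are not calibrated to any real assembler's internals;
  the unitig-plus-minimal-cleaning model is simpler than production
  assemblers, and its absolute N50s are smaller than theirs would be.
- The within-band optimality of alignment extension holds for the chains the
  anchor stage finds; homology below the anchor sensitivity floor is
  invisible.
- Read mapping is ungapped; a read spanning a true indel (none are simulated)
  would be unmapped rather than split.
- Entropy is computed only over mapped reads; contigs with no mapped reads
  are excluded rather than scored zero.
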