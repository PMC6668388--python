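# Methods

This note documents the models, conventions and numerical choices behind
`lrtc`, what the synthetic data generator does and does not emulate, and
the known limitations.

## Coordinate and CIGAR conventions

All coordinates are 0-based half-open internally; SAM `POS` and GTF
coordinates are converted at the I/O boundary, so BED output needs no
further shifting. `=`/`X` CIGAR ops are folded into `M` on ingestion
because every metric here is stated in M/I/D terms. A missing `NM` tag
makes base accuracy *undefined* for that record (reported as absent),
never silently 0. For hard-clipped records the full read length is
recovered as the sum over M, I, S plus H lengths, so aligned and clipped
fractions remain comparable between primary and supplementary records of
the same read.

## Per-read quality metrics

* aligned fraction = (nM + nI) / read length;
* base accuracy = (nM + nI + nD − NM) / (nM + nI + nD), computed on
  primary genome alignments by default (a flag admits other records);
* clipped fraction = (nS + nH) / read length;
* mean base quality is the arithmetic mean of the per-base Phred
  integers. Averaging error probabilities instead would weight rare
  low-quality bases more heavily; the arithmetic mean was chosen as the
  plain reading of "average reported base quality" and is what the
  simulator's constant-quality reads make exact either way.

## Alignment topology

Secondary alignments are alternative placements; a read's secondary
ambiguity is `same_gene_only` when every primary/secondary target is an
isoform of one gene. Supplementary alignments are split-read
continuations; each is categorized by chromosome, strand and positional
overlap with its primary. Overlap is determined on the full reference
footprint (M, D and N ops) — the footprint a spliced alignment occupies
on the genome — while the overlap *ratio* divides by the primary's
alignment length nM + nD only, so ratios above 1 are possible for
intron-rich primaries. A same-chromosome, opposite-strand, overlapping
supplementary is the signature of an un-split double-stranded read.

The palindrome scan computes, per read, the length of the longest
substring whose perfect reverse complement also occurs in the read,
equivalently the longest common substring of the read and its reverse
complement; values below 10 nt report as 0. The production
implementation builds a suffix automaton of the read and walks the
reverse complement (linear time); tests verify exact agreement with an
independent O(n²) dynamic-programming oracle. `N` bases never match,
including against another `N`. Hairpin geometry (arm/loop constraints)
is deliberately out of scope: the definition is purely string-based.

## Transcript coverage and truncation

The best target transcript of a read is selected among all primary and
secondary transcriptome alignments by (1) keeping alignments whose
aligned-nucleotide count (nM + nI; an nM-only mode exists) is at least
`ratio` (default 0.9) of the per-read maximum, then (2) taking the
survivor with the largest coverage fraction (nM + nD)/transcript length.
Ties go to higher coverage, then the primary record, then the
lexicographically smaller transcript id, making the procedure
deterministic. Because a truncated read of a long isoform also fits any
shorter isoform containing the retained region, the selected coverage is
an upper bound on coverage of the true transcript of origin; tests
verify the bound against simulation truth. Length strata default to
{<1 kb, 1–2 kb, 2–5 kb, ≥5 kb} and are configurable; the 2 kb edge is
where complete single-read coverage becomes rare in real long-read data.

The expected transcript molecule length distribution weights annotated
lengths by TPM. Its comparison against observed primary-aligned read
lengths uses the exact Kolmogorov–Smirnov sup-distance between the two
step functions, evaluated at (and just before) every jump point of
either; a generic continuous-CDF one-sample KS is wrong here because
the expected distribution is discrete with atoms.

## Junctions

Each `N` op of a (by default primary) genome alignment yields one
observed intron; support counts contributing reads. Secondary and
supplementary records are excluded from support by default to prevent
double counting (a flag includes them). The distance between an observed
and an annotated junction is |Δstart| + |Δend|; the nearest annotated
junction is searched per chromosome, strand-agnostic by default (the
distance is defined on positions alone), with ties broken by smaller
intron start. Canonicity: GT donor and AG acceptor on the junction's
strand; when the strand is unknown, the motif-consistent strand is used,
and a junction with no motif-consistent strand is non-canonical.

## Assignment ambiguity

A read's compatibility class at ratio `p` is the set of targets scoring
at least `p` × its best alignment score — a deliberate stand-in for a
quantifier's equivalence classes that mirrors the aligner's `-p`
score-ratio semantics rather than re-implementing k-mer chaining. Class
size is non-increasing in `p` by construction. The nested census tests,
for every unordered same-gene pair, byte-identity and contiguous
substring containment of the spliced sequences; "subsequence" is read as
contiguous substring because that is the containment a read drawn from
one transcript can exhibit in another. The self-assignment experiment
treats each annotated transcript as a proxy for an error-free
full-length read: its alignment set is every transcript containing it
(scored by proxy length) plus every transcript it properly contains
(scored by contained length), and the reported statistic is the fraction
of proxies in singleton classes — the identifiability ceiling of the
catalog itself.

## Counting and saturation

Two counters are provided, both intentionally simple. The transcript
counter assigns each read to its primary transcriptome target when
mapping quality ≥ 5 (truth alignments give ambiguous reads mapq 0, so
multi-target reads drop out, mimicking a mapq filter on a real aligner's
output). The gene counter assigns a primary genome alignment to a gene
when its M/D reference blocks overlap the gene's exon union by ≥ 10
bases; reads passing the threshold for two or more genes are discarded
as ambiguous (an assign-to-max-overlap mode exists). Conservation
(assigned + ambiguous + unassigned = primaries) is asserted in tests.

Saturation curves use *nested* subsampling without replacement — each
depth's sample contains the previous — so curves are exactly monotone
and the full-depth point reproduces full-data detection; independent
resampling is available behind a flag for variance estimation. Pooled
mode merges replicates before sampling. The replicate-exclusive fixture
used in tests puts every pool read on a distinct transcript of one gene,
which forces pooled ≥ single-replicate transcript detection at every
matched depth and makes gene-level curves coincide, with the pooled
full-depth point exceeding any single replicate's ceiling — the
qualitative pooled-vs-single contrast in its sharpest deterministic
form.

## Structural classification

A query transcript's junction chain is compared against a reference
catalog with precedence: identical chain → full splice match; non-empty
consecutive sub-chain of a reference chain → incomplete splice match
("consecutive" because truncation removes junctions only from the ends;
a non-consecutive-subset mode exists for sensitivity analysis); all
junctions annotated but the chain novel → novel in catalog; any
unannotated junction → novel not in catalog. Single-exon queries are
mono-exonic unless they overlap no reference transcript at all, in
which case they are intergenic. Strand must match for chain comparison;
unknown-strand queries are tried on both strands and the
highest-precedence category kept. Transcript 5′/3′ ends are ignored
entirely — classification is chain-only — which means a full splice
match asserts nothing about end completeness. The classifier accepts
any transcript set read from GTF (e.g., an external assembler's output)
and also read-derived chains built directly from spliced alignments; it
performs no assembly.

## The synthetic data generator

The generator is the package's test bed and defines its study
conditions. It emulates:

* **catalog structure** — multi-exon genes (default 2–7 exons of
  80–400 bp, introns 60–800 bp) with up to 3 isoforms sharing junctions:
  exon-skipping variants, nested isoforms built as 5′-exon truncations
  (so the nested sequence is an exact proper substring — a 3′ suffix —
  of its sibling), and byte-identical duplicates; GT–AG motifs planted
  at a configurable fraction of introns (default 0.95);
* **read truncation** — with probability π (default 0.5) a read spans
  its molecule; otherwise a Beta(α, β) fraction (default α=2, β=1, mean
  2/3) is retained, anchored at the 3′ end, matching oligo-dT-primed
  chemistry; a 5′-anchored mode exists for contrast. The Beta form is a
  modeling choice — real truncation lengths are not well characterized —
  and is fully exposed in configuration;
* **errors** — i.i.d. substitutions/insertions/deletions at configured
  rates (defaults 5%/2.5%/2.5%, ~10% total, the regime of native RNA
  basecalls); per-read constant base quality (the analyses use only the
  mean);
* **artifacts** — with probability ρ the reverse complement of a random
  prefix (30–80%) of the read is appended after the polyA tail,
  reproducing both the palindrome signal and the opposite-strand
  overlapping supplementary alignment of un-split double-stranded
  reads;
* **polyA tails** — Poisson lengths, mean 80 nt for protein-coding and
  30 nt for noncoding transcripts;
* **abundance and replicates** — log-normal transcript abundances
  (σ = 1) shared across replicates, reads sampled proportionally.

Alignments are *derived from truth*, not produced by a heuristic
aligner: CIGARs come from the planted edit script, genome records splice
`N` ops across the true transcript's introns, polyA and artifact bases
are soft-clipped, and transcriptome records are emitted for the true
transcript and every same-gene transcript containing the error-free
retained region, scored by matched bases with ties broken
lexicographically; artifact reads additionally emit an opposite-strand
overlapping supplementary genome record. This means downstream results
are checkable against exact oracles, and also that several phenomena of
real data are *not* represented: there are no unaligned or misaligned
reads (alignment rates are 1 by construction), no spurious novel
junctions from alignment errors, no homopolymer-specific or
quality-correlated error structure, no reference bias, and no
basecaller-specific artifacts. Passing tests therefore validate the
*analysis logic* under controlled truth, not aligner behavior on real
reads.

Determinism: a fixed seed yields byte-identical datasets and pipeline
outputs (no timestamps are written into any output file).

## Problem sizes

The test suite and the acceptance script run simulations of 30–450
genes and 2,000–10,000 reads with transcripts of a few hundred bases to
a few kilobases — sizes chosen so the statistical checks (KS < 0.05 at
n = 10⁴, rate recovery within ±10% relative, χ² goodness of fit at
n = 2 × 10⁴, artifact-rate recovery within ±0.02 at n = 5,000) have
comfortable power while the whole suite completes in well under a
minute of simulation time.

## Known limitations

* The compatibility-class construction is score-ratio-based; it will
  not reproduce the equivalence classes of any specific quantifier's
  index exactly.
* The gene counter's exon-union overlap ignores strand (as long-read
  gene counting commonly does in unstranded mode).
* Junction support from single-pass streaming assumes one primary
  record per read; chimeric multi-primary inputs are rejected rather
  than reconciled.
* The palindrome definition is global over the read; it does not model
  hairpin arm/loop geometry.
* FASTQ/SAM parsing trusts the container libraries (Biopython, pysam);
  malformed records surface as their exceptions with read context where
  possible.
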