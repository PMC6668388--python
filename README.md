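# lrtc — long-read transcriptome characterization

`lrtc` is a toolkit for characterizing long-read RNA-seq data (Oxford
Nanopore native RNA and direct cDNA reads) from the perspective of
transcript identification and quantification. It answers the questions a
transcriptomics analyst asks of a new long-read library:

* How well do the reads align, base by base?
* Do individual reads represent full-length transcript molecules, or are
  they truncated — and how does that depend on transcript length?
* How ambiguous is the assignment of a read to its isoform of origin,
  given the redundancy (nested and duplicated transcripts) of the
  annotation catalog?
* Are the splice junctions seen in the reads annotated and canonical?
* How deep must one sequence before transcript and gene detection
  saturates?
* Which reads look like un-split double-stranded artifacts (a sequence
  and its perfect reverse complement in one read)?

The package operates on standard inputs — SAM/BAM alignments to a genome
and to a transcriptome, FASTQ reads, a GTF annotation with a
transcriptome FASTA, optionally a TPM abundance table — and ships a
truth-driven synthetic data generator so every stage can be validated at
desk scale against exact oracles.

## The quantities at the core

For a read with primary alignment CIGAR op counts `nM`, `nI`, `nD` and
aligner edit distance `NM`:

* **aligned fraction** = (nM + nI) / read length
* **base-level accuracy** = (nM + nI + nD − NM) / (nM + nI + nD)
* **transcript coverage fraction** = (nM + nD) / annotated transcript
  length, with the target chosen to maximize coverage among all
  alignments whose aligned-nucleotide count is ≥ 90% of the per-read
  maximum (an upper bound on coverage of the true transcript of origin)
* **junction distance** between an observed and an annotated intron =
  |Δstart| + |Δend|; a junction is *annotated* at distance 0 and
  *canonical* when the intron motif is GT…AG on its strand
* **compatibility class** of a read at score ratio `p` = the set of
  transcripts whose alignment score is ≥ `p` × the read's best score
  (the aligner's `-p` semantics; `p = 0.99` is the stringent setting)
* **structural category** of a junction chain vs a reference catalog:
  full splice match (identical chain), incomplete splice match
  (consecutive sub-chain, as produced by truncation), novel in catalog,
  novel not in catalog, mono-exonic, intergenic
* **longest reverse-complement repeat** of a read = the longest
  substring whose perfect reverse complement also occurs in the read
  (reported when ≥ 10 nt) — the signature of un-split strand artifacts.

## Worked example

Simulate a small annotated transcriptome and run every stage:

```bash
cat > demo.yaml <<'YAML'
outdir: demo_out
seed: 7
simulate:
  n_genes: 12
  n_reads: 500
  max_isoforms: 3
  nested_isoform_rate: 0.3
  palindrome_artifact_rate: 0.1
YAML
lrtc all --config demo.yaml --verbose
```

`demo_out/summary.tsv` then contains (excerpt):

```
mean_aligned_fraction             0.8611541967427911
mean_base_accuracy                0.9035240794858981
mean_coverage_fraction            0.8371143610686358
annotated_junction_fraction       1.0
singleton_class_fraction          0.866
nested_pair_fraction              0.23076923076923078
self_assignment_singleton_fraction 0.9130434782608695
n_detected_transcripts            21
structural_full_splice_match      379
structural_incomplete_splice_match 84
```

Reading these: with the default ~10% planted base error the recovered
mean accuracy is 0.90; reads are on average 86% aligned (the rest is the
soft-clipped polyA tail and artifact append); the mean best-target
coverage of 0.84 reflects the 3′-anchored truncation model; every
junction observed in the reads is annotated (the truth aligner plants no
novel junctions); 87% of reads fall in single-transcript compatibility
classes at `p = 0.99`, while 23% of same-gene transcript pairs are
nested or identical — and even error-free full-length transcript proxies
are only 91% uniquely assignable, the annotation-redundancy ceiling.
Finally, every multi-exon read chain classifies as a full or incomplete
splice match, as expected for truncation-only reads.

Each stage is also available as its own subcommand (`lrtc simulate`,
`metrics`, `topology`, `coverage`, `junctions`, `ambiguity`, `count`,
`saturate`, `classify`) over explicit input paths; run
`lrtc <cmd> --help` for options.

## Library use

```python
from lrtc import io, topology, coverage
from lrtc.records import TargetSpace

records = list(io.read_alignments("transcriptome.bam", TargetSpace.TRANSCRIPTOME))
models = io.read_annotation("annotation.gtf", "transcripts.fa")
lengths = {m.transcript_id: m.length for m in models}
for aln_set in topology.group_alignments(records):
    call = coverage.select_best_target(aln_set, lengths, ratio=0.9)
    print(call.read_id, call.transcript_id, round(call.coverage_fraction, 3))
```

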