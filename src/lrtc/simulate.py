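"""Synthetic transcriptome, long-read and truth-alignment generator.

The generator emulates the statistical structure that the downstream
analyses probe on real ONT RNA-seq data:

* multi-isoform genes with shared junctions, exon-skipping variants,
  nested isoforms (exact 3' substrings of a sibling, mimicking annotated
  transcripts that are proper subsequences of others) and byte-identical
  duplicated isoforms;
* 3'-anchored read truncation — the polyA-proximal end of the molecule is
  retained and a Beta-distributed fraction of the 5' end is lost — plus
  i.i.d. substitution/insertion/deletion errors and appended polyA tails;
* palindromic "un-split strand" artifacts: the reverse complement of a
  prefix of the read appended to it, as when both strands of a cDNA
  duplex traverse the pore as one read;
* multi-replicate sampling from a fixed log-normal abundance model.

Alignments are derived from the simulation truth, not from a heuristic
aligner: CIGARs are reconstructed from the planted edit script, genome
records splice N ops across the true transcript's introns, and
transcriptome records are emitted for every same-gene transcript that
contains the (error-free) retained region, so downstream results can be
checked against an exact oracle.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import io as lio
from .records import (
    AlignmentCategory,
    AlignmentRecord,
    TargetSpace,
    TranscriptModel,
    revcomp,
)

_BASES = "ACGT"
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    Defaults are chosen to resemble a polyA-selected human-like catalog at
    desk scale: multi-exon genes a few hundred bases to a few kb long,
    ~10% total base error, a 3'-anchored truncation model and polyA tails
    with a modal length under 100 nt.
    """

    n_genes: int = 20
    min_isoforms: int = 1
    max_isoforms: int = 3
    min_exons: int = 2
    max_exons: int = 7
    exon_length_range: tuple[int, int] = (80, 400)
    intron_length_range: tuple[int, int] = (60, 800)
    nested_isoform_rate: float = 0.25
    duplicate_rate: float = 0.05
    canonical_motif_fraction: float = 0.95
    lncrna_fraction: float = 0.2
    genes_per_chromosome: int = 10
    abundance_sigma: float = 1.0
    n_reads: int = 1000
    n_replicates: int = 1
    full_length_prob: float = 0.5
    truncation_alpha: float = 2.0
    truncation_beta: float = 1.0
    truncation_anchor: str = "3p"  # "5p" available for contrast experiments
    substitution_rate: float = 0.05
    insertion_rate: float = 0.025
    deletion_rate: float = 0.025
    palindrome_artifact_rate: float = 0.0
    artifact_prefix_range: tuple[float, float] = (0.3, 0.8)
    polya_mean: float = 80.0
    polya_mean_noncoding: float = 30.0
    base_quality: int = 12
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "nested_isoform_rate", "duplicate_rate", "canonical_motif_fraction",
            "lncrna_fraction", "full_length_prob", "substitution_rate",
            "insertion_rate", "deletion_rate", "palindrome_artifact_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.truncation_alpha <= 0 or self.truncation_beta <= 0:
            raise ValueError("Beta truncation parameters must be positive")
        if self.truncation_anchor not in ("3p", "5p"):
            raise ValueError("truncation_anchor must be '3p' or '5p'")
        if self.n_genes < 1 or self.n_reads < 0 or self.n_replicates < 1:
            raise ValueError("invalid catalog/read counts")
        if self.intron_length_range[0] < 4:
            raise ValueError("introns must be at least 4 bases for motif planting")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("exon_length_range", "intron_length_range", "artifact_prefix_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        config = cls(**kwargs)
        config.validate()
        return config


@dataclass
class SyntheticTruth:
    """Per-read ground truth: origin, truncation, planted errors, artifacts."""

    read_id: str
    true_transcript_id: str
    molecule_length: int
    retained_start: int  # 0-based half-open interval on the transcript
    retained_end: int
    n_substitutions: int
    n_insertions: int
    n_deletions: int
    artifact: str  # "none" or "palindromic_append"
    artifact_read_length: int  # read bases in the appended segment
    polya_length: int
    replicate_id: int
    script: str = field(default="", repr=False)  # per-unit edit ops M/X/I/D


# ---------------------------------------------------------------------------
# transcriptome construction


def _distinct_chain(exons: list[int], rng: np.random.Generator, seen: set) -> list[int] | None:
    """Exon-skipping variant: drop a random non-empty subset of internal
    exons of the master chain (indices), keeping first and last.
    """
    internal = exons[1:-1]
    if not internal:
        return None
    for _ in range(10):
        keep = [i for i in internal if rng.random() < 0.6]
        if len(keep) == len(internal):
            continue
        chain = [exons[0], *keep, exons[-1]]
        if tuple(chain) not in seen:
            return chain
    return None


def build_transcriptome(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Generate a genome (per-chromosome sequences) and transcript models.

    Nested isoforms are 5'-exon-truncations of a sibling, so their spliced
    sequence is an exact proper substring (a 3' suffix) of the sibling's;
    duplicated isoforms share coordinates and sequence under a fresh id.
    Splice-site motifs (GT..AG on the annotated strand) are planted at a
    configurable fraction of master introns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genomes: dict[str, list[str]] = {}
    models: list[TranscriptModel] = []

    for g in range(config.n_genes):
        chrom = f"chr{g // config.genes_per_chromosome + 1}"
        genome = genomes.setdefault(chrom, [])
        gene_id = f"G{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if rng.random() < config.lncrna_fraction else "protein_coding"
        n_isoforms = int(rng.integers(config.min_isoforms, config.max_isoforms + 1))
        lo_e = config.min_exons
        if n_isoforms > 1:
            lo_e = max(lo_e, 3)  # room for distinct skipping variants
        n_exons = int(rng.integers(lo_e, max(config.max_exons, lo_e) + 1))

        exon_lens = rng.integers(*config.exon_length_range, size=n_exons, endpoint=True)
        intron_lens = rng.integers(
            *config.intron_length_range, size=max(0, n_exons - 1), endpoint=True
        )
        gene_start = len(genome) + 300
        exons: list[tuple[int, int]] = []
        pos = gene_start
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + int(elen)))
            pos += int(elen)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        gene_end = pos
        # extend genome with random sequence through the gene plus a gap
        need = gene_end + 300 - len(genome)
        genome.extend(rng.choice(list(_BASES), size=need))

        # plant splice motifs per master intron, on the annotated strand
        for i in range(n_exons - 1):
            istart, iend = exons[i][1], exons[i + 1][0]
            canonical = rng.random() < config.canonical_motif_fraction
            donor, acceptor = ("GT", "AG") if canonical else ("AA", "TT")
            if strand == "-":
                donor, acceptor = revcomp(acceptor), revcomp(donor)
            genome[istart], genome[istart + 1] = donor[0], donor[1]
            genome[iend - 2], genome[iend - 1] = acceptor[0], acceptor[1]

        # isoform structures as lists of master exon indices
        master = list(range(n_exons))
        chains: list[list[int]] = [master]
        seen = {tuple(master)}
        has_nested = n_isoforms > 1 and rng.random() < config.nested_isoform_rate
        has_duplicate = n_isoforms > 1 and rng.random() < config.duplicate_rate
        while len(chains) < n_isoforms:
            remaining = n_isoforms - len(chains)
            if has_nested:
                k = int(rng.integers(1, n_exons))
                # drop the first k exons in TRANSCRIPT order (5' truncation)
                chain = master[:-k] if strand == "-" else master[k:]
                chains.append(chain)
                seen.add(tuple(chain))
                has_nested = False
            elif has_duplicate and len(chains) >= 1 and remaining >= 1:
                chains.append(list(chains[int(rng.integers(0, len(chains)))]))
                has_duplicate = False
            else:
                chain = _distinct_chain(master, rng, seen)
                if chain is None:
                    chain = master[:-1] if strand == "-" else master[1:]  # fallback: nested
                chains.append(chain)
                seen.add(tuple(chain))

        for iso_idx, chain in enumerate(chains):
            tid = f"T{g + 1:04d}.{iso_idx + 1}"
            iso_exons = [exons[i] for i in chain]
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    exons=iso_exons,
                    sequence=None,
                    biotype=biotype,
                )
            )

    genome_seqs = {chrom: "".join(seq) for chrom, seq in genomes.items()}
    for model in models:
        parts = [genome_seqs[model.chromosome][s:e] for s, e in model.exons]
        seq = "".join(parts)
        model.sequence = seq if model.strand == "+" else revcomp(seq)
    return genome_seqs, models


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(
    seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float
) -> tuple[str, str]:
    """Apply i.i.d. errors to a sequence; returns (read, edit script).

    The script is one char per alignment unit in walk order: M match,
    X substitution, I insertion, D deletion.
    """
    out: list[str] = []
    script: list[str] = []
    for base in seq:
        if ins and rng.random() < ins:
            out.append(_BASES[int(rng.integers(4))])
            script.append("I")
        if dele and rng.random() < dele:
            script.append("D")
            continue
        if sub and rng.random() < sub:
            out.append(_OTHER[base][int(rng.integers(3))])
            script.append("X")
        else:
            out.append(base)
            script.append("M")
    if "M" not in script and "X" not in script:
        # degenerate all-deleted molecule: keep one aligned base
        out.append(seq[-1])
        script.append("M")
    return "".join(out), "".join(script)


def abundance_model(models: list[TranscriptModel], config: SimConfig) -> dict[str, float]:
    """Log-normal per-transcript abundances, normalized to TPM."""
    rng = np.random.default_rng(config.seed + 1)
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(models))
    total = weights.sum()
    return {
        m.transcript_id: 1e6 * w / total for m, w in zip(models, weights)
    }


def simulate_reads(
    models: list[TranscriptModel],
    config: SimConfig,
    tpm: Optional[dict[str, float]] = None,
) -> tuple[list[tuple[str, str, list[int]]], list[SyntheticTruth]]:
    """Simulate truncated, error-bearing long reads with polyA tails.

    Molecules are sampled proportionally to abundance; with probability
    ``full_length_prob`` the read spans the molecule, otherwise a
    Beta(alpha, beta) fraction anchored at the 3' end is retained. With
    probability ``palindrome_artifact_rate`` the reverse complement of a
    random-length prefix of the read is appended after the polyA tail.
    """
    config.validate()
    if tpm is None:
        tpm = abundance_model(models, config)
    rng = np.random.default_rng(config.seed + 2)
    weights = np.array([tpm[m.transcript_id] for m in models], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all abundances are zero")
    probs = weights / weights.sum()

    reads: list[tuple[str, str, list[int]]] = []
    truths: list[SyntheticTruth] = []
    for rep in range(config.n_replicates):
        for i in range(config.n_reads):
            read_id = f"read_{rep + 1}_{i + 1:06d}"
            model = models[int(rng.choice(len(models), p=probs))]
            length = model.length
            if rng.random() < config.full_length_prob:
                start, end = 0, length
            else:
                f = float(rng.beta(config.truncation_alpha, config.truncation_beta))
                retained = max(1, int(np.ceil(f * length)))
                if config.truncation_anchor == "3p":
                    start, end = length - retained, length
                else:
                    start, end = 0, retained
            molecule = model.sequence[start:end]
            core, script = _apply_errors(
                molecule, rng,
                config.substitution_rate, config.insertion_rate, config.deletion_rate,
            )
            mean = (
                config.polya_mean
                if model.biotype == "protein_coding"
                else config.polya_mean_noncoding
            )
            polya_len = int(rng.poisson(mean))
            artifact = "none"
            artifact_len = 0
            seq = core + "A" * polya_len
            if rng.random() < config.palindrome_artifact_rate:
                lo, hi = config.artifact_prefix_range
                k = max(10, int(np.ceil(float(rng.uniform(lo, hi)) * len(core))))
                k = min(k, len(core))
                seq = seq + revcomp(core[:k])
                artifact = "palindromic_append"
                artifact_len = k
            quals = [config.base_quality] * len(seq)
            reads.append((read_id, seq, quals))
            truths.append(
                SyntheticTruth(
                    read_id=read_id,
                    true_transcript_id=model.transcript_id,
                    molecule_length=length,
                    retained_start=start,
                    retained_end=end,
                    n_substitutions=script.count("X"),
                    n_insertions=script.count("I"),
                    n_deletions=script.count("D"),
                    artifact=artifact,
                    artifact_read_length=artifact_len,
                    polya_length=polya_len,
                    replicate_id=rep + 1,
                    script=script,
                )
            )
    return reads, truths


# ---------------------------------------------------------------------------
# truth-driven alignment


def _rle(units: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in units:
        if n == 0:
            continue
        if op in "X=":
            op = "M"
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _transcript_geometry(model: TranscriptModel) -> tuple[list[int], list[int]]:
    """Exon lengths and intervening genomic intron lengths in transcript
    (5'->3') order.
    """
    exon_lens = [e - s for s, e in model.exons]
    intron_lens = [model.exons[i + 1][0] - model.exons[i][1] for i in range(len(model.exons) - 1)]
    if model.strand == "-":
        exon_lens = exon_lens[::-1]
        intron_lens = intron_lens[::-1]
    return exon_lens, intron_lens


def _map_tpos(model: TranscriptModel, tpos: int) -> int:
    """Genomic coordinate of transcript position ``tpos``."""
    exon_lens, _ = _transcript_geometry(model)
    cum = 0
    for idx, elen in enumerate(exon_lens):
        if tpos < cum + elen:
            offset = tpos - cum
            if model.strand == "+":
                start, _ = model.exons[idx]
                return start + offset
            _, end = model.exons[len(model.exons) - 1 - idx]
            return end - 1 - offset
        cum += elen
    raise ValueError(f"position {tpos} beyond transcript {model.transcript_id}")


def _spliced_cigar(
    model: TranscriptModel, t_start: int, script: str
) -> list[tuple[str, int]]:
    """Transcript-order CIGAR units for an edit script starting at
    transcript position ``t_start``, with N ops inserted at exon
    boundaries.
    """
    exon_lens, intron_lens = _transcript_geometry(model)
    boundaries: dict[int, int] = {}
    cum = 0
    for elen, ilen in zip(exon_lens[:-1], intron_lens):
        cum += elen
        boundaries[cum] = ilen
    units: list[tuple[str, int]] = []
    tpos = t_start
    for op in script:
        if op in "MXD":  # reference-consuming
            if tpos in boundaries and tpos != t_start:
                units.append(("N", boundaries[tpos]))
            tpos += 1
        units.append((op, 1))
    return units


def _genome_record(
    model: TranscriptModel,
    read: tuple[str, str, list[int]],
    category: AlignmentCategory,
    script: str,
    t_start: int,
    clip_before: int,
    clip_after: int,
    flip_strand: bool,
) -> AlignmentRecord:
    """Genome-spliced record for a script slice on transcript coordinates
    [t_start, t_start + refspan). ``clip_before``/``clip_after`` are read
    bases soft-clipped before/after the aligned segment in READ order.
    """
    read_id, seq, quals = read
    units = _spliced_cigar(model, t_start, script)
    refspan = sum(n for op, n in units if op in "MXDN")
    strand = model.strand
    if flip_strand:
        strand = "-" if strand == "+" else "+"
    # reference order: transcript order for + strand models, reversed for -
    if model.strand == "+":
        ref_units = units
        lead, trail = clip_before, clip_after
        g_start = _map_tpos(model, t_start)
    else:
        ref_units = units[::-1]
        lead, trail = clip_after, clip_before
        t_last = t_start + sum(1 for op in script if op in "MXD") - 1
        g_start = _map_tpos(model, t_last)
    cigar = _rle(
        [("S", lead)] + ref_units + [("S", trail)]
    )
    sam_seq = seq if strand == "+" else revcomp(seq)
    sam_quals = quals if strand == "+" else quals[::-1]
    nm = script.count("X") + script.count("I") + script.count("D")
    assert g_start + refspan <= model.end
    return AlignmentRecord(
        read_id=read_id,
        target_id=model.chromosome,
        target_space=TargetSpace.GENOME,
        category=category,
        strand=strand,
        target_start=g_start,
        cigar=cigar,
        mapq=60 if category is AlignmentCategory.PRIMARY else 0,
        nm=nm,
        score=float(script.count("M")),
        sequence=sam_seq,
        qualities=list(sam_quals),
    )


def _script_prefix_for_read_bases(script: str, k: int) -> str:
    """Shortest script prefix consuming ``k`` read bases."""
    consumed = 0
    for i, op in enumerate(script):
        if op in "MXI":
            consumed += 1
            if consumed == k:
                return script[: i + 1]
    return script


def truth_alignments(
    reads: list[tuple[str, str, list[int]]],
    truths: list[SyntheticTruth],
    models: list[TranscriptModel],
) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Derive genome-spliced and transcriptome alignments from truth.

    Transcriptome records are emitted for the true transcript and every
    other same-gene transcript containing the error-free retained region;
    all containing targets share the matched-base score, the primary being
    the lexicographically smallest id. Palindromic-append artifacts yield
    a supplementary genome record on the opposite strand overlapping the
    primary.
    """
    by_id = {m.transcript_id: m for m in models}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    read_by_id = {r[0]: r for r in reads}

    genome_records: list[AlignmentRecord] = []
    txome_records: list[AlignmentRecord] = []
    for truth in truths:
        model = by_id.get(truth.true_transcript_id)
        if model is None or model.sequence is None:
            raise ValueError(f"truth references unknown transcript {truth.true_transcript_id}")
        read = read_by_id[truth.read_id]
        read_id, seq, quals = read
        script = truth.script
        core_len = sum(1 for op in script if op in "MXI")
        tail_len = len(seq) - core_len  # polyA plus any artifact append
        nm = truth.n_substitutions + truth.n_insertions + truth.n_deletions
        score = float(script.count("M"))

        # --- transcriptome space ---
        retained_seq = model.sequence[truth.retained_start : truth.retained_end]
        targets: list[tuple[str, int]] = [(model.transcript_id, truth.retained_start)]
        for sibling in by_gene[model.gene_id]:
            if sibling.transcript_id == model.transcript_id:
                continue
            offset = (sibling.sequence or "").find(retained_seq)
            if offset >= 0:
                targets.append((sibling.transcript_id, offset))
        targets.sort()
        primary_tid = targets[0][0]
        core_cigar = _rle([(op, 1) for op in script])
        for tid, offset in targets:
            category = (
                AlignmentCategory.PRIMARY if tid == primary_tid else AlignmentCategory.SECONDARY
            )
            txome_records.append(
                AlignmentRecord(
                    read_id=read_id,
                    target_id=tid,
                    target_space=TargetSpace.TRANSCRIPTOME,
                    category=category,
                    strand="+",
                    target_start=offset,
                    cigar=_rle(core_cigar + [("S", tail_len)]),
                    mapq=(60 if len(targets) == 1 else 0)
                    if category is AlignmentCategory.PRIMARY
                    else 0,
                    nm=nm,
                    score=score,
                    sequence=seq,
                    qualities=list(quals),
                )
            )

        # --- genome space ---
        genome_records.append(
            _genome_record(
                model, read, AlignmentCategory.PRIMARY,
                script, truth.retained_start,
                clip_before=0, clip_after=tail_len, flip_strand=False,
            )
        )
        if truth.artifact == "palindromic_append":
            sub_script = _script_prefix_for_read_bases(script, truth.artifact_read_length)
            seg_read_len = sum(1 for op in sub_script if op in "MXI")
            genome_records.append(
                _genome_record(
                    model, read, AlignmentCategory.SUPPLEMENTARY,
                    sub_script, truth.retained_start,
                    clip_before=len(seq) - seg_read_len, clip_after=0,
                    flip_strand=True,
                )
            )
    return genome_records, txome_records


# ---------------------------------------------------------------------------
# dataset emission


def write_dataset(config: SimConfig, outdir: str) -> dict[str, str]:
    """Run the full generator and write FASTQ, GTF, FASTA, SAM and truth
    TSV files; byte-identical under a fixed seed. Returns the file map.
    """
    lio.ensure_dir(outdir)
    genome, models = build_transcriptome(config)
    tpm = abundance_model(models, config)
    reads, truths = simulate_reads(models, config, tpm)
    genome_recs, txome_recs = truth_alignments(reads, truths, models)

    paths = {
        "genome_fasta": os.path.join(outdir, "genome.fa"),
        "transcript_fasta": os.path.join(outdir, "transcripts.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "genome_sam": os.path.join(outdir, "genome_alignments.sam"),
        "transcriptome_sam": os.path.join(outdir, "transcriptome_alignments.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "abundance": os.path.join(outdir, "abundance.tsv"),
    }
    lio.write_fasta(genome, paths["genome_fasta"])
    lio.write_fasta(
        {m.transcript_id: m.sequence for m in models}, paths["transcript_fasta"]
    )
    lio.write_gtf(models, paths["gtf"])
    for rep in range(1, config.n_replicates + 1):
        rep_reads = [r for r, t in zip(reads, truths) if t.replicate_id == rep]
        path = os.path.join(outdir, f"reads_rep{rep}.fastq")
        lio.write_fastq(rep_reads, path)
        paths[f"fastq_rep{rep}"] = path
    lio.write_alignments(
        genome_recs, paths["genome_sam"], {c: len(s) for c, s in genome.items()}
    )
    lio.write_alignments(
        txome_recs, paths["transcriptome_sam"],
        {m.transcript_id: m.length for m in models},
    )
    with open(paths["truth"], "w") as out:
        cols = [f.name for f in dataclasses.fields(SyntheticTruth) if f.name != "script"]
        out.write("\t".join(cols) + "\n")
        for t in truths:
            out.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")
    lio.write_abundance_table(tpm, paths["abundance"])
    return paths
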