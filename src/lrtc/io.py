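"""Readers and writers for the standard formats the pipeline touches.

SAM/BAM goes through pysam; FASTA through pyfaidx/Biopython. Coordinates
are converted to 0-based half-open on the way in and back to the 1-based
conventions of SAM/GTF on the way out.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

from .records import (
    AlignmentCategory,
    AlignmentRecord,
    Junction,
    TargetSpace,
    TranscriptModel,
)

_OP_CODES = "MIDNSHP=X"


def _decode_category(flag: int) -> AlignmentCategory:
    if flag & 0x4:
        return AlignmentCategory.UNMAPPED
    if flag & 0x100:
        return AlignmentCategory.SECONDARY
    if flag & 0x800:
        return AlignmentCategory.SUPPLEMENTARY
    return AlignmentCategory.PRIMARY


def read_alignments(path: str, target_space: TargetSpace | str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    Missing NM/AS tags are represented as None, never 0. ``=``/``X`` CIGAR
    ops are folded into M.
    """
    target_space = TargetSpace(target_space)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            category = _decode_category(aln.flag)
            if category is AlignmentCategory.UNMAPPED:
                cigar: list[tuple[str, int]] = []
                target_id = "*"
                start = 0
            else:
                if aln.cigartuples is None:
                    raise ValueError(f"mapped record without CIGAR: {aln.query_name}")
                cigar = []
                for code, length in aln.cigartuples:
                    op = _OP_CODES[code]
                    if op in "=X":
                        op = "M"
                    if cigar and cigar[-1][0] == op:
                        cigar[-1] = (op, cigar[-1][1] + length)
                    else:
                        cigar.append((op, length))
                target_id = aln.reference_name
                start = aln.reference_start
                seq = aln.query_sequence
                if seq is not None:
                    read_ops = sum(n for op, n in cigar if op in "MIS")
                    if read_ops != len(seq):
                        raise ValueError(
                            f"CIGAR/sequence length mismatch for {aln.query_name}: "
                            f"{read_ops} vs {len(seq)}"
                        )
            yield AlignmentRecord(
                read_id=aln.query_name,
                target_id=target_id,
                target_space=target_space,
                category=category,
                strand="-" if aln.flag & 0x10 else "+",
                target_start=start,
                cigar=cigar,
                mapq=aln.mapping_quality,
                nm=aln.get_tag("NM") if aln.has_tag("NM") else None,
                score=aln.get_tag("AS") if aln.has_tag("AS") else None,
                sequence=aln.query_sequence,
                qualities=list(aln.query_qualities) if aln.query_qualities is not None else None,
            )


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str,
    reference_lengths: dict[str, int],
) -> None:
    """Write AlignmentRecords as SAM (text) with a minimal header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    tid = {name: i for i, name in enumerate(reference_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            flag = 0
            if rec.category is AlignmentCategory.UNMAPPED:
                flag |= 0x4
            elif rec.category is AlignmentCategory.SECONDARY:
                flag |= 0x100
            elif rec.category is AlignmentCategory.SUPPLEMENTARY:
                flag |= 0x800
            if rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            if rec.is_mapped:
                a.reference_id = tid[rec.target_id]
                a.reference_start = rec.target_start
                a.cigartuples = [(_OP_CODES.index(op), n) for op, n in rec.cigar]
            a.mapping_quality = rec.mapq
            if rec.sequence is not None:
                a.query_sequence = rec.sequence
                if rec.qualities is not None:
                    a.query_qualities = pysam.qualitystring_to_array(
                        "".join(chr(q + 33) for q in rec.qualities)
                    )
            tags = []
            if rec.nm is not None:
                tags.append(("NM", rec.nm))
            if rec.score is not None:
                tags.append(("AS", int(rec.score)))
            if tags:
                a.set_tags(tags)
            out.write(a)


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for chunk in field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(gtf_path: str, fasta_path: Optional[str] = None) -> list[TranscriptModel]:
    """Build TranscriptModels from an Ensembl-dialect GTF, optionally
    attaching spliced sequences from a transcriptome FASTA keyed by
    transcript id. Duplicate transcript sequences are retained.
    """
    exons: dict[str, dict] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for line_no, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{line_no}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_field)
            try:
                tid = attrs["transcript_id"]
                gid = attrs["gene_id"]
            except KeyError as exc:
                raise ValueError(f"{gtf_path}:{line_no}: missing {exc} attribute")
            entry = exons.setdefault(
                tid,
                {
                    "gene_id": gid,
                    "chromosome": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": attrs.get("transcript_biotype", "protein_coding"),
                },
            )
            entry["exons"].append((int(start) - 1, int(end)))  # GTF is 1-based inclusive
            if tid not in order:
                order.append(tid)

    sequences: dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(fasta_path, "fasta"):
            sequences[rec.id] = str(rec.seq).upper()

    models = []
    for tid in order:
        entry = exons[tid]
        seq = sequences.get(tid)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            chromosome=entry["chromosome"],
            strand=entry["strand"],
            exons=entry["exons"],
            sequence=None,
            biotype=entry["biotype"],
        )
        if seq is not None:
            if len(seq) != model.length:
                raise ValueError(
                    f"FASTA/GTF length disagreement for {tid}: "
                    f"{len(seq)} vs {model.length}"
                )
            model.sequence = seq
        models.append(model)
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str) -> None:
    """Write transcript models as Ensembl-dialect GTF exon features."""
    with open(path, "w") as out:
        for m in models:
            for i, (start, end) in enumerate(m.exons, 1):
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'exon_number "{i}"; transcript_biotype "{m.biotype}";'
                )
                out.write(
                    f"{m.chromosome}\tlrtc\texon\t{start + 1}\t{end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fastq(reads: Iterable[tuple[str, str, list[int]]], path: str) -> None:
    """Write (read_id, sequence, phred qualities) triples as FASTQ."""
    with open(path, "w") as out:
        for read_id, seq, quals in reads:
            qual_str = "".join(chr(q + 33) for q in quals)
            out.write(f"@{read_id}\n{seq}\n+\n{qual_str}\n")


def read_fastq(path: str) -> list[tuple[str, str, list[int]]]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        reads.append((rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])))
    return reads


def write_junction_bed(junctions: Iterable[Junction], path: str) -> None:
    """BED6: chrom, intron_start, intron_end, name, support, strand."""
    with open(path, "w") as out:
        for i, j in enumerate(junctions, 1):
            strand = j.strand if j.strand in "+-" else "."
            out.write(
                f"{j.chromosome}\t{j.intron_start}\t{j.intron_end}\tJ{i}\t{j.support}\t{strand}\n"
            )


def read_abundance_table(path: str) -> dict[str, float]:
    """TSV with header; columns transcript_id and TPM (any order)."""
    table: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_col = header.index("transcript_id")
            tpm_col = header.index("TPM")
        except ValueError:
            raise ValueError(f"{path}: expected columns transcript_id and TPM")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            tpm = float(fields[tpm_col])
            if tpm < 0:
                raise ValueError(f"{path}: negative TPM for {fields[id_col]}")
            table[fields[id_col]] = tpm
    return table


def write_abundance_table(table: dict[str, float], path: str) -> None:
    with open(path, "w") as out:
        out.write("transcript_id\tTPM\n")
        for tid, tpm in table.items():
            out.write(f"{tid}\t{tpm:.6g}\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
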