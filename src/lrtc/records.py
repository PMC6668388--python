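"""Shared domain types for long-read transcriptome characterization.

All coordinates are 0-based half-open internally; 1-based conventions of
SAM and GTF are converted at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

# CIGAR ops that consume read bases (soft clips included, hard clips not)
READ_OPS = frozenset("MIS=X")
# CIGAR ops that consume reference bases
REF_OPS = frozenset("MDN=X")
VALID_OPS = frozenset("MIDNSH=X")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentCategory(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    SUPPLEMENTARY = "supplementary"
    UNMAPPED = "unmapped"


class TargetSpace(str, enum.Enum):
    GENOME = "genome"
    TRANSCRIPTOME = "transcriptome"


@dataclass
class AlignmentRecord:
    """One SAM-style alignment.

    ``cigar`` is an ordered list of ``(op, length)`` tuples using the ops
    M, I, D, N, S, H (``=``/``X`` are folded into M on ingestion). ``nm``
    is the aligner-reported edit distance and ``score`` the AS-style
    alignment score; both are ``None`` when the tag is absent — never 0.
    """

    read_id: str
    target_id: str
    target_space: TargetSpace
    category: AlignmentCategory
    strand: str  # "+" or "-"
    target_start: int  # 0-based
    cigar: list[tuple[str, int]] = field(default_factory=list)
    mapq: int = 0
    nm: Optional[int] = None
    score: Optional[float] = None
    sequence: Optional[str] = None
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        for op, length in self.cigar:
            if op not in VALID_OPS:
                raise ValueError(f"invalid CIGAR op {op!r} in read {self.read_id}")
            if length < 1:
                raise ValueError(f"CIGAR length < 1 in read {self.read_id}")
        if self.category is AlignmentCategory.UNMAPPED and self.cigar:
            raise ValueError(f"unmapped record {self.read_id} has a CIGAR")

    @property
    def is_mapped(self) -> bool:
        return self.category is not AlignmentCategory.UNMAPPED

    def op_total(self, ops: str) -> int:
        return sum(n for op, n in self.cigar if op in ops)

    @property
    def read_length(self) -> int:
        """Full read length, recovered including hard-clipped bases."""
        return self.op_total("MIS=XH")

    @property
    def reference_span(self) -> int:
        """Reference bases consumed (M, D, N)."""
        return self.op_total("MDN=X")

    @property
    def reference_end(self) -> int:
        return self.target_start + self.reference_span

    @property
    def alignment_length(self) -> int:
        """Reference-space alignment length nM + nD (N excluded)."""
        return self.op_total("MD=X")


@dataclass
class TranscriptModel:
    """Annotated isoform: exon structure plus optional spliced sequence."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open genomic intervals
    sequence: Optional[str] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon in {self.transcript_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = end
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence/exon length mismatch for {self.transcript_id}: "
                f"{len(self.sequence)} vs {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Junction:
    """One intron interval on the genome."""

    chromosome: str
    intron_start: int
    intron_end: int
    strand: str = "?"  # "+", "-", or "?" for unknown
    support: int = 0
    motif: Optional[str] = None  # donor + acceptor dinucleotides, e.g. "GTAG"

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError("junction with non-positive intron length")
        if self.support < 0:
            raise ValueError("negative junction support")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chromosome, self.intron_start, self.intron_end)
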