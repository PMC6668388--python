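"""Per-alignment and per-dataset quality metrics.

The two headline per-read quantities are the aligned fraction, the number
of M and I CIGAR characters divided by the full read length, and the
base-level accuracy (nM + nI + nD - NM) / (nM + nI + nD) computed from the
aligner-reported edit distance NM. Both are defined on primary alignments;
hard-clipped bases count toward the read-length denominator so fractions
remain comparable across split alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import AlignmentCategory, AlignmentRecord, TargetSpace


@dataclass(frozen=True)
class CigarSummary:
    nM: int = 0
    nI: int = 0
    nD: int = 0
    nN: int = 0
    nS: int = 0
    nH: int = 0

    @property
    def read_length(self) -> int:
        """Full read length including hard-clipped bases."""
        return self.nM + self.nI + self.nS + self.nH


@dataclass(frozen=True)
class QualityMetrics:
    aligned_fraction: float
    base_accuracy: Optional[float]
    clipped_fraction: float


def summarize_cigar(record: AlignmentRecord) -> CigarSummary:
    """Total CIGAR length per op class; = and X count as M."""
    if not record.is_mapped or not record.cigar:
        raise ValueError(f"cannot summarize CIGAR of unmapped record {record.read_id}")
    totals = {"M": 0, "I": 0, "D": 0, "N": 0, "S": 0, "H": 0}
    for op, n in record.cigar:
        if op in "=X":
            op = "M"
        totals[op] += n
    return CigarSummary(
        nM=totals["M"], nI=totals["I"], nD=totals["D"],
        nN=totals["N"], nS=totals["S"], nH=totals["H"],
    )


def alignment_quality(
    summary: CigarSummary, read_length: int, nm: Optional[int]
) -> QualityMetrics:
    """Aligned fraction, base accuracy and clipped fraction of one record.

    base_accuracy is None when the edit distance is absent — never
    silently 0.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if read_length < summary.nM + summary.nI:
        raise ValueError("read_length smaller than aligned base count")
    aligned_fraction = (summary.nM + summary.nI) / read_length
    denom = summary.nM + summary.nI + summary.nD
    accuracy = None if nm is None else (denom - nm) / denom
    clipped_fraction = (summary.nS + summary.nH) / read_length
    return QualityMetrics(aligned_fraction, accuracy, clipped_fraction)


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = sum(1 for b in seq if b in "GCgc")
    return gc / len(seq)


def read_stats(
    reads: Iterable[tuple[str, str, list[int]]],
    alignments: Iterable[AlignmentRecord],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-read table (length, mean quality, GC, primary-alignment flags)
    plus dataset-level alignment rates per target space.
    """
    per_read: dict[str, dict] = {}
    for read_id, seq, quals in reads:
        per_read[read_id] = {
            "read_id": read_id,
            "length": len(seq),
            "mean_quality": sum(quals) / len(quals) if quals else float("nan"),
            "gc_fraction": _gc_fraction(seq),
            "has_primary_genome": False,
            "has_primary_transcriptome": False,
        }
    for rec in alignments:
        if rec.category is not AlignmentCategory.PRIMARY:
            continue
        if rec.read_id not in per_read:
            raise ValueError(f"alignment references unknown read {rec.read_id}")
        key = (
            "has_primary_genome"
            if rec.target_space is TargetSpace.GENOME
            else "has_primary_transcriptome"
        )
        per_read[rec.read_id][key] = True
    table = pd.DataFrame(per_read.values())
    n = len(table)
    summary = {
        "n_reads": float(n),
        "genome_alignment_rate": table["has_primary_genome"].mean() if n else 0.0,
        "transcriptome_alignment_rate": (
            table["has_primary_transcriptome"].mean() if n else 0.0
        ),
    }
    return table, summary


def strip_clipped(
    read: tuple[str, str, list[int]], primary: AlignmentRecord
) -> tuple[str, str, list[int]]:
    """Remove the soft-clipped prefix/suffix of a read according to its
    primary alignment; the retained length equals nM + nI.
    """
    if primary.category is not AlignmentCategory.PRIMARY:
        raise ValueError("strip_clipped requires the primary alignment")
    read_id, seq, quals = read
    left = primary.cigar[0][1] if primary.cigar and primary.cigar[0][0] == "S" else 0
    right = primary.cigar[-1][1] if primary.cigar and primary.cigar[-1][0] == "S" else 0
    end = len(seq) - right
    return read_id, seq[left:end], quals[left:end]
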