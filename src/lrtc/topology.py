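"""Secondary/supplementary alignment structure and palindrome detection.

Supplementary alignments are split-read continuations; on ONT cDNA data a
supplementary that overlaps its primary on the opposite strand is the
signature of an un-split double-stranded read (both strands of the cDNA
duplex read as one molecule). The palindrome scan finds the longest
substring of a read whose perfect reverse complement also occurs in the
read, reported only when at least ``min_len`` bases long.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .records import AlignmentCategory, AlignmentRecord, revcomp


@dataclass
class ReadAlignmentSet:
    """All mapped records of one read in one target space."""

    read_id: str
    primary: AlignmentRecord
    secondaries: list[AlignmentRecord] = field(default_factory=list)
    supplementaries: list[AlignmentRecord] = field(default_factory=list)

    def all_records(self) -> list[AlignmentRecord]:
        return [self.primary, *self.secondaries, *self.supplementaries]


class SupplementaryCategory(str, enum.Enum):
    SAME_CHR_SAME_STRAND_OVERLAP = "same_chr_same_strand_overlap"
    SAME_CHR_SAME_STRAND_NONOVERLAP = "same_chr_same_strand_nonoverlap"
    SAME_CHR_DIFF_STRAND_OVERLAP = "same_chr_diff_strand_overlap"
    SAME_CHR_DIFF_STRAND_NONOVERLAP = "same_chr_diff_strand_nonoverlap"
    DIFF_CHR = "diff_chr"


@dataclass(frozen=True)
class SupplementaryCall:
    category: SupplementaryCategory
    overlap_ratio: float


class SecondaryAmbiguity(str, enum.Enum):
    NO_SECONDARY = "no_secondary"
    SAME_GENE_ONLY = "same_gene_only"
    MULTI_GENE = "multi_gene"


def group_alignments(records: Iterable[AlignmentRecord]) -> list[ReadAlignmentSet]:
    """Partition mapped records into per-read sets; unmapped records are
    dropped. Exactly one primary per read is required.
    """
    by_read: dict[str, dict[str, list[AlignmentRecord]]] = defaultdict(
        lambda: {"primary": [], "secondary": [], "supplementary": []}
    )
    order: list[str] = []
    for rec in records:
        if not rec.is_mapped:
            continue
        if rec.read_id not in by_read:
            order.append(rec.read_id)
        by_read[rec.read_id][rec.category.value].append(rec)
    sets = []
    for read_id in order:
        groups = by_read[read_id]
        if len(groups["primary"]) != 1:
            raise ValueError(
                f"read {read_id} has {len(groups['primary'])} primary alignments"
            )
        sets.append(
            ReadAlignmentSet(
                read_id=read_id,
                primary=groups["primary"][0],
                secondaries=groups["secondary"],
                supplementaries=groups["supplementary"],
            )
        )
    return sets


def classify_secondary_ambiguity(
    aln_set: ReadAlignmentSet, transcript_to_gene: Mapping[str, str]
) -> SecondaryAmbiguity:
    """Whether all primary+secondary targets are isoforms of one gene."""
    if not aln_set.secondaries:
        return SecondaryAmbiguity.NO_SECONDARY
    genes = set()
    for rec in [aln_set.primary, *aln_set.secondaries]:
        if rec.target_id not in transcript_to_gene:
            raise ValueError(f"unknown transcript {rec.target_id}")
        genes.add(transcript_to_gene[rec.target_id])
    return (
        SecondaryAmbiguity.SAME_GENE_ONLY
        if len(genes) == 1
        else SecondaryAmbiguity.MULTI_GENE
    )


def classify_supplementary(
    primary: AlignmentRecord, supplementary: AlignmentRecord
) -> SupplementaryCall:
    """Categorize a supplementary alignment relative to its primary by
    chromosome, strand and reference-position overlap.

    Overlap is determined on the full reference footprint of each
    alignment (M, D and N ops), the way spliced alignment positions are
    compared; the ratio divides the overlap by the primary alignment
    length nM + nD, so it can exceed 1 for intron-rich primaries.
    """
    if supplementary.target_id != primary.target_id:
        return SupplementaryCall(SupplementaryCategory.DIFF_CHR, 0.0)
    p_start, p_end = primary.target_start, primary.reference_end
    s_start, s_end = supplementary.target_start, supplementary.reference_end
    overlap = max(0, min(p_end, s_end) - max(p_start, s_start))
    ratio = overlap / primary.alignment_length if primary.alignment_length else 0.0
    same_strand = supplementary.strand == primary.strand
    if same_strand:
        cat = (
            SupplementaryCategory.SAME_CHR_SAME_STRAND_OVERLAP
            if overlap > 0
            else SupplementaryCategory.SAME_CHR_SAME_STRAND_NONOVERLAP
        )
    else:
        cat = (
            SupplementaryCategory.SAME_CHR_DIFF_STRAND_OVERLAP
            if overlap > 0
            else SupplementaryCategory.SAME_CHR_DIFF_STRAND_NONOVERLAP
        )
    return SupplementaryCall(cat, ratio)


class _SuffixAutomaton:
    """Suffix automaton over one string, used for longest-common-substring
    queries against another string.
    """

    def __init__(self, text: str) -> None:
        self.next: list[dict[str, int]] = [{}]
        self.link = [-1]
        self.length = [0]
        last = 0
        for ch in text:
            cur = len(self.next)
            self.next.append({})
            self.length.append(self.length[last] + 1)
            self.link.append(-1)
            p = last
            while p != -1 and ch not in self.next[p]:
                self.next[p][ch] = cur
                p = self.link[p]
            if p == -1:
                self.link[cur] = 0
            else:
                q = self.next[p][ch]
                if self.length[p] + 1 == self.length[q]:
                    self.link[cur] = q
                else:
                    clone = len(self.next)
                    self.next.append(dict(self.next[q]))
                    self.length.append(self.length[p] + 1)
                    self.link.append(self.link[q])
                    while p != -1 and self.next[p].get(ch) == q:
                        self.next[p][ch] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur

    def longest_common_substring(self, other: str) -> int:
        best = 0
        v, length = 0, 0
        for ch in other:
            while v and ch not in self.next[v]:
                v = self.link[v]
                length = self.length[v]
            if ch in self.next[v]:
                v = self.next[v][ch]
                length += 1
            else:
                v, length = 0, 0
            best = max(best, length)
        return best


def longest_revcomp_repeat(sequence: str, min_len: int = 10) -> int:
    """Length of the longest substring whose perfect reverse complement
    also occurs in the sequence; 0 when shorter than ``min_len``.

    Equivalent to the longest common substring of the sequence and its
    reverse complement. N bases never match, including against another N.
    """
    if not sequence:
        return 0
    sequence = sequence.upper()
    # make N in the reverse complement unmatchable, even against N
    rc = revcomp(sequence).replace("N", "#")
    best = _SuffixAutomaton(sequence).longest_common_substring(rc)
    return best if best >= min_len else 0


def palindrome_scan(
    reads: Iterable[tuple[str, str, list[int]]],
    min_len: int = 10,
    sample: int | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Longest reverse-complement repeat length per read, optionally on a
    seeded random subsample of reads.
    """
    reads = list(reads)
    if sample is not None and sample < len(reads):
        import numpy as np

        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=sample, replace=False)
        reads = [reads[i] for i in sorted(idx)]
    return {rid: longest_revcomp_repeat(seq, min_len) for rid, seq, _ in reads}
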