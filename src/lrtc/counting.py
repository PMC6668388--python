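"""Read-to-feature counting and detection/saturation analysis.

Two deliberately simple counters: a transcriptome counter assigning each
read to its primary target when the mapping quality passes a threshold
(default 5), and a gene-overlap counter assigning primary genome
alignments to the single gene whose exon union they overlap by at least
10 reference bases, discarding multi-gene overlaps as ambiguous. A
feature is considered detected when its count is >= 1; saturation curves
record detected transcripts and genes under nested random subsampling of
the read pool, either per replicate or after pooling replicates.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import AlignmentCategory, AlignmentRecord, TranscriptModel


class FeatureLevel(str, enum.Enum):
    TRANSCRIPT = "transcript"
    GENE = "gene"


@dataclass
class CountTable:
    level: FeatureLevel
    counts: dict[str, int]
    n_assigned: int
    n_ambiguous: int
    n_unassigned: int

    def detected(self, threshold: int = 1) -> set[str]:
        return {f for f, c in self.counts.items() if c >= threshold}


@dataclass(frozen=True)
class SaturationPoint:
    depth: int
    n_detected_transcripts: int
    n_detected_genes: int
    mode: str  # "single_replicate" or "pooled"
    replicate_id: Optional[int] = None


def count_transcripts_primary(
    records: Sequence[AlignmentRecord],
    transcript_to_gene: Optional[Mapping[str, str]] = None,
    min_mapq: int = 5,
) -> tuple[CountTable, Optional[CountTable]]:
    """Count each read once toward its primary target transcript if the
    mapping quality is >= ``min_mapq``; optionally aggregate to genes."""
    counts: Counter = Counter()
    n_assigned = n_unassigned = 0
    for rec in records:
        if rec.category is not AlignmentCategory.PRIMARY or not rec.is_mapped:
            continue
        if rec.mapq >= min_mapq:
            counts[rec.target_id] += 1
            n_assigned += 1
        else:
            n_unassigned += 1
    table = CountTable(FeatureLevel.TRANSCRIPT, dict(counts), n_assigned, 0, n_unassigned)
    gene_table = None
    if transcript_to_gene is not None:
        gene_counts: Counter = Counter()
        for tid, c in counts.items():
            gene_counts[transcript_to_gene[tid]] += c
        gene_table = CountTable(
            FeatureLevel.GENE, dict(gene_counts), n_assigned, 0, n_unassigned
        )
    return table, gene_table


def _reference_blocks(record: AlignmentRecord) -> list[tuple[int, int]]:
    """Reference intervals covered by M/D runs (N splits blocks)."""
    blocks = []
    pos = record.target_start
    start = pos
    open_block = False
    for op, n in record.cigar:
        if op in "MD=X":
            if not open_block:
                start = pos
                open_block = True
            pos += n
        elif op == "N":
            if open_block:
                blocks.append((start, pos))
                open_block = False
            pos += n
    if open_block:
        blocks.append((start, pos))
    return blocks


def _exon_union(models: Sequence[TranscriptModel]) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Merged exon intervals per (chromosome, gene)."""
    per_gene: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for m in models:
        per_gene[(m.chromosome, m.gene_id)].extend(m.exons)
    unions = {}
    for key, intervals in per_gene.items():
        intervals.sort()
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        unions[key] = [tuple(iv) for iv in merged]
    return unions


def _overlap_bases(blocks: list[tuple[int, int]], union: list[tuple[int, int]]) -> int:
    total = 0
    for bs, be in blocks:
        for us, ue in union:
            total += max(0, min(be, ue) - max(bs, us))
    return total


def count_genes_overlap(
    records: Sequence[AlignmentRecord],
    models: Sequence[TranscriptModel],
    min_overlap: int = 10,
    assign_max_overlap: bool = False,
) -> CountTable:
    """Assign primary genome alignments to genes by exon-union overlap.

    A read is assigned when its M/D reference blocks overlap exactly one
    gene's exon union by >= ``min_overlap`` bases; reads passing the
    threshold for two or more genes are discarded as ambiguous (or, with
    ``assign_max_overlap``, given to the gene with the largest overlap).
    """
    unions = _exon_union(models)
    by_chrom: dict[str, list[tuple[str, list[tuple[int, int]]]]] = defaultdict(list)
    for (chrom, gene), union in unions.items():
        by_chrom[chrom].append((gene, union))
    counts: Counter = Counter()
    n_assigned = n_ambiguous = n_unassigned = 0
    for rec in records:
        if rec.category is not AlignmentCategory.PRIMARY or not rec.is_mapped:
            continue
        blocks = _reference_blocks(rec)
        hits = []
        for gene, union in by_chrom.get(rec.target_id, []):
            ov = _overlap_bases(blocks, union)
            if ov >= min_overlap:
                hits.append((gene, ov))
        if len(hits) == 1:
            counts[hits[0][0]] += 1
            n_assigned += 1
        elif len(hits) > 1:
            if assign_max_overlap:
                hits.sort(key=lambda h: (-h[1], h[0]))
                counts[hits[0][0]] += 1
                n_assigned += 1
            else:
                n_ambiguous += 1
        else:
            n_unassigned += 1
    return CountTable(FeatureLevel.GENE, dict(counts), n_assigned, n_ambiguous, n_unassigned)


def detection_summary(
    table: CountTable,
    models: Sequence[TranscriptModel],
    bins: Sequence[int] = (1000, 2000, 5000),
    threshold: int = 1,
) -> tuple[set[str], pd.DataFrame]:
    """Detected feature set plus detection rate of the catalog stratified
    by transcript length (transcript-level tables only)."""
    from .coverage import length_stratum

    detected = table.detected(threshold)
    if table.level is FeatureLevel.GENE:
        return detected, pd.DataFrame()
    rows: dict[str, list[bool]] = defaultdict(list)
    for m in models:
        rows[length_stratum(m.length, bins)].append(m.transcript_id in detected)
    frame = pd.DataFrame(
        [
            {
                "stratum": stratum,
                "n_transcripts": len(flags),
                "n_detected": int(np.sum(flags)),
                "detection_rate": float(np.mean(flags)),
            }
            for stratum, flags in sorted(rows.items())
        ]
    )
    return detected, frame


def saturation_curve(
    replicate_records: Sequence[Sequence[AlignmentRecord]],
    depths: Sequence[int],
    transcript_to_gene: Mapping[str, str],
    seed: int = 0,
    mode: str = "pooled",
    min_mapq: int = 5,
    nested: bool = True,
) -> list[SaturationPoint]:
    """Detected transcripts/genes vs sampled depth.

    Reads are subsampled without replacement; nested subsamples (each
    depth's sample containing the previous) make every curve monotone
    non-decreasing by construction. In pooled mode replicates are merged
    before sampling; in single mode one curve is produced per replicate.
    """
    if mode not in ("pooled", "single_replicate", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    def one_curve(pool: Sequence[AlignmentRecord], label: str, rep: Optional[int]):
        by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
        for rec in pool:
            if rec.category is AlignmentCategory.PRIMARY and rec.is_mapped:
                by_read[rec.read_id].append(rec)
        read_ids = sorted(by_read)
        for depth in depths:
            if depth > len(read_ids):
                raise ValueError(f"depth {depth} exceeds pool size {len(read_ids)}")
        perm = rng.permutation(len(read_ids))
        points = []
        for depth in sorted(depths):
            if nested:
                chosen = perm[:depth]
            else:
                chosen = rng.choice(len(read_ids), size=depth, replace=False)
            records = [r for i in chosen for r in by_read[read_ids[i]]]
            table, gene_table = count_transcripts_primary(
                records, transcript_to_gene, min_mapq=min_mapq
            )
            points.append(
                SaturationPoint(
                    depth=depth,
                    n_detected_transcripts=len(table.detected()),
                    n_detected_genes=len(gene_table.detected()),
                    mode=label,
                    replicate_id=rep,
                )
            )
        return points

    if mode == "pooled":
        pool = [rec for rep in replicate_records for rec in rep]
        return one_curve(pool, "pooled", None)
    points = []
    for i, rep in enumerate(replicate_records, 1):
        points.extend(one_curve(rep, "single_replicate", i))
    return points
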