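"""Junction-chain comparison of query transcript models against a
reference catalog.

Categories, in precedence order: a query whose intron chain equals a
reference chain is a full splice match; a non-empty chain that is a
consecutive sub-chain of some reference chain (junctions lost only from
the ends, as truncation produces) is an incomplete splice match; a novel
combination of individually annotated junctions is novel-in-catalog; a
chain with any unannotated junction is novel-not-in-catalog. Single-exon
queries are mono-exon, unless they overlap no reference transcript at
all, in which case they are intergenic (as are spliced queries without
reference overlap that would otherwise be novel).

Transcript ends are ignored entirely: comparison is on junction chains
only.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import AlignmentRecord, TranscriptModel


def model_from_alignment(record: AlignmentRecord, query_id: str) -> TranscriptModel:
    """Read-derived transcript structure: exon blocks are the M/D runs of
    a spliced genome alignment, introns its N ops. Used to classify read
    chains against an annotation catalog."""
    exons = []
    pos = record.target_start
    start = pos
    open_block = False
    for op, n in record.cigar:
        if op in "MD=X":
            if not open_block:
                start, open_block = pos, True
            pos += n
        elif op == "N":
            if open_block:
                exons.append((start, pos))
                open_block = False
            pos += n
    if open_block:
        exons.append((start, pos))
    return TranscriptModel(
        transcript_id=query_id,
        gene_id=query_id,
        chromosome=record.target_id,
        strand=record.strand,
        exons=exons,
    )


@dataclass(frozen=True)
class JunctionChain:
    chromosome: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for i in range(1, len(self.introns)):
            if self.introns[i][0] < self.introns[i - 1][1]:
                raise ValueError("introns out of order or overlapping")


class StructuralCategory(str, enum.Enum):
    FULL_SPLICE_MATCH = "full_splice_match"
    INCOMPLETE_SPLICE_MATCH = "incomplete_splice_match"
    NOVEL_IN_CATALOG = "novel_in_catalog"
    NOVEL_NOT_IN_CATALOG = "novel_not_in_catalog"
    MONO_EXON = "mono_exon"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class StructuralCall:
    query_id: str
    category: StructuralCategory
    matched_reference_id: Optional[str] = None


def junction_chain(model: TranscriptModel) -> JunctionChain:
    """Intron chain of a transcript model; empty for single-exon models."""
    return JunctionChain(
        chromosome=model.chromosome,
        strand=model.strand,
        introns=tuple(model.introns()),
    )


def _is_consecutive_subchain(
    query: tuple[tuple[int, int], ...], reference: tuple[tuple[int, int], ...]
) -> bool:
    n, m = len(query), len(reference)
    if n == 0 or n > m:
        return False
    return any(reference[i : i + n] == query for i in range(m - n + 1))


_CATEGORY_RANK = {
    StructuralCategory.FULL_SPLICE_MATCH: 0,
    StructuralCategory.INCOMPLETE_SPLICE_MATCH: 1,
    StructuralCategory.NOVEL_IN_CATALOG: 2,
    StructuralCategory.NOVEL_NOT_IN_CATALOG: 3,
    StructuralCategory.MONO_EXON: 4,
    StructuralCategory.INTERGENIC: 5,
}


def _classify_one_strand(
    query: TranscriptModel,
    chain: tuple[tuple[int, int], ...],
    strand: str,
    ref_by_key: dict,
    junctions_by_chrom_strand: dict,
    spans_by_chrom: dict,
) -> StructuralCall:
    overlaps = any(
        query.start < e and s < query.end for s, e in spans_by_chrom.get(query.chromosome, [])
    )
    if not overlaps:
        return StructuralCall(query.transcript_id, StructuralCategory.INTERGENIC)
    if not chain:
        return StructuralCall(query.transcript_id, StructuralCategory.MONO_EXON)
    refs = ref_by_key.get((query.chromosome, strand), [])
    for ref_chain, ref_id in refs:
        if ref_chain == chain:
            return StructuralCall(
                query.transcript_id, StructuralCategory.FULL_SPLICE_MATCH, ref_id
            )
    for ref_chain, ref_id in refs:
        if _is_consecutive_subchain(chain, ref_chain):
            return StructuralCall(
                query.transcript_id, StructuralCategory.INCOMPLETE_SPLICE_MATCH, ref_id
            )
    annotated = junctions_by_chrom_strand.get((query.chromosome, strand), set())
    if all(j in annotated for j in chain):
        return StructuralCall(query.transcript_id, StructuralCategory.NOVEL_IN_CATALOG)
    return StructuralCall(query.transcript_id, StructuralCategory.NOVEL_NOT_IN_CATALOG)


def classify_structural(
    queries: Sequence[TranscriptModel], references: Sequence[TranscriptModel]
) -> list[StructuralCall]:
    """One StructuralCall per query transcript.

    Strand must match for chain comparison; unknown-strand queries are
    compared on both strands and the best (highest-precedence) category
    kept. Genomic overlap with any reference transcript, regardless of
    strand, rescues a query from the intergenic category.
    """
    ref_by_key: dict = defaultdict(list)
    junctions_by: dict = defaultdict(set)
    spans_by_chrom: dict = defaultdict(list)
    for ref in references:
        chain = junction_chain(ref)
        ref_by_key[(ref.chromosome, ref.strand)].append((chain.introns, ref.transcript_id))
        junctions_by[(ref.chromosome, ref.strand)].update(chain.introns)
        spans_by_chrom[ref.chromosome].append((ref.start, ref.end))
    calls = []
    for query in queries:
        chain = tuple(query.introns())
        strands = [query.strand] if query.strand in "+-" else ["+", "-"]
        candidates = [
            _classify_one_strand(query, chain, s, ref_by_key, junctions_by, spans_by_chrom)
            for s in strands
        ]
        calls.append(min(candidates, key=lambda c: _CATEGORY_RANK[c.category]))
    return calls


def overlap_sets(sets_by_dataset: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection sizes over identified-reference-id sets
    (UpSet semantics): each element counts once, toward the exact pattern
    of datasets containing it."""
    if not sets_by_dataset:
        raise ValueError("need at least one set")
    names = sorted(sets_by_dataset)
    universe = set().union(*sets_by_dataset.values())
    patterns: dict[tuple[str, ...], int] = defaultdict(int)
    for element in universe:
        pattern = tuple(n for n in names if element in sets_by_dataset[n])
        patterns[pattern] += 1
    return dict(sorted(patterns.items()))
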