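"""Compatibility-class ambiguity analysis and the nested-transcript census.

A read's compatibility class is the set of target transcripts whose
alignment score is at least ``p`` times the read's best score, mirroring
the aligner's -p score-ratio semantics for reporting secondary
alignments (default 0.8; the stringent setting used for transcriptome
work is 0.99). The class stands in for a quantifier's equivalence class:
the transcripts the read's alignments cannot distinguish.

The nested census enumerates, among pairs of same-gene transcripts, those
whose spliced sequence is byte-identical or a proper contiguous substring
of the sibling's — the annotation redundancy that makes unambiguous read
assignment impossible even for error-free full-length reads.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records import TranscriptModel
from .topology import ReadAlignmentSet


class NestedRelation(str, enum.Enum):
    PROPER_SUBSTRING = "proper_substring"
    IDENTICAL = "identical"


@dataclass(frozen=True)
class NestedPair:
    container_id: str
    contained_id: str
    relation: NestedRelation


@dataclass(frozen=True)
class CompatibilityClass:
    transcript_ids: frozenset[str]
    n_reads: int


def _record_score(record, fallback_matched_bases: bool):
    if record.score is not None:
        return float(record.score)
    if fallback_matched_bases:
        from .metrics import summarize_cigar

        s = summarize_cigar(record)
        return float(s.nM)
    raise ValueError(
        f"record {record.read_id}->{record.target_id} lacks an alignment score; "
        "re-run with fallback_matched_bases=True to score by matched bases"
    )


def compatibility_classes(
    aln_sets: Sequence[ReadAlignmentSet],
    p: float = 0.8,
    fallback_matched_bases: bool = False,
) -> tuple[list[CompatibilityClass], dict[str, int], dict]:
    """Per-read compatibility classes at score-ratio threshold ``p``.

    Returns the distinct classes with read counts, the per-read class
    size, and summary statistics of the class-size distribution.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    class_counts: Counter = Counter()
    sizes: dict[str, int] = {}
    for aln_set in aln_sets:
        records = [aln_set.primary, *aln_set.secondaries]
        scores = {}
        for rec in records:
            score = _record_score(rec, fallback_matched_bases)
            scores[rec.target_id] = max(score, scores.get(rec.target_id, -np.inf))
        best = max(scores.values())
        members = frozenset(t for t, s in scores.items() if s >= p * best)
        class_counts[members] += 1
        sizes[aln_set.read_id] = len(members)
    classes = [
        CompatibilityClass(ids, n) for ids, n in sorted(
            class_counts.items(), key=lambda kv: sorted(kv[0])
        )
    ]
    size_arr = np.array(list(sizes.values())) if sizes else np.array([0])
    summary = {
        "n_reads": len(sizes),
        "n_classes": len(classes),
        "mean_class_size": float(size_arr.mean()),
        "median_class_size": float(np.median(size_arr)),
        "size_distribution": dict(sorted(Counter(sizes.values()).items())),
        "singleton_fraction": float((size_arr == 1).mean()) if sizes else float("nan"),
    }
    return classes, sizes, summary


def find_nested_pairs(
    models: Sequence[TranscriptModel],
) -> tuple[list[NestedPair], dict]:
    """Identical and proper-substring relations among same-gene transcript
    pairs, with pair totals and the nested fraction."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        if m.sequence is None:
            raise ValueError(f"transcript {m.transcript_id} has no sequence")
        by_gene.setdefault(m.gene_id, []).append(m)
    pairs: list[NestedPair] = []
    n_pairs = 0
    n_identical = 0
    for gene_models in by_gene.values():
        for i in range(len(gene_models)):
            for j in range(i + 1, len(gene_models)):
                a, b = gene_models[i], gene_models[j]
                n_pairs += 1
                if a.sequence == b.sequence:
                    pairs.append(
                        NestedPair(a.transcript_id, b.transcript_id, NestedRelation.IDENTICAL)
                    )
                    n_identical += 1
                elif b.sequence in a.sequence:
                    pairs.append(
                        NestedPair(a.transcript_id, b.transcript_id, NestedRelation.PROPER_SUBSTRING)
                    )
                elif a.sequence in b.sequence:
                    pairs.append(
                        NestedPair(b.transcript_id, a.transcript_id, NestedRelation.PROPER_SUBSTRING)
                    )
    summary = {
        "n_same_gene_pairs": n_pairs,
        "n_nested_pairs": len(pairs),
        "n_identical_pairs": n_identical,
        "nested_fraction": len(pairs) / n_pairs if n_pairs else float("nan"),
    }
    return pairs, summary


def self_assignment_test(models: Sequence[TranscriptModel], p: float = 0.8) -> float:
    """Fraction of annotated transcripts that, used as proxies for
    error-free full-length reads, fall in single-transcript compatibility
    classes.

    Each proxy's alignment set consists of every catalog transcript
    containing it as an exact substring (scored by the proxy length) plus
    every transcript it properly contains (scored by the contained
    length); classes are formed at score-ratio threshold ``p``.
    """
    if not models:
        raise ValueError("empty catalog")
    for m in models:
        if m.sequence is None:
            raise ValueError(f"transcript {m.transcript_id} has no sequence")
    n_singleton = 0
    for proxy in models:
        scores: dict[str, float] = {}
        for other in models:
            if other.transcript_id == proxy.transcript_id:
                scores[other.transcript_id] = float(len(proxy.sequence))
            elif proxy.sequence in other.sequence:
                scores[other.transcript_id] = float(len(proxy.sequence))
            elif other.sequence in proxy.sequence:
                scores[other.transcript_id] = float(len(other.sequence))
        best = max(scores.values())
        members = {t for t, s in scores.items() if s >= p * best}
        if len(members) == 1:
            n_singleton += 1
    return n_singleton / len(models)
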