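"""Best-target transcript selection and coverage-fraction analysis.

A read's transcript coverage fraction is the number of M and D CIGAR
characters of the chosen transcriptome alignment divided by the annotated
transcript length. The best target is chosen among all primary and
secondary alignments whose aligned-nucleotide count is at least a fixed
ratio (default 90%) of the per-read maximum, taking the alignment with
the largest coverage fraction; because truncated reads of a long isoform
also fit its shorter siblings, the selected fraction is an upper bound on
coverage of the true transcript of origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import summarize_cigar
from .records import AlignmentRecord, TranscriptModel
from .topology import ReadAlignmentSet

DEFAULT_LENGTH_BINS = (1000, 2000, 5000)


@dataclass(frozen=True)
class CoverageCall:
    read_id: str
    transcript_id: str
    coverage_fraction: float
    aligned_nt: int
    length_stratum: str


def length_stratum(length: int, bins: Sequence[int] = DEFAULT_LENGTH_BINS) -> str:
    edges = sorted(bins)
    prev = 0
    for edge in edges:
        if length < edge:
            return f"[{prev},{edge})"
        prev = edge
    return f">={prev}"


def _aligned_nt(record: AlignmentRecord, include_insertions: bool = True) -> int:
    s = summarize_cigar(record)
    return s.nM + s.nI if include_insertions else s.nM


def _coverage(record: AlignmentRecord, lengths: Mapping[str, int]) -> float:
    s = summarize_cigar(record)
    return (s.nM + s.nD) / lengths[record.target_id]


def select_best_target(
    aln_set: ReadAlignmentSet,
    transcript_lengths: Mapping[str, int],
    ratio: float = 0.9,
    include_insertions: bool = True,
    bins: Sequence[int] = DEFAULT_LENGTH_BINS,
) -> Optional[CoverageCall]:
    """Keep alignments whose aligned-nt count is >= ratio x the per-read
    maximum, then choose the one with the largest coverage fraction.

    Ties go to the higher coverage, then the primary record, then the
    lexicographically smaller transcript id.
    """
    records = [r for r in [aln_set.primary, *aln_set.secondaries] if r.is_mapped]
    if not records:
        return None
    aligned = [_aligned_nt(r, include_insertions) for r in records]
    cutoff = ratio * max(aligned)
    survivors = [
        (r, a) for r, a in zip(records, aligned) if a >= cutoff
    ]
    def sort_key(item):
        rec, a = item
        return (
            -_coverage(rec, transcript_lengths),
            0 if rec is aln_set.primary else 1,
            rec.target_id,
        )
    best, best_aligned = min(survivors, key=sort_key)
    tlen = transcript_lengths[best.target_id]
    return CoverageCall(
        read_id=aln_set.read_id,
        transcript_id=best.target_id,
        coverage_fraction=_coverage(best, transcript_lengths),
        aligned_nt=best_aligned,
        length_stratum=length_stratum(tlen, bins),
    )


def max_covered_portion(
    aln_set: ReadAlignmentSet, transcript_lengths: Mapping[str, int]
) -> Optional[float]:
    """Maximum covered portion of any target transcript over all primary
    and secondary alignments (no aligned-nt filter).
    """
    records = [r for r in [aln_set.primary, *aln_set.secondaries] if r.is_mapped]
    if not records:
        return None
    return max(_coverage(r, transcript_lengths) for r in records)


def coverage_by_stratum(
    calls: Iterable[CoverageCall],
    models: Sequence[TranscriptModel],
    bins: Sequence[int] = DEFAULT_LENGTH_BINS,
) -> pd.DataFrame:
    """Per length stratum: n, coverage quartiles and the fraction of
    calls with coverage >= 0.9.
    """
    known = {m.transcript_id for m in models}
    rows: dict[str, list[float]] = {}
    for call in calls:
        if call.transcript_id not in known:
            raise ValueError(f"call references unknown transcript {call.transcript_id}")
        rows.setdefault(call.length_stratum, []).append(call.coverage_fraction)
    out = []
    for stratum in sorted(rows):
        vals = np.asarray(rows[stratum])
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            {
                "stratum": stratum,
                "n": len(vals),
                "q1": q1,
                "median": q2,
                "q3": q3,
                "frac_ge_0.9": float((vals >= 0.9).mean()),
            }
        )
    return pd.DataFrame(
        out, columns=["stratum", "n", "q1", "median", "q3", "frac_ge_0.9"]
    )


def expected_length_distribution(
    models: Sequence[TranscriptModel],
    tpm: Mapping[str, float],
    observed_lengths: Optional[Sequence[int]] = None,
) -> dict:
    """TPM-weighted annotated-length distribution, i.e. the expected
    distribution of transcript molecule lengths, with quantiles and a KS
    statistic against observed primary-aligned read lengths.
    """
    lengths = np.array([m.length for m in models], dtype=float)
    weights = np.array([tpm.get(m.transcript_id, 0.0) for m in models], dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative TPM")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all TPM values are zero")
    probs = weights / total
    order = np.argsort(lengths)
    sorted_lengths = lengths[order]
    cum = np.cumsum(probs[order])

    def cdf(x):
        idx = np.searchsorted(sorted_lengths, x, side="right")
        return np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)

    mean = float((lengths * probs).sum())
    quantiles = {
        q: float(sorted_lengths[np.searchsorted(cum, q, side="left")])
        for q in (0.25, 0.5, 0.75)
    }
    result = {"mean": mean, "quantiles": quantiles}
    if observed_lengths is not None and len(observed_lengths):
        obs = np.sort(np.asarray(observed_lengths, dtype=float))
        n = len(obs)
        # sup distance between two right-continuous step functions,
        # checked at and just before every jump point of either
        grid = np.union1d(obs, sorted_lengths)
        ecdf_right = np.searchsorted(obs, grid, side="right") / n
        ecdf_left = np.searchsorted(obs, grid, side="left") / n
        cdf_right = cdf(grid)
        idx_left = np.searchsorted(sorted_lengths, grid, side="left")
        cdf_left = np.where(idx_left > 0, cum[np.maximum(idx_left - 1, 0)], 0.0)
        result["ks_statistic"] = float(
            max(
                np.abs(ecdf_right - cdf_right).max(),
                np.abs(ecdf_left - cdf_left).max(),
            )
        )
    return result
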