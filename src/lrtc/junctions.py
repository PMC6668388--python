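"""Junction extraction from spliced genome alignments and matching to
annotation.

Each N CIGAR op in a spliced alignment implies an intron; the distance
between an observed and an annotated junction is the absolute difference
between their start positions plus the absolute difference between their
end positions, and the closest annotated junction is found under that
distance. A junction is canonical when the intron begins with the GT
donor dinucleotide and ends with the AG acceptor on its strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import AlignmentCategory, AlignmentRecord, Junction, TranscriptModel, revcomp


@dataclass(frozen=True)
class JunctionMatch:
    observed: Junction
    nearest_annotated: Optional[Junction]
    distance: Optional[int]
    annotated: bool
    canonical: bool


def junctions_from_record(record: AlignmentRecord) -> list[tuple[str, int, int]]:
    """Intron intervals implied by the N ops of one alignment."""
    introns = []
    pos = record.target_start
    for op, n in record.cigar:
        if op == "N":
            introns.append((record.target_id, pos, pos + n))
        if op in "MDN=X":
            pos += n
    return introns


def extract_junctions(
    records: Iterable[AlignmentRecord],
    primary_only: bool = True,
    strand_from_alignment: bool = False,
) -> list[Junction]:
    """Observed junction multiset with per-junction read support.

    Secondary/supplementary alignments are excluded by default to avoid
    double counting. When ``strand_from_alignment`` is set, the record's
    strand is attached to the junction; otherwise the strand is resolved
    later from the splice motif.
    """
    support: Counter = Counter()
    strands: dict[tuple[str, int, int], str] = {}
    for rec in records:
        if not rec.is_mapped:
            continue
        if primary_only and rec.category is not AlignmentCategory.PRIMARY:
            continue
        for key in junctions_from_record(rec):
            support[key] += 1
            if strand_from_alignment:
                prev = strands.get(key)
                strands[key] = rec.strand if prev in (None, rec.strand) else "?"
    return [
        Junction(
            chromosome=c, intron_start=s, intron_end=e,
            strand=strands.get((c, s, e), "?"), support=n,
        )
        for (c, s, e), n in sorted(support.items())
    ]


def annotated_junctions(models: Sequence[TranscriptModel]) -> list[Junction]:
    """Unique annotated junctions of a transcript catalog."""
    seen: dict[tuple[str, int, int], str] = {}
    for m in models:
        for start, end in m.introns():
            key = (m.chromosome, start, end)
            prev = seen.get(key)
            seen[key] = m.strand if prev in (None, m.strand) else "?"
    return [
        Junction(chromosome=c, intron_start=s, intron_end=e, strand=strand)
        for (c, s, e), strand in sorted(seen.items())
    ]


def junction_motif(junction: Junction, genome: Mapping[str, str]) -> Optional[str]:
    """Donor+acceptor 4-mer of the intron on the junction's strand (or on
    the plus strand when the strand is unknown)."""
    if junction.chromosome not in genome:
        raise ValueError(f"chromosome {junction.chromosome} absent from genome")
    seq = genome[junction.chromosome]
    if junction.intron_end - junction.intron_start < 4 or junction.intron_end > len(seq):
        return None
    donor = seq[junction.intron_start : junction.intron_start + 2]
    acceptor = seq[junction.intron_end - 2 : junction.intron_end]
    if junction.strand == "-":
        donor, acceptor = revcomp(acceptor), revcomp(donor)
    return donor + acceptor


def _is_canonical(junction: Junction, genome: Mapping[str, str]) -> tuple[bool, str, Optional[str]]:
    """Resolve canonicity and strand: alignment strand if present, else
    the motif-consistent strand, else unknown (not canonical)."""
    seq = genome[junction.chromosome]
    if junction.intron_end - junction.intron_start < 4:
        return False, junction.strand, None
    fwd = seq[junction.intron_start : junction.intron_start + 2] + \
        seq[junction.intron_end - 2 : junction.intron_end]
    if junction.strand == "+":
        return fwd == "GTAG", "+", fwd
    if junction.strand == "-":
        rev = revcomp(fwd[2:]) + revcomp(fwd[:2])
        return rev == "GTAG", "-", rev
    if fwd == "GTAG":
        return True, "+", fwd
    if fwd == "CTAC":  # GT..AG read on the minus strand
        return True, "-", "GTAG"
    return False, "?", fwd


def match_junctions(
    observed: Sequence[Junction],
    annotated: Sequence[Junction],
    genome: Mapping[str, str],
    strand_restricted: bool = False,
) -> list[JunctionMatch]:
    """Nearest annotated junction per observed junction under the
    start+end distance; ties broken by smaller intron start. Matching is
    per chromosome and strand-agnostic by default.
    """
    by_chrom: dict[str, list[Junction]] = {}
    for j in annotated:
        by_chrom.setdefault(j.chromosome, []).append(j)
    matches = []
    for obs in observed:
        if obs.chromosome not in genome:
            raise ValueError(f"chromosome {obs.chromosome} absent from genome")
        candidates = by_chrom.get(obs.chromosome, [])
        if strand_restricted and obs.strand in "+-":
            candidates = [a for a in candidates if a.strand in ("?", obs.strand)]
        nearest, best = None, None
        for ann in candidates:
            dist = abs(obs.intron_start - ann.intron_start) + abs(
                obs.intron_end - ann.intron_end
            )
            if best is None or dist < best or (
                dist == best and ann.intron_start < nearest.intron_start
            ):
                nearest, best = ann, dist
        canonical, strand, motif = _is_canonical(obs, genome)
        obs = Junction(
            obs.chromosome, obs.intron_start, obs.intron_end,
            strand=strand, support=obs.support, motif=motif,
        )
        matches.append(
            JunctionMatch(
                observed=obs,
                nearest_annotated=nearest,
                distance=best,
                annotated=best == 0,
                canonical=canonical,
            )
        )
    return matches


def junctions_per_read(records: Iterable[AlignmentRecord]) -> dict[str, int]:
    """Number of junctions (N ops) spanned by each read's primary genome
    alignment."""
    counts = {}
    for rec in records:
        if rec.is_mapped and rec.category is AlignmentCategory.PRIMARY:
            counts[rec.read_id] = sum(1 for op, _ in rec.cigar if op == "N")
    return counts


def junction_summary(
    matches: Sequence[JunctionMatch],
    per_read_junctions: Optional[Mapping[str, int]] = None,
    thresholds: Sequence[int] = (1, 5),
) -> dict:
    """Annotation-status tables at each support threshold plus novel
    distance histogram, canonical fractions and the per-read junction
    count distribution."""
    tables = {}
    for threshold in thresholds:
        kept = [m for m in matches if m.observed.support >= threshold]
        n_annotated = sum(m.annotated for m in kept)
        novel = [m for m in kept if not m.annotated]
        dist_hist = Counter(m.distance for m in novel)
        def _canon_frac(group):
            return sum(m.canonical for m in group) / len(group) if group else float("nan")
        tables[threshold] = {
            "n_junctions": len(kept),
            "n_annotated": n_annotated,
            "n_novel": len(novel),
            "annotated_fraction": n_annotated / len(kept) if kept else float("nan"),
            "canonical_fraction_annotated": _canon_frac([m for m in kept if m.annotated]),
            "canonical_fraction_novel": _canon_frac(novel),
            "novel_distance_histogram": dict(sorted(dist_hist.items())),
        }
    result = {"by_threshold": tables}
    if per_read_junctions is not None:
        result["junctions_per_read"] = dict(Counter(per_read_junctions.values()))
    return result


def summary_frame(summary: dict) -> pd.DataFrame:
    rows = []
    for threshold, t in summary["by_threshold"].items():
        rows.append({"min_support": threshold, **{
            k: v for k, v in t.items() if k != "novel_distance_histogram"
        }})
    return pd.DataFrame(rows)
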