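"""Shared fixtures: tiny hand-built records and module-scoped synthetic
datasets, all generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lrtc.records import AlignmentCategory, AlignmentRecord, TargetSpace, TranscriptModel
from lrtc.simulate import SimConfig, build_transcriptome, simulate_reads, truth_alignments


def make_record(
    cigar,
    read_id="r1",
    target_id="chr1",
    category=AlignmentCategory.PRIMARY,
    target_space=TargetSpace.GENOME,
    strand="+",
    target_start=0,
    **kwargs,
):
    return AlignmentRecord(
        read_id=read_id,
        target_id=target_id,
        target_space=target_space,
        category=category,
        strand=strand,
        target_start=target_start,
        cigar=cigar,
        **kwargs,
    )


def random_cigar(rng: np.random.Generator) -> list[tuple[str, int]]:
    """A structurally valid mapped-read CIGAR: optional clips around an
    alignment that starts and ends with M and never repeats an op."""
    ops = []
    if rng.random() < 0.4:
        ops.append(("H" if rng.random() < 0.2 else "S", int(rng.integers(1, 50))))
    n_core = int(rng.integers(1, 8))
    prev = None
    for i in range(n_core):
        if i == 0 or i == n_core - 1:
            op = "M"
        else:
            op = str(rng.choice([o for o in "MIDN" if o != prev]))
        if op == prev:
            continue
        length = int(rng.integers(1, 200 if op != "N" else 2000))
        ops.append((op, length))
        prev = op
    if rng.random() < 0.4:
        ops.append(("S" if rng.random() < 0.8 else "H", int(rng.integers(1, 50))))
    merged = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def cigar_walk_oracle(cigar):
    """Independent per-base CIGAR walk: returns dict of op totals and the
    per-base classification used to cross-check the vectorised metrics."""
    totals = {op: 0 for op in "MIDNSH"}
    for op, n in cigar:
        key = "M" if op in "=X" else op
        for _ in range(n):
            totals[key] += 1
    return totals


def lcs_revcomp_oracle(seq: str) -> int:
    """O(n^2) dynamic-programming longest common substring of seq and its
    reverse complement; N never matches anything."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(seq))
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    n_code = ord("N")
    best = 0
    prev = np.zeros(len(b), dtype=np.int32)
    for i in range(len(a)):
        match = (b == a[i]) & (a[i] != n_code) & (b != n_code)
        cur = np.zeros(len(b), dtype=np.int32)
        cur[0] = 1 if match[0] else 0
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        best = max(best, int(cur.max(initial=0)))
        prev = cur
    return best


@pytest.fixture(scope="session")
def toy_models():
    """Two genes: G1 with a master, a nested (5'-truncated) and a
    duplicate isoform; G2 single-isoform; all on the plus strand with
    hand-computable coordinates."""
    rng = np.random.default_rng(11)
    chrom_seq = "".join(rng.choice(list("ACGT"), size=3000))
    # G1 master: exons [100,200), [300,400), [500,600)
    t1 = TranscriptModel("T1.1", "G1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
    t1.sequence = chrom_seq[100:200] + chrom_seq[300:400] + chrom_seq[500:600]
    # nested: exons 2-3 only -> sequence is a 3' suffix of T1.1
    t2 = TranscriptModel("T1.2", "G1", "chr1", "+", [(300, 400), (500, 600)])
    t2.sequence = t1.sequence[100:]
    # duplicate of the master
    t3 = TranscriptModel("T1.3", "G1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
    t3.sequence = t1.sequence
    t4 = TranscriptModel("T2.1", "G2", "chr1", "+", [(1000, 1150), (1400, 1500)])
    t4.sequence = chrom_seq[1000:1150] + chrom_seq[1400:1500]
    return {"genome": {"chr1": chrom_seq}, "models": [t1, t2, t3, t4]}


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free dataset with truncation, nesting and artifacts."""
    cfg = SimConfig(
        n_genes=10,
        n_reads=400,
        max_isoforms=3,
        nested_isoform_rate=0.4,
        duplicate_rate=0.2,
        substitution_rate=0.0,
        insertion_rate=0.0,
        deletion_rate=0.0,
        palindrome_artifact_rate=0.15,
        full_length_prob=0.5,
        seed=101,
    )
    genome, models = build_transcriptome(cfg)
    reads, truths = simulate_reads(models, cfg)
    genome_recs, txome_recs = truth_alignments(reads, truths, models)
    return {
        "config": cfg,
        "genome": genome,
        "models": models,
        "reads": reads,
        "truths": truths,
        "genome_recs": genome_recs,
        "txome_recs": txome_recs,
    }


@pytest.fixture(scope="session")
def noisy_dataset():
    """Dataset with the default ~10% base error and artifacts."""
    cfg = SimConfig(
        n_genes=8,
        n_reads=300,
        max_isoforms=2,
        palindrome_artifact_rate=0.1,
        seed=202,
    )
    genome, models = build_transcriptome(cfg)
    reads, truths = simulate_reads(models, cfg)
    genome_recs, txome_recs = truth_alignments(reads, truths, models)
    return {
        "config": cfg,
        "genome": genome,
        "models": models,
        "reads": reads,
        "truths": truths,
        "genome_recs": genome_recs,
        "txome_recs": txome_recs,
    }
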