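"""Config-driven end-to-end runs and the consolidated report.

Every stage writes plain tab-separated tables into the output directory;
a key/value ``summary.tsv`` collects the headline quantities. Outputs are
byte-identical under a fixed seed and config (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import ambiguity as amb
from . import counting as cnt
from . import coverage as cov
from . import io as lio
from . import junctions as jx
from . import metrics as mx
from . import structure as st
from . import topology as tp
from .records import AlignmentCategory, TargetSpace, TranscriptModel
from .simulate import SimConfig, write_dataset

ALL_STAGES = (
    "metrics", "topology", "coverage", "junctions",
    "ambiguity", "count", "saturate", "classify",
)


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    # inputs (all optional when `simulate` is given)
    fastq: list[str] = field(default_factory=list)
    genome_sam: Optional[str] = None
    transcriptome_sam: Optional[str] = None
    gtf: Optional[str] = None
    genome_fasta: Optional[str] = None
    transcript_fasta: Optional[str] = None
    tpm: Optional[str] = None
    simulate: Optional[dict] = None
    stages: Sequence[str] = ALL_STAGES
    # stage parameters
    ratio: float = 0.9
    p: float = 0.99
    min_mapq: int = 5
    min_overlap: int = 10
    bins: Sequence[int] = (1000, 2000, 5000)
    junction_thresholds: Sequence[int] = (1, 5)
    depths: Optional[Sequence[int]] = None
    saturation_mode: str = "pooled"
    palindrome_sample: Optional[int] = None
    palindrome_min_len: int = 10

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulate is None:
            missing = [
                name for name in ("genome_sam", "transcriptome_sam", "gtf")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"either `simulate` or input paths {missing} must be provided"
                )
        if not 0 < self.ratio <= 1 or not 0 < self.p <= 1:
            raise ValueError("ratio and p must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config


def _write_tsv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the summary mapping written to
    ``summary.tsv``."""
    import os

    config.validate()
    outdir = lio.ensure_dir(config.outdir)
    plain = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(config).items()
    }
    with open(os.path.join(outdir, "run_config.yaml"), "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)

    if config.simulate is not None:
        sim = SimConfig.from_dict({"seed": config.seed, **config.simulate})
        paths = write_dataset(sim, os.path.join(outdir, "simulated"))
        config.genome_sam = paths["genome_sam"]
        config.transcriptome_sam = paths["transcriptome_sam"]
        config.gtf = paths["gtf"]
        config.genome_fasta = paths["genome_fasta"]
        config.transcript_fasta = paths["transcript_fasta"]
        config.tpm = paths["abundance"]
        config.fastq = [
            paths[k] for k in sorted(paths) if k.startswith("fastq_rep")
        ]

    models = lio.read_annotation(config.gtf, config.transcript_fasta)
    t2g = {m.transcript_id: m.gene_id for m in models}
    tlen = {m.transcript_id: m.length for m in models}
    genome = lio.read_fasta(config.genome_fasta) if config.genome_fasta else {}
    reads = [r for path in config.fastq for r in lio.read_fastq(path)]
    genome_recs = list(lio.read_alignments(config.genome_sam, TargetSpace.GENOME))
    txome_recs = list(
        lio.read_alignments(config.transcriptome_sam, TargetSpace.TRANSCRIPTOME)
    )
    genome_sets = tp.group_alignments(genome_recs)
    txome_sets = tp.group_alignments(txome_recs)
    tpm_table = lio.read_abundance_table(config.tpm) if config.tpm else None

    summary: dict[str, object] = {
        "lrtc_version": __version__,
        "seed": config.seed,
        "n_reads": len(reads),
        "n_transcripts": len(models),
        "n_genes": len(set(t2g.values())),
    }

    if "metrics" in config.stages:
        table, rates = mx.read_stats(reads, genome_recs + txome_recs)
        qual_rows = []
        for s in genome_sets:
            summ = mx.summarize_cigar(s.primary)
            q = mx.alignment_quality(summ, s.primary.read_length, s.primary.nm)
            qual_rows.append(
                {
                    "read_id": s.read_id,
                    "aligned_fraction": q.aligned_fraction,
                    "base_accuracy": q.base_accuracy,
                    "clipped_fraction": q.clipped_fraction,
                }
            )
        qual = pd.DataFrame(qual_rows)
        _write_tsv(table, os.path.join(outdir, "read_stats.tsv"))
        _write_tsv(qual, os.path.join(outdir, "alignment_quality.tsv"))
        summary.update(rates)
        if len(qual):
            summary["mean_aligned_fraction"] = float(qual["aligned_fraction"].mean())
            acc = qual["base_accuracy"].dropna()
            summary["mean_base_accuracy"] = float(acc.mean()) if len(acc) else None

    if "topology" in config.stages:
        rows = []
        for s in txome_sets:
            rows.append(
                {
                    "read_id": s.read_id,
                    "secondary_ambiguity": tp.classify_secondary_ambiguity(s, t2g).value,
                }
            )
        sec = pd.DataFrame(rows)
        supp_rows = []
        for s in genome_sets:
            for supp in s.supplementaries:
                call = tp.classify_supplementary(s.primary, supp)
                supp_rows.append(
                    {
                        "read_id": s.read_id,
                        "category": call.category.value,
                        "overlap_ratio": call.overlap_ratio,
                    }
                )
        supp = pd.DataFrame(supp_rows, columns=["read_id", "category", "overlap_ratio"])
        pal = tp.palindrome_scan(
            reads, min_len=config.palindrome_min_len,
            sample=config.palindrome_sample, seed=config.seed,
        )
        pal_frame = pd.DataFrame(
            sorted(pal.items()), columns=["read_id", "longest_revcomp_repeat"]
        )
        _write_tsv(sec, os.path.join(outdir, "secondary_ambiguity.tsv"))
        _write_tsv(supp, os.path.join(outdir, "supplementary_calls.tsv"))
        _write_tsv(pal_frame, os.path.join(outdir, "palindromes.tsv"))
        if len(sec):
            frac = (sec["secondary_ambiguity"] == "same_gene_only").mean()
            summary["same_gene_only_fraction"] = float(frac)
        summary["n_supplementary"] = len(supp)
        if len(supp):
            summary["supp_diff_strand_overlap_fraction"] = float(
                (supp["category"] == "same_chr_diff_strand_overlap").mean()
            )

    if "coverage" in config.stages:
        calls = []
        for s in txome_sets:
            call = cov.select_best_target(s, tlen, ratio=config.ratio, bins=config.bins)
            if call is not None:
                calls.append(call)
        call_frame = pd.DataFrame([dataclasses.asdict(c) for c in calls])
        strata = cov.coverage_by_stratum(calls, models, bins=config.bins)
        _write_tsv(call_frame, os.path.join(outdir, "coverage_calls.tsv"))
        _write_tsv(strata, os.path.join(outdir, "coverage_by_stratum.tsv"))
        if calls:
            summary["mean_coverage_fraction"] = float(
                call_frame["coverage_fraction"].mean()
            )
        if tpm_table is not None:
            observed = [
                s.primary.read_length for s in genome_sets
            ]
            dist = cov.expected_length_distribution(models, tpm_table, observed)
            summary["expected_length_mean"] = dist["mean"]
            if "ks_statistic" in dist:
                summary["length_ks_statistic"] = dist["ks_statistic"]

    if "junctions" in config.stages:
        observed = jx.extract_junctions(genome_recs)
        annotated = jx.annotated_junctions(models)
        matches = jx.match_junctions(observed, annotated, genome)
        per_read = jx.junctions_per_read(genome_recs)
        jsum = jx.junction_summary(
            matches, per_read, thresholds=config.junction_thresholds
        )
        lio.write_junction_bed(
            [m.observed for m in matches], os.path.join(outdir, "junctions.bed")
        )
        _write_tsv(jx.summary_frame(jsum), os.path.join(outdir, "junction_summary.tsv"))
        top_threshold = min(config.junction_thresholds)
        summary["annotated_junction_fraction"] = jsum["by_threshold"][top_threshold][
            "annotated_fraction"
        ]

    if "ambiguity" in config.stages:
        classes, sizes, csum = amb.compatibility_classes(
            txome_sets, p=config.p, fallback_matched_bases=True
        )
        pairs, nsum = amb.find_nested_pairs(models)
        self_frac = amb.self_assignment_test(models, p=config.p)
        pair_frame = pd.DataFrame(
            [dataclasses.asdict(p_) for p_ in pairs],
            columns=["container_id", "contained_id", "relation"],
        )
        size_frame = pd.DataFrame(
            sorted(sizes.items()), columns=["read_id", "class_size"]
        )
        _write_tsv(pair_frame, os.path.join(outdir, "nested_pairs.tsv"))
        _write_tsv(size_frame, os.path.join(outdir, "class_sizes.tsv"))
        summary["mean_class_size"] = csum["mean_class_size"]
        summary["singleton_class_fraction"] = csum["singleton_fraction"]
        summary["nested_pair_fraction"] = nsum["nested_fraction"]
        summary["self_assignment_singleton_fraction"] = self_frac

    if "count" in config.stages:
        ttable, gtable = cnt.count_transcripts_primary(
            txome_recs, t2g, min_mapq=config.min_mapq
        )
        ov_table = cnt.count_genes_overlap(
            genome_recs, models, min_overlap=config.min_overlap
        )
        detected, det_frame = cnt.detection_summary(ttable, models, bins=config.bins)
        count_frame = pd.DataFrame(
            sorted(ttable.counts.items()), columns=["transcript_id", "count"]
        )
        gene_frame = pd.DataFrame(
            sorted(ov_table.counts.items()), columns=["gene_id", "count"]
        )
        _write_tsv(count_frame, os.path.join(outdir, "transcript_counts.tsv"))
        _write_tsv(gene_frame, os.path.join(outdir, "gene_counts.tsv"))
        _write_tsv(det_frame, os.path.join(outdir, "detection_by_length.tsv"))
        summary["n_detected_transcripts"] = len(detected)
        summary["n_detected_genes"] = len(gtable.detected())

    if "saturate" in config.stages:
        by_rep: dict[str, list] = {}
        for rec in txome_recs:
            rep = rec.read_id.split("_")[1] if rec.read_id.startswith("read_") else "1"
            by_rep.setdefault(rep, []).append(rec)
        replicate_records = [by_rep[k] for k in sorted(by_rep)]
        n_primary = sum(
            1 for r in txome_recs if r.category is AlignmentCategory.PRIMARY
        )
        depths = config.depths or [
            max(1, n_primary // 5), max(1, n_primary // 2), n_primary
        ]
        points = cnt.saturation_curve(
            [txome_recs] if config.saturation_mode == "pooled" else replicate_records,
            depths=[d for d in depths if d <= n_primary],
            transcript_to_gene=t2g,
            seed=config.seed,
            mode=config.saturation_mode,
            min_mapq=config.min_mapq,
        )
        sat_frame = pd.DataFrame([dataclasses.asdict(p_) for p_ in points])
        _write_tsv(sat_frame, os.path.join(outdir, "saturation.tsv"))
        if points:
            summary["saturation_max_transcripts"] = points[-1].n_detected_transcripts

    if "classify" in config.stages:
        queries = [
            st.model_from_alignment(s.primary, f"q_{s.read_id}")
            for s in genome_sets
        ]
        calls = st.classify_structural(queries, models)
        call_frame = pd.DataFrame([dataclasses.asdict(c) for c in calls])
        call_frame["category"] = [c.category.value for c in calls]
        _write_tsv(call_frame, os.path.join(outdir, "structural_calls.tsv"))
        counts = call_frame["category"].value_counts()
        for cat in st.StructuralCategory:
            summary[f"structural_{cat.value}"] = int(counts.get(cat.value, 0))

    summary_frame = pd.DataFrame(
        [(k, v) for k, v in summary.items()], columns=["key", "value"]
    )
    _write_tsv(summary_frame, os.path.join(outdir, "summary.tsv"))
    with open(os.path.join(outdir, "log.txt"), "w") as fh:
        fh.write(f"lrtc version: {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"stages: {','.join(config.stages)}\n")
        fh.write(
            f"parameters: ratio={config.ratio} p={config.p} "
            f"min_mapq={config.min_mapq} min_overlap={config.min_overlap}\n"
        )
    return summary
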