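"""Junction-chain structural categories, the brute-force matcher
cross-check and UpSet-style overlap tables."""

import numpy as np
import pytest

from lrtc import structure as st
from lrtc import topology as tp
from lrtc.records import TranscriptModel
from lrtc.simulate import SimConfig, build_transcriptome, simulate_reads, truth_alignments


def _model(tid, exons, strand="+", chrom="chr1", gene=None):
    return TranscriptModel(tid, gene or tid, chrom, strand, exons)


class TestJunctionChain:
    def test_two_exon_chain(self):
        chain = st.junction_chain(_model("q", [(0, 100), (200, 300)]))
        assert chain.introns == ((100, 200),)

    def test_single_exon_empty_chain(self):
        chain = st.junction_chain(_model("q", [(0, 100)]))
        assert chain.introns == ()

    def test_three_exons_two_introns_in_order(self):
        chain = st.junction_chain(_model("q", [(0, 10), (20, 30), (50, 60)]))
        assert chain.introns == ((10, 20), (30, 50))


REF = [
    # R1: 5 exons -> introns (100,200) (300,400) (500,600) (700,800)
    _model("R1", [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]),
    # R2: shares (100,200) but has a different second intron
    _model("R2", [(0, 100), (200, 350), (450, 500)]),
    _model("R3", [(2000, 2400)]),  # mono-exon reference
]


class TestClassifyStructural:
    def _call(self, query):
        (call,) = st.classify_structural([query], REF)
        return call

    def test_full_splice_match(self):
        q = _model("q", [(10, 100), (200, 300), (400, 500), (600, 700), (800, 880)])
        call = self._call(q)
        assert call.category is st.StructuralCategory.FULL_SPLICE_MATCH
        assert call.matched_reference_id == "R1"

    def test_incomplete_splice_match_middle_introns(self):
        # middle 2 of R1's 4 introns, consecutive
        q = _model("q", [(250, 300), (400, 500), (600, 650)])
        assert self._call(q).category is st.StructuralCategory.INCOMPLETE_SPLICE_MATCH

    def test_novel_combination_of_annotated_junctions(self):
        # mixes R1's first intron with R2's second: all annotated, chain novel
        q = _model("q", [(0, 100), (200, 350), (450, 500), (600, 700), (800, 900)])
        assert self._call(q).category is st.StructuralCategory.NOVEL_IN_CATALOG

    def test_unannotated_junction_is_novel_not_in_catalog(self):
        q = _model("q", [(0, 100), (250, 300)])
        assert self._call(q).category is st.StructuralCategory.NOVEL_NOT_IN_CATALOG

    def test_non_consecutive_subset_is_novel_in_catalog(self):
        # R1's introns 1 and 3, skipping 2: subset but not consecutive
        q = _model("q", [(0, 100), (200, 500), (600, 700)])
        chain = tuple(q.introns())
        assert chain == ((100, 200), (500, 600))
        assert self._call(q).category is st.StructuralCategory.NOVEL_IN_CATALOG

    def test_mono_exon_inside_reference(self):
        q = _model("q", [(420, 480)])
        assert self._call(q).category is st.StructuralCategory.MONO_EXON

    def test_intergenic_no_reference_overlap(self):
        q = _model("q", [(5000, 5100)])
        assert self._call(q).category is st.StructuralCategory.INTERGENIC

    def test_strand_mismatch_blocks_chain_match(self):
        q = _model("q", [(10, 100), (200, 300), (400, 500), (600, 700), (800, 880)],
                   strand="-")
        call = self._call(q)
        assert call.category is not st.StructuralCategory.FULL_SPLICE_MATCH

    def test_unknown_strand_takes_best_category(self):
        q = _model("q", [(10, 100), (200, 300), (400, 500), (600, 700), (800, 880)],
                   strand=".")
        assert self._call(q).category is st.StructuralCategory.FULL_SPLICE_MATCH


def brute_force_classify(query, references):
    """Independent matcher: enumerate every reference chain and every
    consecutive sub-chain explicitly."""
    chain = tuple(query.introns())
    overlap = any(
        r.chromosome == query.chromosome and query.start < r.end and r.start < query.end
        for r in references
    )
    if not overlap:
        return "intergenic"
    if not chain:
        return "mono_exon"
    strands = [query.strand] if query.strand in "+-" else ["+", "-"]
    cats = []
    for strand in strands:
        chains = [
            tuple(r.introns()) for r in references
            if r.chromosome == query.chromosome and r.strand == strand
        ]
        all_junctions = {j for c in chains for j in c}
        subchains = {
            c[i:j]
            for c in chains
            for i in range(len(c))
            for j in range(i + 1, len(c) + 1)
        }
        if chain in chains:
            cats.append("full_splice_match")
        elif chain in subchains:
            cats.append("incomplete_splice_match")
        elif all(j in all_junctions for j in chain):
            cats.append("novel_in_catalog")
        else:
            cats.append("novel_not_in_catalog")
    order = ["full_splice_match", "incomplete_splice_match", "novel_in_catalog",
             "novel_not_in_catalog"]
    return min(cats, key=order.index)


class TestAgainstBruteForce:
    def test_matches_brute_force_on_synthetic_catalog(self):
        cfg = SimConfig(
            n_genes=30, min_isoforms=2, max_isoforms=5, nested_isoform_rate=0.4,
            duplicate_rate=0.2, seed=97,
        )
        _, references = build_transcriptome(cfg)
        assert len(references) <= 200
        rng = np.random.default_rng(97)
        queries = []
        # real isoforms, sub-chains, perturbed and shifted variants
        for i, ref in enumerate(references):
            queries.append(ref)
            introns = ref.introns()
            if len(introns) >= 2:
                # read-like truncation: drop flanking introns
                k = int(rng.integers(1, len(introns)))
                sub = introns[k - 1 : k + 1]
                exons = [(sub[0][0] - 50, sub[0][0])]
                for a, b in zip(sub, sub[1:]):
                    exons.append((a[1], b[0]))
                exons.append((sub[-1][1], sub[-1][1] + 50))
                queries.append(_model(f"q{i}", exons, strand=ref.strand,
                                      chrom=ref.chromosome))
            if introns:
                # jittered junction -> unannotated
                a, b = introns[0]
                queries.append(
                    _model(f"w{i}", [(a - 60, a), (b + 3, b + 63)],
                           strand=ref.strand, chrom=ref.chromosome)
                )
        for query in queries:
            (call,) = st.classify_structural([query], references)
            assert call.category.value == brute_force_classify(query, references), (
                query.transcript_id
            )

    def test_truncated_reads_always_match_or_subchain(self):
        """Multi-exon chains of truncation-only reads are always full or
        incomplete splice matches, never novel."""
        cfg = SimConfig(
            n_genes=10, n_reads=300, full_length_prob=0.3, max_isoforms=2,
            substitution_rate=0, insertion_rate=0, deletion_rate=0, seed=101,
        )
        _, models = build_transcriptome(cfg)
        reads, truths = simulate_reads(models, cfg)
        genome_recs, _ = truth_alignments(reads, truths, models)
        sets = tp.group_alignments(genome_recs)
        queries = [
            st.model_from_alignment(s.primary, f"q_{s.read_id}") for s in sets
        ]
        calls = st.classify_structural(queries, models)
        multi = [
            c for c, q in zip(calls, queries) if len(q.exons) > 1
        ]
        assert multi
        allowed = {
            st.StructuralCategory.FULL_SPLICE_MATCH,
            st.StructuralCategory.INCOMPLETE_SPLICE_MATCH,
        }
        assert all(c.category in allowed for c in multi)


class TestOverlapSets:
    def test_exclusive_patterns(self):
        out = st.overlap_sets({"D1": {"A", "B"}, "D2": {"B", "C"}})
        assert out == {("D1",): 1, ("D1", "D2"): 1, ("D2",): 1}

    def test_identical_sets_single_bar(self):
        out = st.overlap_sets({"D1": {"A", "B"}, "D2": {"A", "B"}})
        assert out == {("D1", "D2"): 2}

    def test_disjoint_sets(self):
        out = st.overlap_sets({"D1": {"A"}, "D2": {"B"}, "D3": {"C"}})
        assert out == {("D1",): 1, ("D2",): 1, ("D3",): 1}

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            st.overlap_sets({})
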