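"""Pileup SNV calling thresholds, annotation through strand, gene ranking."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from gracilib import (
    PileupColumn,
    PileupMatrix,
    annotate_snvs,
    call_snvs,
    summarize_by_gene,
)
from gracilib.variants import SNV, GeneVariantSummary


def column(pos, ref, n_ref, n_alt, alt="T", qual=40, alt_qual=None):
    obs = [(ref, qual)] * n_ref + [(alt, alt_qual if alt_qual is not None else qual)] * n_alt
    return PileupColumn(pos, ref, obs)


class TestCaller:
    def test_below_min_coverage_no_call(self):
        # 9 quality-passing reads is under the coverage floor of 10
        assert call_snvs([column(0, "A", 6, 3)]) == []

    def test_boundary_call_all_three_thresholds(self):
        # 40 reads, 2 alt: depth>=10, freq==0.05, support==2 -> call
        calls = call_snvs([column(0, "A", 38, 2)])
        assert len(calls) == 1
        assert calls[0].frequency == pytest.approx(0.05)

    def test_single_read_support_never_called(self):
        assert call_snvs([column(0, "A", 39, 1)]) == []

    def test_low_quality_bases_invisible_to_depth_and_alt(self):
        # 12 reads but 3 below Q30: depth 9 -> no call even though alt freq high
        obs = [("A", 40)] * 6 + [("T", 40)] * 3 + [("T", 20)] * 3
        assert call_snvs([PileupColumn(0, "A", obs)]) == []

    def test_multiple_alt_alleles_evaluated_independently(self):
        obs = [("A", 40)] * 30 + [("T", 40)] * 8 + [("G", 40)] * 2
        calls = call_snvs([PileupColumn(0, "A", obs)])
        assert {(c.alt_base, c.alt_count) for c in calls} == {("T", 8), ("G", 2)}

    def test_unsorted_input_rejected(self):
        cols = [column(5, "A", 20, 5), column(3, "C", 20, 5)]
        with pytest.raises(ValueError, match="not sorted"):
            call_snvs(cols)

    def test_empty_input_empty_output(self):
        assert call_snvs([]) == []

    def test_matrix_and_column_paths_agree(self):
        ref = "ACGTACGTAC"
        mat = PileupMatrix(ref, min_base_quality=30)
        for start, bases in [(0, "ACGTAC"), (2, "GTACGT"), (2, "TTACGT"), (2, "TTACGT")]:
            mat.add_read(start, bases, 40)
        from_matrix = call_snvs(mat, min_coverage=2, min_frequency=0.05, min_support=2)
        from_columns = call_snvs(
            list(mat.columns()), min_coverage=2, min_frequency=0.05, min_support=2
        )
        assert from_matrix == from_columns
        assert any(c.alt_base == "T" and c.position == 2 for c in from_matrix)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGT"),
                st.integers(0, 30),
                st.integers(0, 10),
                st.integers(20, 45),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_calls_monotone_in_thresholds(self, spec):
        """Raising any threshold can only remove calls, never add them."""
        cols = []
        for i, (ref, n_ref, n_alt, q) in enumerate(spec):
            alt = "A" if ref != "A" else "C"
            cols.append(
                PileupColumn(i, ref, [(ref, q)] * n_ref + [(alt, q)] * n_alt)
            )
        base = {(c.position, c.alt_base) for c in call_snvs(cols)}
        for kwargs in (
            {"min_coverage": 15},
            {"min_frequency": 0.2},
            {"min_base_quality": 41},
            {"min_support": 5},
        ):
            stricter = {(c.position, c.alt_base) for c in call_snvs(cols, **kwargs)}
            assert stricter <= base


class TestAnnotation:
    def test_plus_strand_synonymous(self, toy_genome):
        # geneA codon GAT at CDS offsets 9-11 (genomic 19-21); third position T->C
        snv = SNV(position=21, ref_base="T", alt_base="C", depth=50, alt_count=10)
        (ann,) = annotate_snvs([snv], toy_genome.genes, toy_genome)
        assert ann.gene_id == "geneA"
        assert ann.effect.category == "synonymous"
        assert (ann.effect.ref_aa, ann.effect.alt_aa) == ("D", "D")

    def test_minus_strand_maps_through_strand(self, toy_genome):
        # geneB CDS offset 5 = third base of codon GAT; genomic base is the
        # complement on the plus strand at position end-1-5 = 49
        pos = 49
        assert toy_genome.seq[pos] == "A"  # complement of CDS T
        snv = SNV(position=pos, ref_base="A", alt_base="G", depth=50, alt_count=10)
        (ann,) = annotate_snvs([snv], toy_genome.genes, toy_genome)
        assert ann.gene_id == "geneB"
        # genomic A->G is CDS T->C: GAT->GAC, synonymous
        assert ann.effect.category == "synonymous"
        assert ann.effect.codon_position == 3

    def test_intergenic(self, toy_genome):
        snv = SNV(position=2, ref_base="T", alt_base="C", depth=50, alt_count=10)
        (ann,) = annotate_snvs([snv], toy_genome.genes, toy_genome)
        assert ann.is_intergenic

    def test_reference_mismatch_names_position(self, toy_genome):
        snv = SNV(position=2, ref_base="G", alt_base="C", depth=50, alt_count=10)
        with pytest.raises(ValueError, match="position 2"):
            annotate_snvs([snv], toy_genome.genes, toy_genome)

    def test_overlapping_genes_flagged_twice(self, toy_genome):
        from gracilib import GeneModel

        genes = toy_genome.genes + [GeneModel("geneA2", 13, 28, "+", 25)]
        snv = SNV(position=21, ref_base="T", alt_base="C", depth=50, alt_count=10)
        anns = annotate_snvs([snv], genes, toy_genome)
        assert len(anns) == 2 and all(a.overlapping for a in anns)


class TestSummary:
    def test_pure_synonymous_gene_ranks_first(self, toy_genome):
        anns = []
        # 17 synonymous in geneA (positions recycled; summary only counts)
        snv_syn = SNV(21, "T", "C", 50, 10)
        for _ in range(17):
            anns.extend(annotate_snvs([snv_syn], toy_genome.genes, toy_genome))
        snv_non = SNV(49, "A", "T", 50, 10)  # geneB GAT->GAA = D->E nonsyn
        anns.extend(annotate_snvs([snv_non], toy_genome.genes, toy_genome))
        summaries = summarize_by_gene(anns, toy_genome.genes)
        assert summaries[0].gene_id == "geneA"
        assert summaries[0].n_syn == 17 and summaries[0].n_nonsyn == 0
        assert summaries[0].syn_proportion == 1.0

    def test_gene_without_snvs_is_last_with_nan_proportion(self, toy_genome):
        snv = SNV(21, "T", "C", 50, 10)
        anns = annotate_snvs([snv], toy_genome.genes, toy_genome)
        summaries = summarize_by_gene(anns, toy_genome.genes)
        tail = summaries[-1]
        assert tail.gene_id == "geneB"
        assert (tail.n_syn, tail.n_nonsyn) == (0, 0)
        assert math.isnan(tail.syn_proportion)

    def test_totals_conserved(self, toy_genome):
        snvs = [
            SNV(21, "T", "C", 50, 10),  # geneA syn
            SNV(49, "A", "T", 50, 10),  # geneB nonsyn
            SNV(2, "T", "C", 50, 10),  # intergenic
        ]
        anns = annotate_snvs(snvs, toy_genome.genes, toy_genome)
        summaries = summarize_by_gene(anns, toy_genome.genes)
        classified = sum(s.n_syn + s.n_nonsyn + s.n_indeterminate for s in summaries)
        intergenic = sum(1 for a in anns if a.is_intergenic)
        assert classified + intergenic == len(snvs)

    def test_tie_breaks_by_syn_count_then_id(self):
        a = GeneVariantSummary("b", n_syn=2, n_nonsyn=0)
        b = GeneVariantSummary("a", n_syn=5, n_nonsyn=0)
        from gracilib import GeneModel

        genes = [GeneModel("b", 0, 3), GeneModel("a", 3, 6)]
        ranked = summarize_by_gene([], genes)  # empty: both NaN, id order
        assert [s.gene_id for s in ranked] == ["a", "b"]
        assert b.syn_proportion == a.syn_proportion == 1.0
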