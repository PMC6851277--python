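"""Synthetic-data generator contracts: genomes, loci, variants, reads."""

import numpy as np
import pytest

from gracilib import (
    classify_substitution,
    decompose,
    get_code,
    inject_population_variants,
    make_genome,
    pileup_from_truth,
    plant_repeat_locus,
    reverse_complement,
    simulate_reads,
)
from gracilib.simulate import DEFAULT_UNITS, PopulationSpec


@pytest.fixture(scope="module")
def sim():
    genome, truth = make_genome(length=20_000, n_genes=8, seed=11)
    genome, truth = plant_repeat_locus(genome, truth, n_units=12, seed=12)
    pop = inject_population_variants(genome, truth, n_variants=17, seed=13)
    return pop


class TestMakeGenome:
    def test_contract_gene_count_and_gc(self):
        genome, _ = make_genome(length=50_000, n_genes=40, seed=7)
        assert len(genome.genes) == 40
        assert 0.28 <= genome.gc_fraction <= 0.30
        assert all(len(g) >= 300 and len(g) % 3 == 0 for g in genome.genes)

    def test_same_seed_reproduces_identically(self):
        a, _ = make_genome(length=20_000, n_genes=8, seed=42)
        b, _ = make_genome(length=20_000, n_genes=8, seed=42)
        assert a.seq == b.seq
        assert a.genes == b.genes

    def test_genes_are_stop_free_under_their_code(self):
        genome, _ = make_genome(length=20_000, n_genes=8, seed=1)
        for gene_id, protein in genome.translations().items():
            assert "*" not in protein[:-1], gene_id
            assert protein.endswith("*")
            assert protein.startswith("M")

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="cannot pack"):
            make_genome(length=5_000, n_genes=40, seed=0)


class TestPlantLocus:
    def test_planted_array_decomposes_to_truth(self, code25):
        genome, truth = make_genome(length=20_000, n_genes=8, seed=2)
        genome, truth = plant_repeat_locus(genome, truth, n_units=12, seed=3)
        rl = truth.repeat_locus
        locus = genome.seq[rl.locus_start : rl.locus_end]
        dec = decompose(locus, rl.unit_length, code25)
        assert dec.n_units == 12
        assert "".join(rl.unit_order) == locus
        assert dec.conserved and dec.units[0].translation == "PTD"

    def test_gene_model_still_in_frame_and_stop_free(self):
        genome, truth = make_genome(length=20_000, n_genes=8, seed=2)
        genome, truth = plant_repeat_locus(genome, truth, n_units=12, seed=3)
        protein = genome.translations()[truth.repeat_locus.gene_id]
        assert "*" not in protein[:-1]
        assert "PTD" in protein

    def test_zero_units_is_identity(self):
        genome, truth = make_genome(length=20_000, n_genes=8, seed=2)
        genome2, truth2 = plant_repeat_locus(genome, truth, n_units=0, seed=3)
        assert genome2.seq == genome.seq and truth2.repeat_locus is None

    def test_unit_length_must_be_codon_multiple(self):
        genome, truth = make_genome(length=20_000, n_genes=8, seed=2)
        with pytest.raises(ValueError, match="divisible by 3"):
            plant_repeat_locus(genome, truth, units=("CCAA",), n_units=2, seed=0)


class TestInjectVariants:
    def test_all_injected_variants_are_synonymous(self, sim):
        genome, truth = sim.genome, sim.truth
        gene = genome.gene(truth.repeat_locus.gene_id)
        cds = gene.cds_sequence(genome.seq)
        for v in truth.variants:
            off = gene.genomic_to_cds(v.position)
            alt = v.alt if gene.strand == "+" else reverse_complement(v.alt)
            eff = classify_substitution(cds, off, alt, get_code(gene.transl_table))
            assert eff.category == "synonymous"
            assert eff.codon_position == 3

    def test_variants_confined_to_locus(self, sim):
        rl = sim.truth.repeat_locus
        assert all(rl.locus_start <= v.position < rl.locus_end for v in sim.truth.variants)

    def test_haplotypes_carry_the_recorded_alleles(self, sim):
        for v in sim.truth.variants:
            for k, hap in enumerate(sim.haplotypes):
                expected = v.alt if k in v.haplotypes else v.ref
                assert hap[v.position] == expected

    def test_nonsynonymous_mode_produces_some(self):
        genome, truth = make_genome(length=20_000, n_genes=8, seed=5)
        genome, truth = plant_repeat_locus(genome, truth, n_units=12, seed=6)
        pop = inject_population_variants(
            genome, truth, n_variants=10, synonymous_only=False, seed=7
        )
        gene = genome.gene(truth.repeat_locus.gene_id)
        cds = gene.cds_sequence(genome.seq)
        cats = set()
        for v in pop.truth.variants:
            off = gene.genomic_to_cds(v.position)
            cats.add(classify_substitution(cds, off, v.alt, get_code(25)).category)
        assert cats - {"synonymous"}

    def test_bad_frequency_rejected(self):
        genome, truth = make_genome(length=20_000, n_genes=8, seed=5)
        genome, truth = plant_repeat_locus(genome, truth, seed=6)
        with pytest.raises(ValueError, match="outside"):
            inject_population_variants(genome, truth, freqs=(0.0,), seed=7)


class TestSimulateReads:
    def test_error_free_reads_match_their_haplotype(self, sim):
        reads = simulate_reads(sim, depth=5, seed=21)
        by_id = {}
        for p in reads.pairs:
            by_id[f"{p.pair_id}/1"] = p.r1
            by_id[f"{p.pair_id}/2"] = p.r2
        L = len(sim.genome.seq)
        for pl in reads.placements[:200]:
            hap = sim.haplotypes[pl.haplotype]
            seq = by_id[pl.read_id]
            if pl.strand == "-":
                seq = reverse_complement(seq)
            span = hap[pl.position : pl.position + len(seq)]
            if len(span) < len(seq):  # circular wrap
                span += hap[: len(seq) - len(span)]
            assert seq == span

    def test_realized_depth_and_insert_near_targets(self, sim):
        reads = simulate_reads(sim, depth=40, seed=22)
        L = len(sim.genome.seq)
        total_bases = 2 * reads.read_length * len(reads.pairs)
        assert total_bases / L == pytest.approx(40, rel=0.05)
        r1 = {p.read_id: p.position for p in reads.placements if p.strand == "+"}
        r2 = {p.read_id: p.position for p in reads.placements if p.strand == "-"}
        spans = []
        for rid, pos in r1.items():
            mate = r2[rid.replace("/1", "/2")]
            span = (mate + reads.read_length - pos) % L
            spans.append(span)
        assert np.mean(spans) == pytest.approx(300, rel=0.02)

    def test_same_seed_reproduces_reads(self, sim):
        a = simulate_reads(sim, depth=5, seed=9)
        b = simulate_reads(sim, depth=5, seed=9)
        assert a.pairs == b.pairs and a.placements == b.placements

    def test_error_rate_introduces_mismatches(self, sim):
        noisy = simulate_reads(sim, depth=2, error_rate=0.05, seed=10)
        clean = simulate_reads(sim, depth=2, error_rate=0.0, seed=10)
        diffs = sum(
            a != b
            for pa, pb in zip(noisy.pairs, clean.pairs)
            for a, b in zip(pa.r1 + pa.r2, pb.r1 + pb.r2)
        )
        n_bases = sum(len(p.r1) + len(p.r2) for p in clean.pairs)
        assert diffs / n_bases == pytest.approx(0.05, rel=0.3)

    def test_pileup_from_truth_depth(self, sim):
        reads = simulate_reads(sim, depth=10, seed=30)
        mat = pileup_from_truth(reads, sim.genome.seq)
        assert mat.depth().mean() == pytest.approx(10, rel=0.05)


def test_default_units_all_encode_the_tripeptide(code25):
    from gracilib import translate_cds

    assert {translate_cds(u, code25) for u in DEFAULT_UNITS} == {"PTD"}
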