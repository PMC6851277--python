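"""End-to-end analysis: simulate (or load) a dataset and run every stage.

This is the programmatic form of the full workflow: variant calling and
synonymous/nonsynonymous gene ranking, codon-usage enrichment of the repeat
gene against the genome, wobble-compatibility of its dominant codons,
paired-read reconstruction of the repeat locus, GC-skew assembly
verification and UTR stem-loop detection. The ``bd15-like`` preset
generates the study conditions: a low-GC circular code-25 genome with one
tandem tripeptide-repeat locus whose population heterogeneity is purely
synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as gio
from .codonusage import codon_incidence, enrichment
from .gcskew import SkewProfile, skew_profile
from .gencode import get_code
from .models import Genome
from .repeats import Placement, RepeatLocusModel, reconstruct_locus
from .simulate import (
    SimReads,
    SimTruth,
    inject_population_variants,
    make_genome,
    pileup_from_truth,
    plant_repeat_locus,
    simulate_reads,
)
from .stemloop import FlankHairpin, scan_gene_flanks
from .variants import AnnotatedSNV, GeneVariantSummary, annotate_snvs, call_snvs, summarize_by_gene

#: generation parameters of the bd15-like preset (the study conditions:
#: ~29% G+C, code 25, 40x coverage, 100 bp reads, 300±30 inserts, a
#: 12-unit tripeptide repeat array with 17 synonymous population variants)
BD15_PRESET = dict(
    length=20_000,
    gc_fraction=0.29,
    n_genes=8,
    code=25,
    n_units=12,
    n_variants=17,
    depth=40.0,
    read_length=100,
    insert_mean=300.0,
    insert_sd=30.0,
    error_rate=0.0,
)


@dataclass
class AnalysisResult:
    genome: Genome
    truth: SimTruth
    reads: SimReads
    annotated: list[AnnotatedSNV]
    summaries: list[GeneVariantSummary]
    enrichment_table: object  # pandas DataFrame
    locus_model: RepeatLocusModel | None
    placements: list[Placement] = field(default_factory=list)
    skew: SkewProfile | None = None
    flank_hairpins: list[FlankHairpin] = field(default_factory=list)

    @property
    def repeat_gene_summary(self) -> GeneVariantSummary:
        gid = self.truth.repeat_locus.gene_id
        return next(s for s in self.summaries if s.gene_id == gid)


def analyze_synthetic(
    seed: int = 7,
    preset: dict | None = None,
    config: gio.RunConfig | None = None,
    flank_anchor: int = 60,
) -> AnalysisResult:
    """Run the whole pipeline on a freshly generated synthetic dataset."""
    p = dict(BD15_PRESET)
    if preset:
        p.update(preset)
    cfg = config or gio.RunConfig(seed=seed)
    code = get_code(p["code"])

    genome, truth = make_genome(
        length=p["length"], gc_fraction=p["gc_fraction"], n_genes=p["n_genes"],
        code=p["code"], seed=seed,
    )
    genome, truth = plant_repeat_locus(genome, truth, n_units=p["n_units"], seed=seed + 1)
    pop = inject_population_variants(
        genome, truth, n_variants=p["n_variants"], seed=seed + 2
    )
    reads = simulate_reads(
        pop, depth=p["depth"], read_length=p["read_length"],
        insert_mean=p["insert_mean"], insert_sd=p["insert_sd"],
        error_rate=p["error_rate"], seed=seed + 3,
    )

    # variants → per-gene ranking
    pile = pileup_from_truth(reads, genome.seq, min_base_quality=cfg.min_base_quality)
    snvs = call_snvs(
        pile, min_coverage=cfg.min_coverage, min_base_quality=cfg.min_base_quality,
        min_frequency=cfg.min_frequency, min_support=cfg.min_support,
    )
    annotated = annotate_snvs(snvs, genome.genes, genome)
    summaries = summarize_by_gene(annotated, genome.genes)

    # codon usage: repeat gene vs pooled genome
    rl = truth.repeat_locus
    repeat_gene = genome.gene(rl.gene_id)
    gene_prof = codon_incidence(repeat_gene.cds_sequence(genome.seq))
    genome_prof = codon_incidence([g.cds_sequence(genome.seq) for g in genome.genes])
    enr = enrichment(gene_prof, genome_prof, code)

    # repeat locus reconstruction from the reads
    left = genome.seq[rl.locus_start - flank_anchor : rl.locus_start]
    right = genome.seq[rl.locus_end : rl.locus_end + flank_anchor]
    locus_reads = _reads_near(reads, genome, rl.locus_start, rl.locus_end)
    try:
        model, placements = reconstruct_locus(
            locus_reads, left, right,
            insert_mean=p["insert_mean"], insert_sd=p["insert_sd"],
            unit_length=rl.unit_length, code=code,
        )
    except ValueError:
        model, placements = None, []

    skew = skew_profile(genome.seq, window=cfg.skew_window, step=cfg.skew_step)
    hairpins = scan_gene_flanks(genome, repeat_gene)

    return AnalysisResult(
        genome=genome, truth=truth, reads=reads, annotated=annotated,
        summaries=summaries, enrichment_table=enr, locus_model=model,
        placements=placements, skew=skew, flank_hairpins=hairpins,
    )


def _reads_near(reads: SimReads, genome: Genome, lo: int, hi: int, margin: int = 400):
    """Pairs with at least one mate within ``margin`` of the locus."""
    from .repeats import ReadPair

    L = len(genome.seq)
    wanted = set()
    for pl in reads.placements:
        s, e = pl.position, pl.position + reads.read_length
        if s < hi + margin and e > lo - margin:  # no wrap handling needed mid-genome
            wanted.add(pl.read_id.rsplit("/", 1)[0])
    return [p for p in reads.pairs if p.pair_id in wanted]


def write_outputs(result: AnalysisResult, outdir) -> Path:
    """Write the self-describing output directory for one analysis run."""
    out = gio.ensure_dir(outdir)
    gio.write_fasta(result.genome, out / "genome.fasta")
    gio.write_gff3(result.genome, out / "genes.gff3")
    gio.write_fastq_pairs(result.reads.pairs, out / "reads_1.fastq", out / "reads_2.fastq")
    result.truth.to_json(out / "truth.json")
    gio.write_vcf(result.annotated, result.genome.id, out / "variants.vcf")
    gio.write_gene_summary_tsv(result.summaries, out / "gene_summary.tsv")
    result.enrichment_table.to_csv(out / "codon_enrichment.tsv", sep="\t", index=False)
    result.skew.to_frame().to_csv(out / "gcskew.tsv", sep="\t", index=False)
    with open(out / "stemloops.tsv", "w") as fh:
        fh.write("flank\toffset_start\toffset_end\tstem_bp\tloop_nt\tsequence\n")
        for fh_ in result.flank_hairpins:
            hp = fh_.hairpin
            fh.write(
                f"{fh_.flank}\t{fh_.offset_start}\t{fh_.offset_end}"
                f"\t{hp.stem_length}\t{hp.loop_length}\t{hp.sequence}\n"
            )
    if result.locus_model is not None:
        with open(out / "repeat_locus.fasta", "w") as fh:
            fh.write(">repeat_locus_consensus\n")
            fh.write(result.locus_model.consensus + "\n")
        with open(out / "placements.tsv", "w") as fh:
            fh.write("read_id\tposition\torientation\tstatus\n")
            for pl in result.placements:
                fh.write(f"{pl.read_id}\t{pl.position}\t{pl.orientation}\t{pl.status}\n")
    return out
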