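"""Threshold-based SNV calling and synonymous/nonsynonymous summarization.

The caller reproduces the filtering logic of a classic pileup-threshold
variant caller run with minimum coverage 10, minimum base quality 30 and
minimum variant allele frequency 0.05, plus an explicit minimum of two
supporting reads (variants seen on a single read are never reported).
Depth is quality-filtered depth: bases below the quality threshold
contribute neither to coverage nor to allele counts.

Per-gene summaries count synonymous vs nonsynonymous substitutions under
the gene's own translation table and rank genes by synonymous proportion —
the statistic that singles out a locus under strong stabilizing selection,
where population heterogeneity is tolerated only at silent sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .gencode import (
    GeneticCode,
    INDETERMINATE,
    SubstitutionEffect,
    classify_substitution,
    get_code,
    normalize_dna,
    reverse_complement,
)
from .models import GeneModel, Genome

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PileupColumn:
    """One genomic position: reference base plus per-read (base, quality)."""

    position: int
    ref_base: str
    observations: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ref_base = normalize_dna(self.ref_base)
        for base, qual in self.observations:
            if qual < 0:
                raise ValueError(f"negative quality at position {self.position}")
            if normalize_dna(base) not in "ACGTN":
                raise ValueError(f"invalid base {base!r} at position {self.position}")


class PileupMatrix:
    """Vectorized pileup: quality-filtered base counts per position.

    Bases below ``min_base_quality`` are dropped at construction; the
    threshold is recorded so :func:`call_snvs` can refuse a stricter filter
    than the matrix can honour.
    """

    def __init__(self, ref_seq: str, min_base_quality: int = 30):
        self.ref_seq = normalize_dna(ref_seq)
        self.min_base_quality = min_base_quality
        self.counts = np.zeros((4, len(self.ref_seq)), dtype=np.int32)

    def add_read(self, start: int, bases: str, qualities: Sequence[int] | int) -> None:
        """Add an aligned, gap-free read starting at ``start`` (circular wrap)."""
        n = len(self.ref_seq)
        bases = normalize_dna(bases)
        if isinstance(qualities, int):
            if qualities < self.min_base_quality:
                return
            quals = None
        else:
            quals = np.asarray(qualities)
        for i, b in enumerate(bases):
            if b == "N":
                continue
            if quals is not None and quals[i] < self.min_base_quality:
                continue
            self.counts[_BASE_INDEX[b], (start + i) % n] += 1

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def columns(self) -> Iterable[PileupColumn]:
        """Expand to per-column form (observations carry the filter quality)."""
        q = self.min_base_quality
        for pos in range(len(self.ref_seq)):
            obs = []
            for bi, base in enumerate(_BASES):
                obs.extend([(base, q)] * int(self.counts[bi, pos]))
            if obs:
                yield PileupColumn(pos, self.ref_seq[pos], obs)


@dataclass(frozen=True)
class SNV:
    """A called single-nucleotide variant (0-based position)."""

    position: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int

    @property
    def frequency(self) -> float:
        return self.alt_count / self.depth

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("SNV alt equals ref")
        if not 0 < self.alt_count <= self.depth:
            raise ValueError("alt_count must be in (0, depth]")


def _call_column(
    ref: str,
    counts4: Sequence[int],
    position: int,
    min_coverage: int,
    min_frequency: float,
    min_support: int,
) -> list[SNV]:
    depth = int(sum(counts4))
    if depth < min_coverage:
        return []
    out = []
    for base, cnt in zip(_BASES, counts4):
        cnt = int(cnt)
        if base == ref or cnt == 0:
            continue
        if cnt >= min_support and cnt / depth >= min_frequency:
            out.append(SNV(position, ref, base, depth, cnt))
    return out


def call_snvs(
    pileup: PileupMatrix | Iterable[PileupColumn],
    min_coverage: int = 10,
    min_base_quality: int = 30,
    min_frequency: float = 0.05,
    min_support: int = 2,
) -> list[SNV]:
    """Call SNVs from a pileup.

    Each non-reference allele at a column is evaluated independently and
    emitted iff quality-filtered depth ≥ ``min_coverage``, allele frequency
    ≥ ``min_frequency`` and supporting reads ≥ ``min_support``.

    Raises
    ------
    ValueError
        If per-column input is not sorted by position, or a
        :class:`PileupMatrix` was built with a laxer quality filter than
        ``min_base_quality``.
    """
    if isinstance(pileup, PileupMatrix):
        if pileup.min_base_quality < min_base_quality:
            raise ValueError(
                f"pileup matrix filtered at Q{pileup.min_base_quality}, "
                f"cannot honour min_base_quality={min_base_quality}"
            )
        depth = pileup.depth()
        snvs: list[SNV] = []
        # only columns that can possibly yield a call need inspection
        nonref = pileup.counts.sum(axis=0)
        for pos in np.nonzero(depth >= min_coverage)[0]:
            ref = pileup.ref_seq[pos]
            col = pileup.counts[:, pos]
            if ref in _BASE_INDEX and int(col[_BASE_INDEX[ref]]) == int(nonref[pos]):
                continue  # all observations are reference
            snvs.extend(
                _call_column(ref, col, int(pos), min_coverage, min_frequency, min_support)
            )
        return snvs

    snvs = []
    last = -1
    for col in pileup:
        if col.position <= last:
            raise ValueError(f"pileup columns not sorted at position {col.position}")
        last = col.position
        counts4 = [0, 0, 0, 0]
        for base, qual in col.observations:
            base = normalize_dna(base)
            if qual >= min_base_quality and base in _BASE_INDEX:
                counts4[_BASE_INDEX[base]] += 1
        snvs.extend(
            _call_column(
                normalize_dna(col.ref_base), counts4, col.position,
                min_coverage, min_frequency, min_support,
            )
        )
    return snvs


INTERGENIC = "intergenic"


@dataclass(frozen=True)
class AnnotatedSNV:
    """An SNV with its gene context (gene_id None ⇒ intergenic)."""

    snv: SNV
    gene_id: str | None
    effect: SubstitutionEffect | None
    overlapping: bool = False  # set when the SNV hits >1 gene and multiple records are emitted

    @property
    def is_intergenic(self) -> bool:
        return self.gene_id is None


def annotate_snvs(
    snvs: Iterable[SNV],
    genes: Sequence[GeneModel],
    genome: Genome | str,
    code: GeneticCode | None = None,
) -> list[AnnotatedSNV]:
    """Map each SNV to a codon-level effect in its containing gene.

    Minus-strand genes are handled by classifying on the reverse-complemented
    CDS with complemented alleles. SNVs hitting more than one gene produce
    one flagged record per gene; intergenic SNVs get ``gene_id=None``.

    Raises
    ------
    ValueError
        If an SNV's reference base disagrees with the genome sequence.
    """
    seq = genome.seq if isinstance(genome, Genome) else normalize_dna(genome)
    out: list[AnnotatedSNV] = []
    for snv in snvs:
        if seq[snv.position] != snv.ref_base:
            raise ValueError(
                f"reference mismatch at position {snv.position}: "
                f"SNV says {snv.ref_base}, genome has {seq[snv.position]}"
            )
        hits = [g for g in genes if g.contains(snv.position)]
        if not hits:
            out.append(AnnotatedSNV(snv, None, None))
            continue
        flagged = len(hits) > 1
        for gene in hits:
            gene_code = code if code is not None else get_code(gene.transl_table)
            cds = gene.cds_sequence(seq)
            offset = gene.genomic_to_cds(snv.position)
            alt = snv.alt_base if gene.strand == "+" else reverse_complement(snv.alt_base)
            effect = classify_substitution(cds, offset, alt, gene_code)
            out.append(AnnotatedSNV(snv, gene.gene_id, effect, overlapping=flagged))
    return out


@dataclass
class GeneVariantSummary:
    """Per-gene synonymous / nonsynonymous substitution counts."""

    gene_id: str
    n_syn: int = 0
    n_nonsyn: int = 0
    n_indeterminate: int = 0

    @property
    def n_classified(self) -> int:
        return self.n_syn + self.n_nonsyn

    @property
    def syn_proportion(self) -> float:
        """n_syn / (n_syn + n_nonsyn); NaN when no classifiable SNV."""
        if self.n_classified == 0:
            return math.nan
        return self.n_syn / self.n_classified


def summarize_by_gene(
    annotated: Iterable[AnnotatedSNV], genes: Sequence[GeneModel]
) -> list[GeneVariantSummary]:
    """One summary per gene, ranked by synonymous proportion.

    Ranking is by syn_proportion descending, ties broken by n_syn then
    gene id; genes with no classifiable SNV rank last (proportion NaN).
    Stop gains/losses count as nonsynonymous (the amino-acid sequence
    changes); indeterminate effects are tallied but excluded from the
    proportion denominator.
    """
    table = {g.gene_id: GeneVariantSummary(g.gene_id) for g in genes}
    for ann in annotated:
        if ann.gene_id is None:
            continue
        s = table[ann.gene_id]
        if ann.effect.category == "synonymous":
            s.n_syn += 1
        elif ann.effect.category in (INDETERMINATE, "stop_retained"):
            # neither changes the protein nor counts as a silent coding change
            s.n_indeterminate += 1
        else:
            s.n_nonsyn += 1
    return sorted(
        table.values(),
        key=lambda s: (
            0 if s.n_classified else 1,  # defined proportions first
            -(s.syn_proportion if s.n_classified else 0.0),
            -s.n_syn,
            s.gene_id,
        ),
    )
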