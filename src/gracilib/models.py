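"""Shared genome / gene-model containers.

Coordinates are 0-based half-open internally everywhere in this package;
conversion to the 1-based inclusive convention of GFF3/VCF happens only in
:mod:`gracilib.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gencode import get_code, normalize_dna, reverse_complement, translate_cds


@dataclass
class GeneModel:
    """A CDS on a (possibly circular) genome.

    ``start``/``end`` are 0-based half-open genomic coordinates; genes do not
    wrap the origin. ``transl_table`` selects the genetic code (25 for
    Gracilibacteria-style UGA→Gly coding).
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    transl_table: int = 11

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def cds_sequence(self, genome_seq: str) -> str:
        """Coding-strand sequence of the gene (reverse-complemented for −)."""
        sub = normalize_dna(genome_seq[self.start : self.end])
        return reverse_complement(sub) if self.strand == "-" else sub

    def genomic_to_cds(self, position: int) -> int:
        """Map a genomic coordinate to the 0-based offset within the CDS."""
        if not self.contains(position):
            raise ValueError(f"position {position} outside gene {self.gene_id}")
        if self.strand == "+":
            return position - self.start
        return self.end - 1 - position


@dataclass
class Genome:
    """A nucleotide sequence plus its gene models."""

    seq: str
    genes: list[GeneModel] = field(default_factory=list)
    id: str = "genome"
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = normalize_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        s = self.seq
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence with circular wrap-around when ``end`` exceeds length."""
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError(f"[{start}, {end}) beyond linear sequence of length {n}")
        return self.seq[start:] + self.seq[: end - n]

    def translations(self) -> dict[str, str]:
        """Translate every gene under its own table."""
        out = {}
        for g in self.genes:
            out[g.gene_id] = translate_cds(g.cds_sequence(self.seq), get_code(g.transl_table))
        return out
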