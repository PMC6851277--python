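"""Readers/writers for the standard formats and the run configuration.

All internal coordinates in this package are 0-based half-open; GFF3 and
VCF are 1-based inclusive. The conversion lives here, in two tiny functions
used by every exporter, so that it cannot drift between formats.

FASTA/FASTQ go through Biopython's SeqIO. The GFF3 and VCF support covers
the subset this pipeline emits (CDS features with a transl_table attribute;
SNVs with DP/AF/EFF INFO fields) and fails loudly, with line numbers, on
anything malformed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Genome
from .variants import SNV, AnnotatedSNV, GeneVariantSummary


# --- coordinate conventions -------------------------------------------------

def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open → 1-based inclusive (GFF3/VCF convention)."""
    return start + 1, end


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive → 0-based half-open."""
    return start1 - 1, end1


# --- FASTA / FASTQ ----------------------------------------------------------

def write_fasta(sequences: dict[str, str] | Genome, path) -> None:
    if isinstance(sequences, Genome):
        sequences = {sequences.id: sequences.seq}
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(pairs, path1, path2, quality: int = 37) -> None:
    """Write mate files (ids suffixed /1 and /2), uniform quality."""
    def recs(which):
        for p in pairs:
            seq = p.r1 if which == 1 else p.r2
            r = SeqRecord(Seq(seq), id=f"{p.pair_id}/{which}", description="")
            r.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield r

    SeqIO.write(recs(1), str(path1), "fastq")
    SeqIO.write(recs(2), str(path2), "fastq")


def read_fastq_pairs(path1, path2):
    """Read mate files back into ReadPair objects (paired by /1 /2 suffix)."""
    from .repeats import ReadPair

    r1 = {rec.id.rsplit("/", 1)[0]: str(rec.seq) for rec in SeqIO.parse(str(path1), "fastq")}
    r2 = {rec.id.rsplit("/", 1)[0]: str(rec.seq) for rec in SeqIO.parse(str(path2), "fastq")}
    if set(r1) != set(r2):
        raise ValueError("mate files do not pair up")
    return [ReadPair(pid, r1[pid], r2[pid]) for pid in sorted(r1)]


# --- GFF3 -------------------------------------------------------------------

def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.seq)}\n")
        for g in sorted(genome.genes, key=lambda g: g.start):
            start1, end1 = to_one_based(g.start, g.end)
            attrs = f"ID={g.gene_id};transl_table={g.transl_table}"
            fh.write(
                f"{genome.id}\tgracilib\tCDS\t{start1}\t{end1}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    """Parse CDS records; the transl_table attribute selects the genetic code."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            _, _, ftype, start1, end1, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            try:
                start, end = to_zero_based(int(start1), int(end1))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: CDS record lacks an ID attribute")
            genes.append(
                GeneModel(gene_id, start, end, strand, int(attr_map.get("transl_table", 11)))
            )
    return genes


# --- VCF --------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=EFF,Number=.,Type=String,Description="gene|category|ref_aa|alt_aa|codon_index|codon_position, or intergenic">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(annotated: Sequence[AnnotatedSNV], chrom: str, path) -> None:
    by_pos: dict[int, list[AnnotatedSNV]] = {}
    for ann in annotated:
        by_pos.setdefault(ann.snv.position, []).append(ann)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.replace("#CHROM", f"##contig=<ID={chrom}>\n#CHROM", 1))
        for pos in sorted(by_pos):
            # one row per distinct alt at the site
            by_alt: dict[str, list[AnnotatedSNV]] = {}
            for ann in by_pos[pos]:
                by_alt.setdefault(ann.snv.alt_base, []).append(ann)
            for alt, group in sorted(by_alt.items()):
                snv = group[0].snv
                effs = []
                for ann in group:
                    if ann.is_intergenic:
                        effs.append("intergenic")
                    else:
                        e = ann.effect
                        effs.append(
                            f"{ann.gene_id}|{e.category}|{e.ref_aa}|{e.alt_aa}"
                            f"|{e.codon_index}|{e.codon_position}"
                        )
                info = f"DP={snv.depth};AF={snv.frequency:.6g};EFF={','.join(effs)}"
                fh.write(
                    f"{chrom}\t{pos + 1}\t.\t{snv.ref_base}\t{alt}\t.\tPASS\t{info}\n"
                )


def read_vcf(path) -> list[SNV]:
    """Re-parse a VCF written by :func:`write_vcf` back into SNVs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected ≥8 VCF columns")
            _, pos1, _, ref, alt, _, _, info = parts[:8]
            kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
            try:
                depth = int(kv["DP"])
                af = float(kv["AF"])
            except KeyError as e:
                raise ValueError(f"{path}:{lineno}: missing INFO field {e}") from None
            out.append(
                SNV(int(pos1) - 1, ref, alt, depth, int(round(af * depth)))
            )
    return out


# --- pileup TSV dialect -----------------------------------------------------

def write_pileup_tsv(columns, path) -> None:
    """position <TAB> ref <TAB> base:qual,base:qual,... (1-based positions)."""
    with open(path, "w") as fh:
        for col in columns:
            obs = ",".join(f"{b}:{q}" for b, q in col.observations)
            fh.write(f"{col.position + 1}\t{col.ref_base}\t{obs}\n")


def read_pileup_tsv(path):
    from .variants import PileupColumn

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 pileup columns")
            pos1, ref, obs_s = parts
            try:
                obs = [
                    (b, int(q))
                    for b, q in (item.split(":") for item in obs_s.split(",") if item)
                ]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed base:quality pair") from None
            out.append(PileupColumn(int(pos1) - 1, ref, obs))
    return out


# --- TSV reports ------------------------------------------------------------

def write_gene_summary_tsv(summaries: Sequence[GeneVariantSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_syn\tn_nonsyn\tn_indeterminate\tsyn_proportion\n")
        for s in summaries:
            prop = "NA" if s.n_classified == 0 else f"{s.syn_proportion:.4f}"
            fh.write(f"{s.gene_id}\t{s.n_syn}\t{s.n_nonsyn}\t{s.n_indeterminate}\t{prop}\n")


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline parameters; round-trips losslessly through a key=value file."""

    min_coverage: int = 10
    min_base_quality: int = 30
    min_frequency: float = 0.05
    min_support: int = 2
    transl_table: int = 25
    skew_window: int = 1000
    skew_step: int = 1000
    seed: int = 0
    output_dir: str = "gracilib_out"

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.min_support < 1:
            raise ValueError("coverage/support thresholds must be ≥ 1")
        if not 0.0 < self.min_frequency <= 1.0:
            raise ValueError("min_frequency must be in (0, 1]")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be ≥ 0")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                k, v = line.split("=", 1)
                if k not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {k!r}")
                kwargs[k] = casts[types[k]](v)
        return cls(**kwargs)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
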