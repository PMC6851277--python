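"""Translation tables and substitution-effect classification.

Gracilibacteria (BD1-5) and other members of the candidate phyla radiation
use NCBI translation table 25, in which the UGA stop codon is reassigned to
glycine. Everything downstream of variant calling in this package — calling
a substitution synonymous or nonsynonymous, checking that simulated genes
are stop-free, decomposing a repeat array into tripeptide-coding units —
depends on translating codons under the correct table, so the tables live
here as first-class objects.

Codons are handled in the DNA alphabet throughout (``TGA``, not ``UGA``);
RNA input is normalized U→T on entry. A codon containing ``N`` translates
to ``X`` and classifies as ``indeterminate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator

STOP = "*"
UNKNOWN_AA = "X"

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def normalize_dna(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table.

    Attributes
    ----------
    id : int
        NCBI translation table identifier (11 = bacterial, 25 = candidate
        division SR1 / Gracilibacteria with TGA→G).
    mapping : dict
        codon (DNA 3-mer) → one-letter amino acid, or ``"*"`` for stop.
    start_codons : frozenset
        Codons usable as initiators under this table.
    """

    id: int
    mapping: dict[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ValueError(f"codon table must have 64 entries, got {len(self.mapping)}")
        bad = {aa for aa in self.mapping.values() if aa != STOP and aa not in _AA20}
        if bad:
            raise ValueError(f"non-standard amino acid symbols in table: {bad}")

    def translate_codon(self, codon: str) -> str:
        """One codon → one symbol; N anywhere in the codon yields X."""
        codon = normalize_dna(codon)
        if len(codon) != 3:
            raise ValueError(f"codon must be a 3-mer, got {codon!r}")
        if "N" in codon:
            return UNKNOWN_AA
        try:
            return self.mapping[codon]
        except KeyError:
            raise ValueError(f"codon {codon!r} is not over ACGT") from None

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.mapping.items() if aa == STOP)

    def to_tsv(self, path) -> None:
        """Serialize as a two-column (codon, symbol) TSV for inspection."""
        with open(path, "w") as fh:
            fh.write("codon\taa\n")
            for codon in sorted(self.mapping):
                fh.write(f"{codon}\t{self.mapping[codon]}\n")


def _load_table(table_id: int) -> GeneticCode:
    name = f"code{table_id}.tsv"
    mapping: dict[str, str] = {}
    starts: set[str] = set()
    ref = resources.files("gracilib.data").joinpath(name)
    for line in ref.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("codon"):
            continue
        codon, aa, is_start = line.split("\t")
        mapping[codon] = aa
        if is_start == "1":
            starts.add(codon)
    return GeneticCode(id=table_id, mapping=mapping, start_codons=frozenset(starts))


_KNOWN_TABLES = (11, 25)


@lru_cache(maxsize=None)
def get_code(table_id: int) -> GeneticCode:
    """Return a built-in translation table (11 or 25).

    Raises
    ------
    ValueError
        If ``table_id`` is not a known table.
    """
    if table_id not in _KNOWN_TABLES:
        raise ValueError(f"unknown translation table: {table_id}")
    return _load_table(table_id)


def iter_codons(cds: str) -> Iterator[str]:
    cds = normalize_dna(cds)
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    for i in range(0, len(cds), 3):
        yield cds[i : i + 3]


def translate_cds(cds: str, code: GeneticCode) -> str:
    """Translate a coding sequence; stops appear as ``*`` in the output.

    Internal stops are reported in the returned string rather than raised,
    so callers (e.g. the synthetic-genome validator) can locate them.
    """
    return "".join(code.translate_codon(c) for c in iter_codons(cds))


#: substitution-effect categories
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAIN = "stop_gain"
STOP_LOSS = "stop_loss"
STOP_RETAINED = "stop_retained"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class SubstitutionEffect:
    """Codon-level effect of a single-base substitution within a CDS."""

    category: str
    ref_aa: str
    alt_aa: str
    codon_index: int  # ordinal of the affected codon within the CDS, 0-based
    codon_position: int  # 1..3
    ref_codon: str
    alt_codon: str

    @property
    def is_synonymous(self) -> bool:
        return self.category == SYNONYMOUS


def _categorize(ref_aa: str, alt_aa: str) -> str:
    if UNKNOWN_AA in (ref_aa, alt_aa):
        return INDETERMINATE
    if ref_aa == STOP and alt_aa == STOP:
        return STOP_RETAINED
    if ref_aa == STOP:
        return STOP_LOSS
    if alt_aa == STOP:
        return STOP_GAIN
    if ref_aa == alt_aa:
        return SYNONYMOUS
    return NONSYNONYMOUS


def classify_substitution(
    cds: str, cds_offset: int, alt_base: str, code: GeneticCode
) -> SubstitutionEffect:
    """Classify the effect of substituting ``alt_base`` at ``cds_offset``.

    The offset is 0-based within the (forward, in-frame) coding sequence.
    For genes on the minus strand, map the genomic variant through the
    strand first (see :func:`gracilib.variants.annotate_snvs`).
    """
    cds = normalize_dna(cds)
    alt_base = normalize_dna(alt_base)
    if not 0 <= cds_offset < len(cds):
        raise ValueError(f"offset {cds_offset} outside CDS of length {len(cds)}")
    if alt_base not in "ACGTN" or len(alt_base) != 1:
        raise ValueError(f"invalid alternate base {alt_base!r}")
    ref_base = cds[cds_offset]
    if alt_base == ref_base:
        raise ValueError(f"alternate base equals reference ({ref_base}) at offset {cds_offset}")
    codon_index = cds_offset // 3
    codon_position = cds_offset % 3 + 1
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    if len(ref_codon) != 3:
        raise ValueError("offset falls in a trailing partial codon")
    alt_codon = ref_codon[: codon_position - 1] + alt_base + ref_codon[codon_position:]
    ref_aa = code.translate_codon(ref_codon)
    alt_aa = code.translate_codon(alt_codon)
    return SubstitutionEffect(
        category=_categorize(ref_aa, alt_aa),
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
    )
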