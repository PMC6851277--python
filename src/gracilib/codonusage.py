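"""Codon-incidence profiling, gene-vs-genome enrichment, and tRNA wobble pairing.

Incidence is expressed as codons per 100 codons of input, so values for the
synonymous codons of one amino acid sum to that amino acid's frequency per
100 residues. Comparing a single gene's profile against the pooled profile
of all genes exposes codon-level selection — e.g. a tandem-repeat gene that
uses one proline codon almost exclusively while the genome spreads usage
over all four.

Wobble compatibility follows the standard pairing rules at the anticodon
5′ (position 34) base: G reads C/U, C reads G, U reads A/G, A reads U, and
inosine reads U/C/A. Anticodons are given 5′→3′ in RNA alphabet, so the
wobble base is the first character and pairs with the codon's third base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

from .gencode import GeneticCode, iter_codons, normalize_dna

ALL_CODONS = ["".join(p) for p in product("ACGT", repeat=3)]

#: anticodon position-34 base → codon third-position bases it can read (RNA)
WOBBLE_RULES: Mapping[str, frozenset[str]] = {
    "G": frozenset("CU"),
    "C": frozenset("G"),
    "U": frozenset("AG"),
    "A": frozenset("U"),
    "I": frozenset("UCA"),
}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class CodonUsageProfile:
    """Codon incidence per 100 codons, over one or more pooled CDSs."""

    incidence: Mapping[str, float]
    n_codons: int

    def __post_init__(self) -> None:
        total = sum(self.incidence.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"incidences must sum to 100, got {total}")

    def __getitem__(self, codon: str) -> float:
        return self.incidence.get(normalize_dna(codon), 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"codon": ALL_CODONS, "incidence": [self.incidence.get(c, 0.0) for c in ALL_CODONS]}
        )


def codon_incidence(
    cds_set: Iterable[str] | str, code: GeneticCode | None = None
) -> CodonUsageProfile:
    """Pooled codon counts over all input CDSs, scaled to per-100-codons.

    Pooling is length-weighted: a long gene contributes proportionally more
    codons than a short one. ``code`` is accepted for interface symmetry
    with the enrichment report but does not affect counting.
    """
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    counts: Counter[str] = Counter()
    for cds in cds_set:
        for codon in iter_codons(cds):
            if "N" not in codon:
                counts[codon] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no codons in input")
    return CodonUsageProfile(
        incidence={c: 100.0 * k / n for c, k in counts.items()}, n_codons=n
    )


def mean_gene_incidence(cds_set: Iterable[str]) -> CodonUsageProfile:
    """Unweighted per-gene mean profile (each gene contributes equally).

    The alternative reading of "average codon usage of all genes"; the
    pooled, length-weighted :func:`codon_incidence` is the default
    genome-wide expectation.
    """
    profiles = [codon_incidence(cds) for cds in cds_set]
    if not profiles:
        raise ValueError("no genes in input")
    inc = {
        c: sum(p.incidence.get(c, 0.0) for p in profiles) / len(profiles) for c in ALL_CODONS
    }
    # renormalize away float drift so the profile invariant holds exactly
    total = sum(inc.values())
    inc = {c: 100.0 * v / total for c, v in inc.items()}
    return CodonUsageProfile(incidence=inc, n_codons=sum(p.n_codons for p in profiles))


def enrichment(
    gene_profile: CodonUsageProfile,
    genome_profile: CodonUsageProfile,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-codon fold-change of a gene's usage over the genome-wide profile.

    Returns a 64-row frame with columns codon, gene_incidence,
    genome_incidence, fold and flag; fold is gene/genome, ``inf`` (flagged
    ``gene_only``) when the codon is absent genome-wide but present in the
    gene, 0 when absent from the gene (flagged ``absent`` if absent from
    both). When a genetic code is supplied, within-amino-acid synonymous
    codon shares are added for both profiles.
    """
    rows = []
    for codon in ALL_CODONS:
        g = gene_profile[codon]
        w = genome_profile[codon]
        if w > 0:
            fold = g / w
            flag = "absent" if (g == 0 and w == 0) else ""
        elif g > 0:
            fold = float("inf")
            flag = "gene_only"
        else:
            fold = 0.0
            flag = "absent"
        rows.append({"codon": codon, "gene_incidence": g, "genome_incidence": w,
                     "fold": fold, "flag": flag})
    df = pd.DataFrame(rows)
    if code is not None:
        df["aa"] = [code.translate_codon(c) for c in df["codon"]]
        for col, src in (("gene_share", "gene_incidence"), ("genome_share", "genome_incidence")):
            aa_tot = df.groupby("aa")[src].transform("sum")
            df[col] = (df[src] / aa_tot).where(aa_tot > 0, 0.0)
    return df


def _check_triplet(seq: str, name: str, alphabet: str) -> str:
    if len(seq) != 3 or any(b not in alphabet for b in seq):
        raise ValueError(f"malformed {name}: {seq!r}")
    return seq


def wobble_compatible(codon: str, anticodon: str) -> bool:
    """True iff the anticodon can decode the codon.

    Codon positions 1–2 must pair Watson–Crick with anticodon positions
    3–2; the codon third base must be admitted by the wobble rule for the
    anticodon's 5′ base. Inosine (``I``) is allowed at the wobble position
    only.
    """
    codon = normalize_dna(codon).replace("T", "U")
    _check_triplet(codon, "codon", "ACGU")
    anticodon = anticodon.upper().replace("T", "U")
    if len(anticodon) != 3:
        raise ValueError(f"malformed anticodon: {anticodon!r}")
    if any(b not in "ACGU" for b in anticodon[1:]) or anticodon[0] not in "ACGUI":
        raise ValueError(f"malformed anticodon: {anticodon!r}")
    if (codon[0], anticodon[2]) not in _WC_PAIRS:
        return False
    if (codon[1], anticodon[1]) not in _WC_PAIRS:
        return False
    return codon[2] in WOBBLE_RULES[anticodon[0]]


def codons_read_by(anticodon: str) -> set[str]:
    """All codons (RNA alphabet) the anticodon can decode."""
    out = set()
    for third in "ACGU":
        for first in "ACGU":
            for second in "ACGU":
                codon = first + second + third
                if wobble_compatible(codon, anticodon):
                    out.add(codon)
    return out
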