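"""Perfect-stem DNA hairpin detection and nearest-neighbor folding energy.

A hairpin (stem-loop) is a self-complementary region folding back on
itself: a double-stranded stem of Watson–Crick pairs closed by an unpaired
loop of ≥ 3 nt. Hairpins in the untranslated flanks of a gene are candidate
recombination or transcription-regulation signals, and unusually long
perfect stems (≥ 14 bp) are rare enough to be noteworthy.

Stability is scored as the folding free energy ΔG (kcal/mol): the sum of
unified DNA nearest-neighbor stacking terms over the stem plus a hairpin
loop initiation penalty, evaluated at a stated temperature (default 37 °C).
Stack enthalpies/entropies and the loop penalty table ship as data files
(SantaLucia 1998; SantaLucia & Hicks 2004). More negative ΔG = more stable.
Terminal mismatch and salt corrections are not applied, which is why
computed values can differ from a full folding program by ~1 kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .gencode import normalize_dna, reverse_complement
from .models import GeneModel, Genome

_R = 1.987204e-3  # kcal/(mol K)
_T37 = 310.15


def _load_nn_params() -> dict[str, tuple[float, float]]:
    params: dict[str, tuple[float, float]] = {}
    text = resources.files("gracilib.data").joinpath("dna_nn_params.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("stack"):
            continue
        stack, dh, ds = line.split("\t")
        params[stack] = (float(dh), float(ds))
        params[reverse_complement(stack)] = (float(dh), float(ds))
    return params


def _load_loop_table() -> dict[int, float]:
    table: dict[int, float] = {}
    text = resources.files("gracilib.data").joinpath("dna_hairpin_loops.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("loop_size"):
            continue
        n, dg = line.split("\t")
        table[int(n)] = float(dg)
    return table


_NN = _load_nn_params()
_LOOPS = _load_loop_table()


def hairpin_loop_dg37(loop_length: int) -> float:
    """Hairpin loop initiation ΔG°37 (kcal/mol), interpolated/extrapolated."""
    if loop_length < 3:
        raise ValueError("hairpin loops shorter than 3 nt are sterically impossible")
    if loop_length in _LOOPS:
        return _LOOPS[loop_length]
    sizes = sorted(_LOOPS)
    if loop_length > sizes[-1]:  # Jacobson-Stockmayer extrapolation
        return _LOOPS[sizes[-1]] + 1.75 * _R * _T37 * math.log(loop_length / sizes[-1])
    lo = max(s for s in sizes if s < loop_length)
    hi = min(s for s in sizes if s > loop_length)
    frac = (loop_length - lo) / (hi - lo)
    return _LOOPS[lo] + frac * (_LOOPS[hi] - _LOOPS[lo])


@dataclass(frozen=True)
class Hairpin:
    """A perfect-stem hairpin within an input sequence (0-based half-open span)."""

    start: int
    end: int
    stem_length: int
    loop_length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.loop_length < 3:
            raise ValueError("loop_length must be ≥ 3")
        if self.end - self.start != 2 * self.stem_length + self.loop_length:
            raise ValueError("span inconsistent with stem and loop lengths")
        stem5 = self.sequence[: self.stem_length]
        stem3 = self.sequence[-self.stem_length:]
        if stem5 != reverse_complement(stem3):
            raise ValueError("stem arms are not Watson-Crick complementary")

    @property
    def structure(self) -> str:
        """Dot-bracket string over the hairpin span."""
        return "(" * self.stem_length + "." * self.loop_length + ")" * self.stem_length

    @property
    def stem5(self) -> str:
        return self.sequence[: self.stem_length]


def find_hairpin(
    sequence: str, min_stem: int = 8, min_loop: int = 3, max_loop: int = 12
) -> Hairpin | None:
    """Best perfect-Watson-Crick hairpin in ``sequence``, or None.

    Maximizes stem length; ties go to the smallest loop, then the leftmost
    position. Only perfect stems count (a single mismatch ends the stem).
    """
    seq = normalize_dna(sequence)
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must be over ACGT")
    n = len(seq)
    best: Hairpin | None = None
    for loop in range(min_loop, max_loop + 1):
        # loop occupies [i, i+loop); stem grows outwards from its edges
        for i in range(1, n - loop):
            stem = 0
            left, right = i - 1, i + loop
            while left >= 0 and right < n and seq[left] == reverse_complement(seq[right]):
                stem += 1
                left -= 1
                right += 1
            if stem < min_stem:
                continue
            cand = Hairpin(
                start=left + 1,
                end=right,
                stem_length=stem,
                loop_length=loop,
                sequence=seq[left + 1 : right],
            )
            if (
                best is None
                or cand.stem_length > best.stem_length
                or (cand.stem_length == best.stem_length and cand.loop_length < best.loop_length)
                or (
                    cand.stem_length == best.stem_length
                    and cand.loop_length == best.loop_length
                    and cand.start < best.start
                )
            ):
                best = cand
    return best


def find_hairpins(
    sequence: str, min_stem: int = 8, min_loop: int = 3, max_loop: int = 12
) -> list[Hairpin]:
    """All non-overlapping hairpins, greedily best-first (for flank scans)."""
    seq = normalize_dna(sequence)
    out: list[Hairpin] = []
    masked_start = 0
    # greedy: take the best hairpin, blank its span, repeat on the remainder
    remaining = [(0, seq)]
    while remaining:
        offset, chunk = remaining.pop()
        if len(chunk) < 2 * min_stem + min_loop:
            continue
        hp = find_hairpin(chunk, min_stem=min_stem, min_loop=min_loop, max_loop=max_loop)
        if hp is None:
            continue
        out.append(
            Hairpin(hp.start + offset, hp.end + offset, hp.stem_length, hp.loop_length,
                    hp.sequence)
        )
        remaining.append((offset, chunk[: hp.start]))
        remaining.append((offset + hp.end, chunk[hp.end :]))
    return sorted(out, key=lambda h: h.start)


def stack_dg(dinucleotide: str, temperature: float = 37.0) -> float:
    """ΔG of one nearest-neighbor stack (5'→3' top strand) at ``temperature`` °C."""
    d = normalize_dna(dinucleotide)
    if d not in _NN:
        raise ValueError(f"unknown dinucleotide stack {dinucleotide!r}")
    dh, ds = _NN[d]
    return dh - (temperature + 273.15) * ds / 1000.0


def hairpin_delta_g(hairpin: Hairpin, temperature: float = 37.0) -> float:
    """Folding free energy of a hairpin, kcal/mol.

    Sum of nearest-neighbor stack terms over the stem plus the hairpin-loop
    initiation penalty. The loop penalty is treated as purely entropic and
    scaled linearly in absolute temperature from its 37 °C value.
    """
    t_kelvin = temperature + 273.15
    dg = 0.0
    stem = hairpin.stem5
    for i in range(hairpin.stem_length - 1):
        dg += stack_dg(stem[i : i + 2], temperature)
    dg += hairpin_loop_dg37(hairpin.loop_length) * t_kelvin / _T37
    return dg


@dataclass(frozen=True)
class FlankHairpin:
    """A hairpin in a gene flank, with offsets relative to the gene end.

    ``flank`` is ``"5p"`` (upstream of the start, in gene orientation) or
    ``"3p"`` (downstream of the stop). Offsets are distances from the gene
    boundary to the hairpin span: for the 3′ flank, offset_start = 5 means
    the hairpin begins 5 bp after the stop codon; for the 5′ flank, offsets
    count upstream from the start codon.
    """

    flank: str
    offset_start: int
    offset_end: int
    hairpin: Hairpin


def scan_gene_flanks(
    genome: Genome,
    gene: GeneModel,
    flank_window: int = 200,
    min_stem: int = 8,
    min_loop: int = 3,
    max_loop: int = 12,
) -> list[FlankHairpin]:
    """Detect hairpins in the two UTR-side windows flanking a gene.

    Flanks are taken in gene orientation (the 5′ flank of a minus-strand
    gene lies genomically downstream and is reverse-complemented), so a
    gene and its reverse-complement fixture report identically. On a linear
    sequence a flank running off the contig is truncated with a warning.
    """
    import warnings

    n = len(genome.seq)
    results: list[FlankHairpin] = []
    for flank in ("5p", "3p"):
        upstream = (flank == "5p") == (gene.strand == "+")
        if upstream:
            lo, hi = gene.start - flank_window, gene.start
        else:
            lo, hi = gene.end, gene.end + flank_window
        if genome.circular:
            seq = genome.fetch(lo % n, lo % n + (hi - lo))
        else:
            clo, chi = max(lo, 0), min(hi, n)
            if (clo, chi) != (lo, hi):
                warnings.warn(f"{flank} flank of {gene.gene_id} truncated at contig edge")
            lo, hi = clo, chi
            seq = genome.seq[lo:hi]
        if gene.strand == "-":
            seq = reverse_complement(seq)
        for hp in find_hairpins(seq, min_stem=min_stem, min_loop=min_loop, max_loop=max_loop):
            width = len(seq)
            if flank == "3p":
                results.append(FlankHairpin("3p", hp.start, hp.end, hp))
            else:
                results.append(FlankHairpin("5p", -(width - hp.start), -(width - hp.end), hp))
    return results
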