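# Methods

This note documents the models and procedures gracilib implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Genetic codes and substitution effects

Translation tables 11 (bacterial) and 25 (Gracilibacteria / candidate
division SR1; TGA→Gly) ship as TSV data files and are the single source of
truth at runtime; the test suite cross-checks them against Biopython's NCBI
tables. Codons are handled in DNA alphabet throughout — RNA input is
normalized U→T on entry — because every file format the package touches is
DNA.

A substitution is classified by translating the affected codon before and
after the change: `synonymous` (same amino acid, neither a stop),
`nonsynonymous`, `stop_gain`, `stop_loss`, plus two categories outside the
classical four: `stop_retained` for stop→stop changes (e.g. TAA→TAG) and
`indeterminate` when the codon contains an ambiguous base (N). Neither of
the extra categories enters the synonymous-proportion denominator:
stop-retained changes do not alter the protein but are not silent *coding*
changes either, and how ambiguous bases were treated in comparable studies
is generally unstated, so they are tallied separately and excluded. Genes
on the minus strand are classified on the reverse-complemented CDS with
complemented alleles.

Partial or frameshifted genes are unsupported, and no evolutionary-rate
normalization (dN/dS with site counts) is applied — the per-gene statistic
is the raw count ratio n_syn/(n_syn+n_nonsyn).

## Variant calling

The caller reproduces classic threshold-based pileup calling: defaults are
minimum coverage 10, minimum base quality 30, minimum allele frequency
0.05 — the *c*/*q*/*fr* convention of such callers — plus a minimum of two
supporting reads, so that a variant seen on a single read is never
reported. Depth is quality-filtered depth: a base below Q30 contributes
neither to coverage nor to allele counts, matching how such callers define
the frequency denominator. Each non-reference allele at a column is
evaluated independently. Calls are monotone in all three thresholds
(property-tested).

Two pileup representations exist: per-column `PileupColumn` lists (the
reference implementation and the TSV interchange form) and a numpy-backed
`PileupMatrix` of quality-filtered base counts used for genome-scale
simulations. Both feed the same per-column decision rule and the test
suite asserts their calls are identical on shared inputs. Indel calling,
realignment and strand-bias statistics are out of scope.

## Codon usage and wobble pairing

Codon incidence is reported **per 100 codons**, so the values for one
amino acid's synonymous codons sum to that amino acid's frequency per 100
residues. The genome-wide expectation is the pooled (length-weighted)
profile over all CDSs; an unweighted per-gene mean (`mean_gene_incidence`)
is also provided since "average codon usage of all genes" admits both
readings. Enrichment is the per-codon ratio gene/genome, with infinity
flagged when a codon is absent genome-wide and zero when absent from the
gene; within-amino-acid codon shares are reported alongside.

Wobble compatibility requires Watson–Crick pairing at codon positions 1–2
(against anticodon positions 3–2) and applies the standard position-34
rules at the third position: G reads C/U, C reads G, U reads A/G, A reads
U, inosine reads U/C/A. Anticodons are accepted 5′→3′ in RNA alphabet with
inosine allowed at the wobble position only. tRNA gene finding and
RSCU/CAI indices are not implemented; the anticodon set is an input.

## Repeat locus reconstruction

`detect_unit_length` scans periods 3–50 by autocorrelation match fraction.
The fundamental unit is the smallest period attaining the maximal
fraction, except that a divisor of that period is preferred when the
divisor's own fraction reaches 0.6 — an array of two alternating 9-mers is
thereby reported as 9, not 18. Below 0.6 everywhere, the sequence has no
tandem structure.

`reconstruct_locus` algorithmizes manual curation-by-read-repositioning.
It is a deterministic greedy layout: (1) reads overlapping a unique flank
by ≥ 15 exact bases anchor each side; (2) each side grows by the read
whose prefix matches the consensus suffix over ≥ 25 bases with zero
mismatches by default ("perfect read support"), candidates ranked by
insert-consistent mate placement (within mean ± 3 sd), fewest novel repeat
unit variants introduced, largest overlap, then lexicographic read id —
the overlap criterion sits before the lexicographic fallback because in a
near-perfect tandem a short period-shifted match can masquerade as support
for skipping repeat copies; (3) the two arms reconcile by maximal exact
overlap, else an N-gap sized from the depth-based length estimate is
emitted and flagged. Equal-evidence ties with different continuations set
a segment ambiguity flag rather than failing silently. Unit-count
uncertainty is reported as insert_sd / unit_length, reflecting that exact
repeat numbers are unknowable when the array exceeds the read span.

The locus length estimate is total locus-read bases divided by mean flank
depth, with uncertainty length/√(n_reads). Scaffold joining uses perfect
end overlaps ≥ 100 bp only; a scaffold whose own ends overlap is
circularized and trimmed once; conflicting joins are reported and none
applied; near-perfect (one-mismatch) overlaps are reported as diagnostics
but never joined. Joining considers forward orientations only — a known
limitation; reverse-complement joins require pre-orienting the scaffolds.

## GC skew

Windowed skew is (G−C)/(G+C) per window (default 1000/1000, configurable —
the published method this follows does not fix window sizes), with
circular wrap-around; a window with no G or C gets skew 0 and is flagged.
The cumulative value after window *i* is attained at that window's **end**,
so ori/ter are reported at `window_start + window` of the extremal
windows; reporting window starts would bias every call one window early.
Ori at the minimum / ter at the maximum is the convention for a
leading-strand G excess on the plus strand; both extrema and the fit
quality are always reported, so the opposite convention is recoverable.
The bidirectional-replication verdict requires the two-segment
piecewise-linear interpolant through the extrema to reach R² ≥ 0.9.

Note that reverse complementation leaves the cumulative curve's *values*
unchanged up to a constant (cum′(m) = cum(n−m−2) − total), so each
extremum keeps its role at the mirrored coordinate; window skews negate
and reverse. The tests encode this algebra.

## Stem-loops and folding energy

`find_hairpin` searches all loop sizes 3–12 and grows perfect
Watson–Crick stems outward, returning the hairpin maximizing stem length
(ties: smaller loop, then leftmost). G·T wobble pairs are not accepted in
stems by default. ΔG is the sum of unified DNA nearest-neighbor stack
terms over the stem plus a hairpin-loop initiation penalty, at 37 °C by
default; stacks carry ΔH/ΔS (SantaLucia 1998) so temperature matters,
and loop penalties (SantaLucia & Hicks 2004) are treated as purely
entropic and scaled linearly in absolute temperature, with linear
interpolation between tabulated sizes and a Jacobson–Stockmayer term
beyond 30 nt. Terminal mismatches, dangling ends and salt corrections are
deliberately omitted; against full folding programs this costs roughly
0.5–1 kcal/mol, which is why a ±1.5 kcal/mol tolerance is attached to any
comparison with externally computed values. Partition-function folding and
multiloop structures are out of scope.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:

- a circular genome at 29% G+C with non-overlapping, stop-free,
  alternating-strand genes under code 25;
- a replication-driven two-arm skew: between the planted origin (L/4) and
  terminus (3L/4) the plus strand draws G over C at amplitude 0.2
  (P(G|G-or-C) = 0.6), reversed on the other arm — applied at the genomic
  strand level, so minus-strand genes are drawn with the opposite bias and
  recover it on reverse complementation. Amplitude 0.2 is at the strong
  end of observed bacterial windowed skews; it gives a clean two-arm curve
  at the 20–50 kb scale the tests use;
- one in-frame tandem array (default 12 units of four 9-mer variants all
  coding Pro-Thr-Asp) planted at a codon boundary mid-gene in a
  plus-strand gene;
- population heterogeneity as K = 5 equal-weight haplotypes; each injected
  variant is a codon third-position change that preserves the amino acid
  under code 25, confined to the array by default, with its requested
  frequency rounded to the nearest achievable multiple of 1/K (both
  values recorded in the truth). The default of 17 variants mirrors the
  scale of heterogeneity such a locus shows;
- paired-end reads at 40× with 100 bp reads and 300 ± 30 bp inserts in FR
  orientation, uniform Q37, optional per-base substitution errors.

All randomness flows through one explicit seed per call; identical seeds
reproduce byte-identical output. Because the haplotypes differ from the
reference only by substitutions, read placements from the truth double as
alignments (`pileup_from_truth`); read mapping itself is outside the
package's scope, and the pipeline accepts externally produced pileups for
real data.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error profiles beyond uniform
substitutions, mapping ambiguity and soft-clipping, indels and
repeat-number (length) polymorphism of the array (off by default, matching
the observation that read length caps what is knowable), GC-dependent
coverage bias, and chimeric or contaminant reads.

## Problem sizes and determinism

The end-to-end recovery properties run at 20 kb / 8 genes / 40× over 20
seeds, and skew recovery at 50 kb over 20 seeds — sizes chosen so the full
suite completes in well under a minute while each dataset still contains
hundreds of read pairs through the locus and 50 skew windows. The
acceptance script's quantities are fully deterministic (discrete geometry
and closed-form thermodynamics); its `--seed` flag exists for interface
uniformity. Reports are written in stable orderings (gene id, then
position) so reruns are byte-identical.
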