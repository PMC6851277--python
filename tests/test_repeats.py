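"""Tandem unit detection, decomposition, locus reconstruction, scaffold joining."""

import numpy as np
import pytest

from gracilib import (
    ReadPair,
    decompose,
    detect_unit_length,
    estimate_locus_length,
    get_code,
    join_end_overlaps,
    reconstruct_locus,
    reverse_complement,
)


class TestUnitDetection:
    def test_exact_tandem(self):
        assert detect_unit_length("CCAACTGAT" * 8) == 9

    def test_alternating_units_report_fundamental_period(self):
        assert detect_unit_length(("CCAACTGAT" + "CCAACAGAT") * 4) == 9

    def test_random_sequence_has_no_tandem_structure(self):
        rng = np.random.default_rng(42)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        with pytest.raises(ValueError, match="no tandem structure"):
            detect_unit_length(seq)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_unit_length("ACGTAC")


class TestDecompose:
    def test_conserved_tripeptide_array(self, code25):
        seq = "CCAACTGAT" + "CCAACAGAT" + "CCTACAGAT" + "CCAACTGAT"
        dec = decompose(seq, 9, code25)
        assert dec.n_units == 4
        assert len(dec.units) == 3  # three distinct variants
        assert dec.order == ["U1", "U2", "U3", "U1"]
        assert all(u.translation == "PTD" for u in dec.units)
        assert dec.conserved

    def test_nonconserved_unit_reported(self, code25):
        seq = "CCAACTGAT" * 3 + "CCAACTAAT"  # last unit codes PTN
        dec = decompose(seq, 9, code25)
        assert not dec.conserved
        assert dec.offending == ["U2"]

    def test_single_unit(self, code25):
        dec = decompose("CCAACTGAT", 9, code25)
        assert dec.n_units == 1 and dec.units[0].count == 1

    def test_trailing_partial_unit_flagged(self, code25):
        dec = decompose("CCAACTGAT" * 2 + "CCAA", 9, code25)
        assert dec.partial_tail == "CCAA"
        assert dec.n_units == 2


class TestLengthEstimate:
    def test_arithmetic(self):
        est = estimate_locus_length(4200, 42, n_reads=42)
        assert est.length == pytest.approx(100.0)
        assert est.uncertainty == pytest.approx(100 / np.sqrt(42))

    def test_no_reads_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no locus-assigned reads"):
            est = estimate_locus_length(0, 42, n_reads=0)
        assert (est.length, est.uncertainty) == (0.0, 0.0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            estimate_locus_length(4200, 0, n_reads=10)


def _pairs_from_layout(locus: str, read_len: int, insert: int, step: int) -> list[ReadPair]:
    """Tile error-free FR read pairs across a linear sequence."""
    pairs = []
    i = 0
    for start in range(0, len(locus) - insert + 1, step):
        frag = locus[start : start + insert]
        pairs.append(
            ReadPair(f"p{i:04d}", frag[:read_len], reverse_complement(frag[-read_len:]))
        )
        i += 1
    return pairs


class TestReconstruct:
    LEFT = "ATGGCTGCATCAGGATCCTTAGCAAGCGTACGTTGGCAATGCTAGCATCGAT"
    RIGHT = "TTGGCCAATGGCCATTACGATCGATCGGCTAGCTAGGATCCAGTCAATGCAA"

    def test_spanning_read_recovers_exactly(self, code25):
        locus = self.LEFT + "CCAACTGAT" * 3 + self.RIGHT
        pairs = _pairs_from_layout(locus, read_len=90, insert=min(131, len(locus)), step=4)
        model, placements = reconstruct_locus(
            pairs, self.LEFT, self.RIGHT, insert_mean=131, insert_sd=10,
            unit_length=9, code=code25,
        )
        assert model.interior == "CCAACTGAT" * 3
        assert not model.is_ambiguous
        assert model.decomposition.order == ["U1", "U1", "U1"]
        assert {p.status for p in placements} <= {"anchored", "pair-inferred"}

    def test_simulated_multi_unit_locus_unit_count_within_one(self, code25):
        # the locus sits inside flanking context so fragments start on both
        # sides and junction-spanning reads exist at every offset
        rng = np.random.default_rng(1)
        units = ["CCAACTGAT", "CCAACAGAT", "CCTACAGAT"]
        order = [units[i] for i in rng.integers(0, 3, size=12)]
        pad5 = self._context(200, 11)
        pad3 = self._context(200, 12)
        region = pad5 + self.LEFT + "".join(order) + self.RIGHT + pad3
        pairs = _pairs_from_layout(region, read_len=100, insert=200, step=3)
        model, _ = reconstruct_locus(
            pairs, self.LEFT, self.RIGHT, insert_mean=200, insert_sd=10,
            unit_length=9, code=code25,
        )
        assert abs(model.estimated_unit_count - 12) <= 1
        assert model.interior == "".join(order)

    @staticmethod
    def _context(n, seed):
        rng = np.random.default_rng(seed)
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_deterministic_under_input_order(self, code25):
        locus = self.LEFT + "CCAACTGAT" * 5 + self.RIGHT
        pairs = _pairs_from_layout(locus, read_len=80, insert=140, step=5)
        m1, p1 = reconstruct_locus(pairs, self.LEFT, self.RIGHT, 150, 10)
        m2, p2 = reconstruct_locus(pairs[::-1], self.LEFT, self.RIGHT, 150, 10)
        assert m1.consensus == m2.consensus
        assert p1 == p2

    def test_unanchored_locus_rejected(self):
        pairs = [ReadPair("p0", "ACGT" * 25, "TGCA" * 25)]
        with pytest.raises(ValueError, match="unanchored locus"):
            reconstruct_locus(pairs, self.LEFT, self.RIGHT, 300, 30)

    def test_equally_parsimonious_extensions_flag_ambiguity(self):
        # a seed read anchors the left flank; two non-anchoring reads then
        # offer the same 25-base overlap but different continuations, with no
        # placed mates to arbitrate: a true two-layout ambiguity
        seed = self.LEFT[-40:] + "ACGT"
        grown = self.LEFT + "ACGT"
        r_a = grown[-25:] + "AAAAA" + self.RIGHT[:30]
        r_b = grown[-25:] + "GGGGG" + self.RIGHT[:30]
        r_fin = ("AAAAA" + self.RIGHT[:30])[-25:] + self.RIGHT[30:]
        pairs = [
            ReadPair("p0", seed, reverse_complement(seed)),
            ReadPair("p1", r_a, reverse_complement(r_a)),
            ReadPair("p2", r_b, reverse_complement(r_b)),
            ReadPair("p3", r_fin, reverse_complement(r_fin)),
        ]
        model, placements = reconstruct_locus(
            pairs, self.LEFT, self.RIGHT, insert_mean=300, insert_sd=30,
            min_anchor=30, min_overlap=25,
        )
        assert model.is_ambiguous
        assert any(p.status == "ambiguous" for p in placements)
        # lexicographic tie-break picks p1's continuation
        assert "AAAAA" + self.RIGHT[:30] in model.consensus


class TestJoin:
    @staticmethod
    def _random_seq(n, seed):
        rng = np.random.default_rng(seed)
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_perfect_end_overlap_joins(self):
        core_a = self._random_seq(600, 1)
        shared = self._random_seq(500, 2)
        core_b = self._random_seq(600, 3)
        res = join_end_overlaps({"a": core_a + shared, "b": shared + core_b})
        (joined,) = res.scaffolds.values()
        assert joined == core_a + shared + core_b
        assert any(c.applied and c.overlap == 500 for c in res.candidates)

    def test_one_mismatch_reported_but_not_joined(self):
        core_a = self._random_seq(600, 1)
        shared = self._random_seq(500, 2)
        broken = shared[:250] + ("A" if shared[250] != "A" else "C") + shared[251:]
        res = join_end_overlaps({"a": core_a + shared, "b": broken + self._random_seq(600, 3)})
        assert len(res.scaffolds) == 2  # nothing joined
        near = [c for c in res.candidates if not c.applied]
        assert near and near[0].overlap == 500

    def test_self_overlap_circularizes_and_trims_once(self):
        core = self._random_seq(2000, 4)
        end = self._random_seq(200, 5)
        scaffold = end + core + end
        res = join_end_overlaps({"s": scaffold})
        assert res.circular["s"]
        assert len(res.scaffolds["s"]) == len(scaffold) - 200

    def test_conflicting_joins_report_all_apply_none(self):
        shared = self._random_seq(300, 6)
        a = self._random_seq(400, 7) + shared
        b = shared + self._random_seq(400, 8)
        c = shared + self._random_seq(400, 9)
        res = join_end_overlaps({"a": a, "b": b, "c": c})
        assert len(res.scaffolds) == 3
        assert sum(not cand.applied for cand in res.candidates) >= 2

    def test_below_min_overlap_not_joined(self):
        shared = self._random_seq(99, 10)
        res = join_end_overlaps(
            {"a": self._random_seq(300, 11) + shared, "b": shared + self._random_seq(300, 12)}
        )
        assert len(res.scaffolds) == 2
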