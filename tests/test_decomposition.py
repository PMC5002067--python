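"""Test-case algebra: partition validation, enumeration, fusion, filters."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import naturalmoves as nm
from naturalmoves.decomposition import (
    Chain,
    CombinatorialExplosionError,
    Decomposition,
    MoltenZone,
    Segment,
    StructureIndex,
    TestCase,
    TorsionDOF,
)


def simple_chain(n=20, cid="A"):
    return StructureIndex(chains=(Chain(cid, tuple(range(1, n + 1))),))


class TestValidation:
    def test_canonical_groove_decomposition_is_valid(self, mhc_decomposition):
        assert nm.validate_decomposition(mhc_decomposition).ok

    def test_single_segment_whole_chain_no_mz(self):
        d = Decomposition(
            structure=simple_chain(10),
            segments=(Segment("S1", "A", 1, 10),),
        )
        assert nm.validate_decomposition(d).ok

    def test_overlapping_segments_reported(self):
        d = Decomposition(
            structure=simple_chain(20),
            segments=(Segment("S1", "A", 1, 10), Segment("S2", "A", 10, 20)),
        )
        report = nm.validate_decomposition(d)
        assert not report.ok
        assert any(v.kind == "overlap" and ":10" in v.message for v in report.violations)

    def test_uncovered_residue_is_orphan(self):
        d = Decomposition(
            structure=simple_chain(10),
            segments=(Segment("S1", "A", 1, 5), Segment("S2", "A", 7, 10)),
            molten_zones=(),
        )
        report = nm.validate_decomposition(d)
        assert any(v.kind == "orphan" for v in report.violations)

    def test_nucleic_mode_every_residue_a_segment(self, ddd_decomposition):
        # atom-level zones only: no residue-level molten zones, partition holds
        assert nm.validate_decomposition(ddd_decomposition).ok
        assert all(m.kind == "atom" for m in ddd_decomposition.molten_zones)

    def test_partition_counts(self, mhc_decomposition):
        d = mhc_decomposition
        seg_res = sum(len(s.residues()) for s in d.segments)
        mz_res = sum(len(m.residues) for m in d.molten_zones)
        assert seg_res + mz_res == len(d.structure.residues)


class TestEnumeration:
    def test_three_molten_zones_give_eight_cases(self, mhc_decomposition):
        cases = nm.enumerate_test_cases(mhc_decomposition)
        assert [c.label for c in cases] == [
            "000", "001", "010", "011", "100", "101", "110", "111",
        ]

    def test_zero_togglable_dofs_single_empty_case(self):
        d = Decomposition(structure=simple_chain(5), segments=(Segment("S1", "A", 1, 5),))
        cases = nm.enumerate_test_cases(d)
        assert len(cases) == 1 and cases[0].label == ""

    def test_grouped_torsions_toggle_as_one_bit(self):
        # 2 torsions grouped + 1 molten zone -> 2 bits -> 4 cases
        torsions = tuple(
            TorsionDOF(f"t{i}", "A", ((5, "N"), (5, "CA"), (5, "SC"), (6, "CA")), ((6, "CA"),))
            for i in (1, 2)
        )
        d = Decomposition(
            structure=simple_chain(12),
            segments=(Segment("S1", "A", 1, 5), Segment("S2", "A", 8, 12)),
            molten_zones=(MoltenZone("MZ", "residue", "A", residues=(6, 7), flanking=("S1", "S2")),),
            torsions=torsions,
        )
        cases = nm.enumerate_test_cases(d, torsion_groups=[("t1", "t2")])
        assert len(cases) == 4  # brute force: |{0,1}|^2

    def test_cap_refuses_combinatorial_explosion(self):
        segs = tuple(Segment(f"S{i}", "A", 3 * i + 1, 3 * i + 2) for i in range(22))
        mzs = tuple(
            MoltenZone(f"M{i}", "residue", "A", residues=(3 * i + 3,), flanking=(f"S{i}", f"S{i+1}"))
            for i in range(21)
        )
        d = Decomposition(structure=simple_chain(66), segments=segs, molten_zones=mzs)
        with pytest.raises(CombinatorialExplosionError, match="combinatorial explosion"):
            nm.enumerate_test_cases(d)

    @given(st.integers(min_value=0, max_value=6))
    def test_counting_matches_brute_force(self, n_mz):
        segs = tuple(Segment(f"S{i}", "A", 3 * i + 1, 3 * i + 2) for i in range(n_mz + 1))
        mzs = tuple(
            MoltenZone(f"M{i}", "residue", "A", residues=(3 * i + 3,), flanking=(f"S{i}", f"S{i+1}"))
            for i in range(n_mz)
        )
        d = Decomposition(
            structure=simple_chain(3 * (n_mz + 1)), segments=segs, molten_zones=mzs
        )
        cases = nm.enumerate_test_cases(d)
        assert len(cases) == 2**n_mz
        assert len({c.label for c in cases}) == 2**n_mz  # distinct bit strings


TABLE1 = {  # published segment sets for the five-segment decomposition
    "111": 5, "110": 4, "101": 4, "011": 4,
    "100": 3, "010": 3, "001": 3, "000": 2,
}


class TestApply:
    @pytest.mark.parametrize("label,expected", sorted(TABLE1.items()))
    def test_effective_segment_counts_match_published_table(
        self, mhc_decomposition, label, expected
    ):
        case = nm.parse_testcase_label(label, mhc_decomposition)
        eff = nm.apply_test_case(mhc_decomposition, case)
        assert len(eff.effective_segments) == expected

    def test_specific_fusions(self, mhc_decomposition):
        eff = nm.apply_test_case(
            mhc_decomposition, nm.parse_testcase_label("010", mhc_decomposition)
        )
        assert [s.id for s in eff.effective_segments] == ["A1+A2", "B1", "B2+B3"]
        eff0 = nm.apply_test_case(
            mhc_decomposition, nm.parse_testcase_label("000", mhc_decomposition)
        )
        assert [s.id for s in eff0.effective_segments] == ["A1+A2", "B1+B2+B3"]

    def test_fused_segment_absorbs_zone_residues(self, mhc_decomposition):
        eff = nm.apply_test_case(
            mhc_decomposition, nm.parse_testcase_label("000", mhc_decomposition)
        )
        a = next(s for s in eff.effective_segments if s.id == "A1+A2")
        a1 = mhc_decomposition.segment("A1")
        a2 = mhc_decomposition.segment("A2")
        # residues between A1 and A2 (the deactivated zone) move with the fusion
        assert set(range(a1.head, a2.tail + 1)) == set(a.residues)

    def test_bit_length_mismatch_rejected(self, mhc_decomposition):
        with pytest.raises(ValueError, match="bits"):
            nm.apply_test_case(mhc_decomposition, TestCase(bits=(0, 1), label="01"))

    @given(st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)), st.integers(0, 2))
    def test_fusion_monotonicity(self, mhc_decomposition, bits, flip_pos):
        """Deactivating any additional zone never increases the segment count."""
        if bits[flip_pos] == 0:
            return
        label = "".join(map(str, bits))
        lowered = list(bits)
        lowered[flip_pos] = 0
        low_label = "".join(map(str, lowered))
        n_high = len(
            nm.apply_test_case(
                mhc_decomposition, nm.parse_testcase_label(label, mhc_decomposition)
            ).effective_segments
        )
        n_low = len(
            nm.apply_test_case(
                mhc_decomposition, nm.parse_testcase_label(low_label, mhc_decomposition)
            ).effective_segments
        )
        assert n_low <= n_high

    def test_extremes_bound_segment_count(self, mhc_decomposition):
        n_all_on = len(
            nm.apply_test_case(
                mhc_decomposition, nm.parse_testcase_label("111", mhc_decomposition)
            ).effective_segments
        )
        n_all_off = len(
            nm.apply_test_case(
                mhc_decomposition, nm.parse_testcase_label("000", mhc_decomposition)
            ).effective_segments
        )
        assert n_all_on == len(mhc_decomposition.segments)
        assert n_all_off == 2  # one maximal run per helix


class TestLabels:
    def test_parse_example(self, mhc_decomposition):
        t = nm.parse_testcase_label("010", mhc_decomposition)
        assert t.bits == (0, 1, 0)

    def test_empty_label_on_empty_decomposition(self):
        d = Decomposition(structure=simple_chain(5), segments=(Segment("S1", "A", 1, 5),))
        t = nm.parse_testcase_label("", d)
        assert t.bits == ()

    def test_invalid_symbol_rejected(self, mhc_decomposition):
        with pytest.raises(ValueError, match="only '0'/'1'"):
            nm.parse_testcase_label("012", mhc_decomposition)

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=10))
    def test_roundtrip_format_parse(self, bits):
        label = "".join(map(str, bits))
        segs = tuple(Segment(f"S{i}", "A", 3 * i + 1, 3 * i + 2) for i in range(len(bits) + 1))
        mzs = tuple(
            MoltenZone(f"M{i}", "residue", "A", residues=(3 * i + 3,), flanking=(f"S{i}", f"S{i+1}"))
            for i in range(len(bits))
        )
        d = Decomposition(
            structure=simple_chain(3 * (len(bits) + 1)), segments=segs, molten_zones=mzs
        )
        assert nm.format_testcase(nm.parse_testcase_label(label, d)) == label


class TestDnaFilters:
    def test_torsion_bits_equal_rule(self, ddd_decomposition):
        cases = nm.enumerate_test_cases(ddd_decomposition)
        assert len(cases) == 8
        kept = nm.dna_filter_testcases(cases, [nm.bits_equal(0, 1)])
        assert [c.label for c in kept] == ["000", "001", "110", "111"]

    def test_drop_near_duplicate_case(self, ddd_decomposition):
        cases = nm.enumerate_test_cases(ddd_decomposition)
        kept = nm.dna_filter_testcases(
            cases, [nm.bits_equal(0, 1), nm.drop_labels(["110"])]
        )
        assert [c.label for c in kept] == ["000", "001", "111"]

    def test_empty_rule_set_is_identity(self, ddd_decomposition):
        cases = nm.enumerate_test_cases(ddd_decomposition)
        assert nm.dna_filter_testcases(cases, []) == cases
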