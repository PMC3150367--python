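import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efg_paralogs.alignment import Alignment
from efg_paralogs.conservation import (
    ColumnProfile,
    classify_position,
    column_profile,
    conservation_difference,
    domain_conservation,
    hydropathy,
    is_conserved,
)
from efg_paralogs.errors import ConsistencyError
from oracles import column_entropy_bits


def column_alignment(column: str) -> Alignment:
    return Alignment([f"s{i}" for i in range(len(column))], [ch for ch in column])


def profile(pct_top, top="A", other="G", n=100, position=1):
    """Synthetic two-residue ColumnProfile with exact top percentage."""
    k = round(pct_top * n / 100)
    aln = column_alignment(top * k + other * (n - k))
    p = column_profile(aln, 0)
    return ColumnProfile(position, p.freqs, 0.0, p.info_bits, p.top_residue,
                         p.top_conservation_pct, True, n)


class TestColumnProfile:
    def test_single_residue_column_has_max_bits(self):
        p = column_profile(column_alignment("A" * 20), 0)
        assert p.info_bits == pytest.approx(math.log2(20))
        assert p.top_residue == "A" and p.top_conservation_pct == 100

    def test_uniform_column_has_zero_bits(self):
        p = column_profile(column_alignment("ACDEFGHIKLMNPQRSTVWY"), 0)
        assert p.info_bits == pytest.approx(0, abs=1e-12)

    def test_80_20_split_matches_direct_entropy(self):
        p = column_profile(column_alignment("A" * 8 + "G" * 2), 0)
        expected = math.log2(20) - (-(0.8 * math.log2(0.8) + 0.2 * math.log2(0.2)))
        assert p.info_bits == pytest.approx(expected)
        assert p.info_bits == pytest.approx(3.600, abs=5e-4)

    def test_all_gap_column_not_callable(self):
        p = column_profile(column_alignment("-----"), 0)
        assert not p.callable and p.info_bits is None

    def test_gappy_column_flagged_not_callable(self):
        p = column_profile(column_alignment("AA----"), 0)
        assert not p.callable  # gap fraction 2/3 > 1/2
        assert p.info_bits is not None  # frequencies still computed

    def test_ambiguity_codes_excluded_from_frequencies(self):
        p = column_profile(column_alignment("AAAX"), 0)
        assert p.freqs == {"A": 1.0} and p.n_counted == 3

    @given(st.lists(st.sampled_from("ACDEFGHIKL-X"), min_size=2, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_info_bits_matches_brute_force_entropy(self, chars):
        column = "".join(chars)
        if not any(ch in "ACDEFGHIKL" for ch in column):
            return
        p = column_profile(column_alignment(column), 0)
        assert p.info_bits == pytest.approx(column_entropy_bits(column), abs=1e-10)

    @given(st.integers(1, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_bits_maximal_iff_single_residue(self, n_a, n_g):
        p = column_profile(column_alignment("A" * n_a + "G" * n_g), 0)
        if n_g == 0:
            assert p.info_bits == pytest.approx(math.log2(20))
        else:
            assert p.info_bits < math.log2(20)


class TestIsConserved:
    @pytest.mark.parametrize(
        "bits,expected", [(4.32, True), (2.99, False), (3.0, True)]
    )
    def test_three_bit_threshold_inclusive(self, bits, expected):
        p = ColumnProfile(1, {"A": 1.0}, 0.0, bits, "A", 100.0, True, 10)
        assert is_conserved(p) is expected

    def test_not_callable_is_false_with_warning(self):
        p = ColumnProfile(1, {}, 1.0, None, None, 0.0, callable=False)
        with pytest.warns(UserWarning):
            assert is_conserved(p) is False


class TestClassifyPosition:
    def test_both_conserved_different_residues_is_type_one(self):
        call = classify_position(profile(100, "A"), profile(86, "G"))
        assert call.category == "type_I"

    def test_sub_threshold_second_subfamily_is_none(self):
        # conserved by bits on both sides but 76 % < 80 % residue threshold
        call = classify_position(profile(100, "T"), profile(76, "S"))
        assert call.category == "none"

    def test_relaxed_first_conserved_second_is_type_two(self):
        p1 = ColumnProfile(1, {"D": 0.61, "S": 0.29, "N": 0.10}, 0.0, 2.9, "D", 61.0, True, 100)
        call = classify_position(p1, profile(88, "D"))
        assert call.category == "type_II"
        assert call.difference_pct == 27

    def test_same_top_residue_both_conserved_is_shared(self):
        call = classify_position(profile(95, "A"), profile(96, "A"))
        assert call.category == "shared"

    def test_type_two_precedes_shared_when_difference_large(self):
        # both sides conserved with the same residue, but the difference
        # criterion fires: typed as II (stronger selection in subfamily 2)
        p1 = profile(62, "D")  # 3.04 bits, top D
        call = classify_position(p1, profile(88, "D"))
        assert call.category == "type_II"

    def test_inclusive_boundaries_at_80_pct_and_25_diff(self):
        call = classify_position(profile(80, "A"), profile(98, "G", "A"))
        assert call.category == "type_I"
        call = classify_position(profile(71, "G", "A"), profile(96, "G", "A"))
        assert call.category == "type_II" and call.difference_pct == 25

    def test_mismatched_positions_rejected(self):
        with pytest.raises(ConsistencyError):
            classify_position(profile(90, position=1), profile(90, position=2))

    @given(
        st.integers(5, 100), st.integers(5, 100),
        st.sampled_from("AG"), st.sampled_from("AG"),
    )
    @settings(max_examples=200, deadline=None)
    def test_categories_exclusive_and_exhaustive(self, pct1, pct2, top1, top2):
        call = classify_position(
            profile(pct1, top1, "C"), profile(pct2, top2, "C")
        )
        assert call.category in {"type_I", "type_II", "shared", "none"}


class TestConservationDifference:
    @pytest.mark.parametrize("p1,p2,expected", [(61, 88, 27), (45, 84, 39), (50, 50, 0)])
    def test_printed_differences(self, p1, p2, expected):
        assert conservation_difference(p1, p2) == expected

    @given(st.integers(0, 100), st.integers(0, 100))
    def test_antisymmetric(self, a, b):
        assert conservation_difference(a, b) == -conservation_difference(b, a)


class TestHydropathy:
    @pytest.mark.parametrize("residue,index", [("L", 3.8), ("G", -0.4), ("K", -3.9), ("A", 1.8), ("I", 4.5)])
    def test_kyte_doolittle_values(self, residue, index):
        assert hydropathy(residue) == index

    def test_ambiguity_code_rejected(self):
        with pytest.raises(KeyError):
            hydropathy("X")


class TestDomainConservation:
    domains = {"I": (1, 10), "II": (11, 20)}

    def test_all_and_none_conserved(self):
        assert domain_conservation([True] * 20, self.domains) == {"I": 100.0, "II": 100.0}
        assert domain_conservation([False] * 20, self.domains) == {"I": 0.0, "II": 0.0}

    def test_partial_count(self):
        flags = [True] * 4 + [False] * 16
        assert domain_conservation(flags, self.domains)["I"] == 40.0

    def test_empty_interval_undefined(self):
        assert domain_conservation([True] * 5, {"bad": (4, 2)})["bad"] is None

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ConsistencyError):
            domain_conservation([True] * 20, {"a": (1, 10), "b": (5, 15)})
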