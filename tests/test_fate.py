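import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efg_paralogs.errors import ConsistencyError, SequenceError, SpecError
from efg_paralogs.fate import (
    CODON_TO_AA,
    FateModelParams,
    STOP_CODONS,
    SubstitutionPair,
    classify_fate_point,
    codon_differences,
    codon_sites,
    jukes_cantor,
    loss_fraction,
    model_curves,
    ng86_dnds,
    power_law_neo,
    saturation_filter,
    selection_class,
    weibull_survival,
)
from efg_paralogs.synth import make_codon_pair, make_loss_scenario
from oracles import oracle_codon_differences, oracle_codon_sites, oracle_ng86

ALL_CODONS = sorted(CODON_TO_AA)


class TestCodonCounting:
    def test_sites_match_oracle_for_every_codon(self):
        for codon in ALL_CODONS:
            assert codon_sites(codon) == pytest.approx(oracle_codon_sites(codon))

    def test_differences_match_oracle_for_all_codon_pairs(self):
        # exhaustive over all sense-codon pairs, covering 0-3 differences
        for ca, cb in itertools.product(ALL_CODONS[::3], ALL_CODONS[::3]):
            assert codon_differences(ca, cb) == pytest.approx(
                oracle_codon_differences(ca, cb)
            ), (ca, cb)

    def test_total_differences_equal_hamming_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ca, cb = (ALL_CODONS[i] for i in rng.integers(0, len(ALL_CODONS), 2))
            sd, nd = codon_differences(ca, cb)
            assert sd + nd == pytest.approx(sum(a != b for a, b in zip(ca, cb)))


class TestJukesCantor:
    def test_zero_proportion(self):
        assert jukes_cantor(0.0) == 0.0

    def test_saturation_at_three_quarters(self):
        assert math.isinf(jukes_cantor(0.75))

    @given(st.floats(0.001, 0.7))
    @settings(max_examples=200)
    def test_inverts_forward_expectation(self, d):
        p = 0.75 * (1 - math.exp(-4 * d / 3))
        assert jukes_cantor(p) == pytest.approx(d, abs=1e-10)


class TestNg86:
    def test_identical_sequences_zero(self):
        pair = ng86_dnds("ATGGCTAAA", "ATGGCTAAA")
        assert pair.dN == 0 and pair.dS == 0 and pair.omega is None

    def test_single_synonymous_change(self):
        pair = ng86_dnds("GCT" * 10, "GCC" + "GCT" * 9)
        assert pair.dN == 0 and pair.dS > 0

    def test_single_nonsynonymous_change(self):
        pair = ng86_dnds("AAA" * 10, "GAA" + "AAA" * 9)
        assert pair.dS == 0 and pair.dN > 0

    def test_symmetric_in_arguments(self):
        a, b = make_codon_pair(12, 2, 3, seed=5)
        pa, pb = ng86_dnds(a, b), ng86_dnds(b, a)
        assert (pa.dN, pa.dS) == pytest.approx((pb.dN, pb.dS))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_on_small_pairs(self, seed):
        # 5-codon pairs with up to 2 differing codons (multi-hit included)
        rng = np.random.default_rng(seed)
        n_diff = int(rng.integers(0, 3))
        a, b = make_codon_pair(5, n_diff, 2 - n_diff, seed=seed + 100)
        pair = ng86_dnds(a, b)
        dn, ds = oracle_ng86(a, b)
        assert pair.dN == pytest.approx(dn, abs=1e-12)
        assert pair.dS == pytest.approx(ds, abs=1e-12)

    def test_multi_hit_codon_matches_oracle(self):
        a = "ATG" + "GCT" + "AAA" * 3
        b = "ATG" + "TTA" + "AAA" * 3  # two-position codon difference
        pair = ng86_dnds(a, b)
        dn, ds = oracle_ng86(a, b)
        assert (pair.dN, pair.dS) == pytest.approx((dn, ds), abs=1e-12)

    def test_agrees_with_independent_library_estimator(self):
        # cross-check against Bio.codonalign on stop-free-intermediate pairs
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for seed in range(5):
            a, b = make_codon_pair(20, 3, 2, seed=seed)
            pair = ng86_dnds(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert pair.dN == pytest.approx(dn, abs=1e-9)
            assert pair.dS == pytest.approx(ds, abs=1e-9)

    def test_frame_violation_rejected(self):
        with pytest.raises(SequenceError):
            ng86_dnds("ATGGC", "ATGGC")

    def test_length_mismatch_rejected(self):
        with pytest.raises(SequenceError):
            ng86_dnds("ATGGCT", "ATG")

    def test_internal_stop_rejected(self):
        with pytest.raises(SequenceError):
            ng86_dnds("ATGTAAGCT", "ATGTAAGCT")


class TestSaturationFilter:
    def make(self, ds):
        return SubstitutionPair("a", "b", 0.1, ds, 0.1 / ds if ds else None, ds > 3)

    def test_above_three_removed(self):
        retained, removed = saturation_filter([self.make(3.5)])
        assert retained == [] and len(removed) == 1

    def test_below_three_kept(self):
        retained, _ = saturation_filter([self.make(2.0)])
        assert len(retained) == 1

    def test_exactly_three_kept(self):
        retained, _ = saturation_filter([self.make(3.0)])
        assert len(retained) == 1

    @given(st.lists(st.floats(0, 10), max_size=20))
    @settings(max_examples=100)
    def test_never_removes_ds_at_most_three(self, ds_values):
        pairs = [self.make(ds) for ds in ds_values]
        _, removed = saturation_filter(pairs)
        assert all(p.dS > 3 for p in removed)


class TestSelectionClass:
    @pytest.mark.parametrize(
        "omega,expected",
        [(0.05, "purifying"), (1.0, "neutral"), (2.0, "positive"),
         (0.8, "neutral"), (1.2, "neutral"), (None, "unclassified")],
    )
    def test_binning(self, omega, expected):
        assert selection_class(omega) == expected


class TestModelCurves:
    params = FateModelParams(theta1=0.3, neo=power_law_neo(0.5, 0.8))

    def test_neutral_line_is_identity(self):
        curves = model_curves([0.0, 1.0, 2.5], self.params)
        assert curves["neutral"] == [0.0, 1.0, 2.5]

    def test_subfunctionalization_scales_by_theta1(self):
        curves = model_curves([2.0], self.params)
        assert curves["subfunctionalization"] == [pytest.approx(0.6)]

    def test_zero_ds_gives_zero_everywhere(self):
        curves = model_curves([0.0], self.params)
        for key, vals in curves.items():
            assert vals[0] == 0.0, key

    def test_degrades_without_neo_model(self):
        curves = model_curves([1.0], FateModelParams(theta1=0.5))
        assert curves["neo_mean"] is None and curves["neutral"] == [1.0]

    def test_quantiles_bracket_mean(self):
        curves = model_curves([0.5, 1.0, 2.0], self.params)
        for lo, mid, hi in zip(curves["neo_q05"], curves["neo_mean"], curves["neo_q95"]):
            assert lo <= mid <= hi

    def test_invalid_theta1_rejected(self):
        with pytest.raises(ValueError):
            FateModelParams(theta1=0.0)


class TestClassifyFatePoint:
    params = FateModelParams(theta1=0.3, neo=power_law_neo(0.5, 1.0))

    def test_point_on_neutral_line(self):
        pair = SubstitutionPair("a", "b", 1.0, 1.0, 1.0, False)
        assert classify_fate_point(pair, self.params)["neutral"] == "within"

    def test_point_below_neo_q05(self):
        pair = SubstitutionPair("a", "b", 0.01, 1.0, 0.01, False)
        assert classify_fate_point(pair, self.params)["neo"] == "below_q05"

    def test_saturated_pair_refused(self):
        pair = SubstitutionPair("a", "b", 0.1, 4.0, 0.025, True)
        with pytest.raises(ConsistencyError):
            classify_fate_point(pair, self.params)

    def test_points_sampled_in_envelope_stay_in_envelope(self):
        # draws between the quantile curves classify as within >= 90 %
        rng = np.random.default_rng(42)
        neo = self.params.neo
        n_within = 0
        for _ in range(1000):
            ds = float(rng.uniform(0.1, 2.5))
            dn = float(rng.uniform(neo.q05(ds), neo.q95(ds)))
            pair = SubstitutionPair("a", "b", dn, ds, dn / ds, False)
            if classify_fate_point(pair, self.params)["neo"] == "within_envelope":
                n_within += 1
        assert n_within >= 900


class TestWeibullSurvival:
    def test_survival_starts_at_one(self):
        assert weibull_survival(0.0, 2.0, 1.5) == 1.0

    def test_shape_one_is_exponential(self):
        assert weibull_survival(1.0, 1.0, 1.0) == pytest.approx(math.exp(-1))

    def test_closed_form(self):
        assert weibull_survival(2.0, 1.7, 0.9) == pytest.approx(
            math.exp(-((2.0 / 0.9) ** 1.7))
        )

    @given(st.floats(0, 10), st.floats(0.1, 5), st.floats(0.1, 5))
    @settings(max_examples=100)
    def test_monotone_non_increasing(self, t, shape, scale):
        assert weibull_survival(t, shape, scale) >= weibull_survival(t + 0.5, shape, scale)

    def test_non_positive_parameters_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(1.0, 0.0, 1.0)


class TestLossFraction:
    def test_no_deletions_zero_percent(self):
        scenario, presence = make_loss_scenario(8, 0.0, seed=1)
        assert loss_fraction(scenario, presence).loss_pct == 0.0

    def test_all_deleted_hundred_percent(self):
        scenario, presence = make_loss_scenario(8, 1.0, seed=2)
        assert loss_fraction(scenario, presence).loss_pct == 100.0

    def test_six_of_seven_lost(self):
        scenario, presence = make_loss_scenario(7, 6 / 7, seed=3)
        report = loss_fraction(scenario, presence)
        assert report.loss_pct == pytest.approx(85.7, abs=0.1)
        assert (report.duplication_count, report.deletion_count) == (1, 6)

    def test_inconsistent_presence_rejected(self):
        scenario, presence = make_loss_scenario(6, 0.5, seed=4)
        deleted = next(k for k, v in presence.items() if not v)
        presence[deleted] = True
        with pytest.raises(ConsistencyError):
            loss_fraction(scenario, presence)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_direct_leaf_count_on_random_scenarios(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        frac = float(rng.uniform(0, 1))
        scenario, presence = make_loss_scenario(n, frac, seed=seed + 50)
        report = loss_fraction(scenario, presence)
        expected = 100.0 * sum(not v for v in presence.values()) / n
        assert report.loss_pct == pytest.approx(expected)

    def test_monotone_in_deletion_set(self):
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        losses = [
            loss_fraction(*make_loss_scenario(12, f, seed=9)).loss_pct for f in fractions
        ]
        assert losses == sorted(losses)


class TestMakeCodonPair:
    def test_pure_synonymous_request(self):
        a, b = make_codon_pair(10, 1, 0, seed=0)
        pair = ng86_dnds(a, b)
        assert pair.dN == 0 and pair.dS > 0

    def test_pure_nonsynonymous_request(self):
        a, b = make_codon_pair(10, 0, 1, seed=0)
        pair = ng86_dnds(a, b)
        assert pair.dS == 0 and pair.dN > 0

    def test_impossible_request_rejected(self):
        with pytest.raises(SpecError):
            make_codon_pair(3, 2, 2, seed=0)

    def test_seed_determinism(self):
        assert make_codon_pair(15, 3, 2, seed=7) == make_codon_pair(15, 3, 2, seed=7)
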