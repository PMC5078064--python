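"""Splice-variant fractions, profile labels and the high/low split."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nkp44var import profiling
from nkp44var.profiling import (
    ProfileLabel,
    Subgroup,
    call_positive,
    classify_profile,
    classify_sample,
    cohort_summary,
    isoform_fractions,
    positive_share,
    split_high_low,
)


class TestCallPositive:
    @pytest.mark.parametrize(
        "value, tau, expected",
        [(0.0, 0.0, False), (0.01, 0.0, True), (0.4, 0.5, False), (0.5, 0.5, False)],
    )
    def test_strict_inequality(self, value, tau, expected):
        assert call_positive(value, tau) is expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            call_positive(-1.0)


class TestIsoformFractions:
    @pytest.mark.parametrize(
        "v, expected",
        [((10, 0, 0), (100, 0, 0)), ((2, 2, 4), (25, 25, 50)), ((1, 1, 2), (25, 25, 50))],
    )
    def test_percentages(self, v, expected):
        fr = isoform_fractions(*v)
        assert (fr.f1, fr.f2, fr.f3) == pytest.approx(expected)

    def test_zero_total_gives_undefined_fractions(self):
        fr = isoform_fractions(0, 0, 0)
        assert math.isnan(fr.f1) and math.isnan(fr.f2) and math.isnan(fr.f3)
        assert not fr.defined

    @given(
        st.tuples(
            st.floats(0, 1e6, allow_nan=False),
            st.floats(0, 1e6, allow_nan=False),
            st.floats(0, 1e6, allow_nan=False),
        ).filter(lambda v: sum(v) > 0)
    )
    def test_defined_fractions_sum_to_100(self, v):
        fr = isoform_fractions(*v)
        assert fr.f1 + fr.f2 + fr.f3 == pytest.approx(100.0, abs=1e-6)


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "ncr1, v, expected",
        [
            (5, (3, 0, 0), ProfileLabel.NKP44_1),
            (5, (3, 0, 1), ProfileLabel.NKP44_2_3),  # 2/3 with or without 1
            (5, (0, 2, 0), ProfileLabel.NKP44_2_3),
            (5, (0, 0, 0), ProfileLabel.NKP44_NEG),
            (0, (3, 0, 0), ProfileLabel.EXCLUDED_NKP46_NEG),
        ],
    )
    def test_definition(self, ncr1, v, expected):
        assert classify_profile(ncr1, *v) is expected

    @given(
        st.floats(0, 1e4, allow_nan=False),
        st.floats(0, 1e4, allow_nan=False),
        st.floats(0, 1e4, allow_nan=False),
        st.floats(0, 1e4, allow_nan=False),
    )
    def test_every_sample_gets_exactly_one_label(self, ncr1, v1, v2, v3):
        assert classify_profile(ncr1, v1, v2, v3) in ProfileLabel

    @given(
        st.floats(0.01, 1e3),
        st.floats(0, 1e3, allow_subnormal=False),
        st.floats(0, 1e3, allow_subnormal=False),
        st.floats(0, 1e3, allow_subnormal=False),
        st.floats(0.001, 1e3),
    )
    def test_scale_invariance_at_tau_zero(self, ncr1, v1, v2, v3, k):
        base = classify_profile(ncr1, v1, v2, v3)
        scaled = classify_profile(k * ncr1, k * v1, k * v2, k * v3)
        assert base is scaled


def _nkp44_1_sample(barcode, v1, ncr1=10.0):
    return classify_sample(barcode, ncr1, v1, 0.0, 0.0)


class TestSplitHighLow:
    def test_even_split_24_gives_12_and_12(self):
        samples = [_nkp44_1_sample(f"TCGA-SY-{i:04d}-03A-01T-0001-13", float(i + 1))
                   for i in range(24)]
        out = split_high_low(samples)
        high = [c for c in out if c.subgroup is Subgroup.HIGH]
        low = [c for c in out if c.subgroup is Subgroup.LOW]
        assert len(high) == 12 and len(low) == 12
        assert min(c.nkp44_1_norm for c in high) > max(c.nkp44_1_norm for c in low)

    def test_odd_n_extra_sample_goes_to_low(self):
        samples = [_nkp44_1_sample(f"TCGA-SY-{i:04d}-03A-01T-0001-13", float(i + 1))
                   for i in range(5)]
        out = split_high_low(samples)
        assert sum(c.subgroup is Subgroup.HIGH for c in out) == 2
        assert sum(c.subgroup is Subgroup.LOW for c in out) == 3

    def test_ties_broken_by_barcode_reproducibly(self):
        samples = [_nkp44_1_sample(f"TCGA-SY-{i:04d}-03A-01T-0001-13", 5.0)
                   for i in range(4)]
        first = split_high_low(samples)
        again = split_high_low(list(reversed(samples)))
        by_bc = {c.barcode: c.subgroup for c in again}
        assert all(by_bc[c.barcode] is c.subgroup for c in first)
        # lexicographically smallest barcodes take HIGH on full ties
        highs = sorted(c.barcode for c in first if c.subgroup is Subgroup.HIGH)
        assert highs == sorted(c.barcode for c in first)[:2]

    def test_sizes_differ_by_at_most_one(self):
        for n in (1, 2, 3, 10, 11):
            samples = [_nkp44_1_sample(f"TCGA-SY-{i:04d}-03A-01T-0001-13", float(i + 1))
                       for i in range(n)]
            out = split_high_low(samples)
            nh = sum(c.subgroup is Subgroup.HIGH for c in out)
            nl = sum(c.subgroup is Subgroup.LOW for c in out)
            assert nh + nl == n and abs(nh - nl) <= 1

    def test_rejects_wrong_label_and_zero_ncr1(self):
        neg = classify_sample("TCGA-SY-0001-03A-01T-0001-13", 5.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="NKP44_1"):
            split_high_low([neg])
        with pytest.raises(ValueError, match="NCR1"):
            # bypass classification by forging ncr1=0 on an NKP44_1 record
            sample = _nkp44_1_sample("TCGA-SY-0001-03A-01T-0001-13", 3.0)
            object.__setattr__(sample, "ncr1_value", 0.0)
            split_high_low([sample])


class TestCohortSummary:
    def test_pure_nkp44_1_group_reports_mean_f1_100(self):
        samples = [_nkp44_1_sample(f"TCGA-SY-{i:04d}-03A-01T-0001-13", float(i + 1))
                   for i in range(6)]
        summ = cohort_summary(samples)
        row = summ.loc[ProfileLabel.NKP44_1.value]
        assert row["n"] == 6
        assert row["mean_f1"] == pytest.approx(100.0)
        assert row["mean_f2"] == pytest.approx(0.0)

    def test_empty_class_has_n0_and_missing_means(self):
        summ = cohort_summary([])
        assert (summ["n"] == 0).all()
        assert summ["mean_f1"].isna().all()

    def test_dirichlet_means_recovered_from_generator_truth(self, rng):
        # group-level mean fractions of a Dirichlet(2, 1, 2) are 40/20/40
        alphas = np.array([2.0, 1.0, 2.0])
        fracs = rng.dirichlet(alphas, size=4000)
        totals = rng.lognormal(3.5, 0.5, size=4000)
        samples = [
            classify_sample(f"TCGA-SY-{i:04d}-03A-01T-0001-13", 10.0,
                            *(fracs[i] * totals[i]))
            for i in range(4000)
        ]
        summ = cohort_summary(samples)
        row = summ.loc[ProfileLabel.NKP44_2_3.value]
        expected = 100 * alphas / alphas.sum()
        assert row["mean_f1"] == pytest.approx(expected[0], abs=1.5)
        assert row["mean_f2"] == pytest.approx(expected[1], abs=1.5)
        assert row["mean_f3"] == pytest.approx(expected[2], abs=1.5)


def test_positive_share_rounds_to_whole_percent():
    assert positive_share(51, 164) == 31
    assert positive_share(0, 10) == 0
    with pytest.raises(ValueError):
        positive_share(5, 0)
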