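import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeiscan import (
    aei_frequencies,
    call_aei,
    excess_kurtosis,
    frequency_filter,
    orient_ratio,
    oriented_mean_sem,
    ratio_to_percent,
    sek,
    summarize_variant,
)
from aeiscan.detection import AeiCall, SampleRatio


def brute_force_g2(values):
    """Independent evaluation of bias-corrected excess kurtosis."""
    n = len(values)
    mean = sum(values) / n
    s = math.sqrt(sum((x - mean) ** 2 for x in values) / (n - 1))
    term = sum(((x - mean) / s) ** 4 for x in values)
    return (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * term
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )


def brute_force_sek(n):
    """Independent evaluation of the SEK closed form."""
    ses = math.sqrt((6.0 * n * (n - 1)) / ((n - 2) * (n + 1) * (n + 3)))
    return 2.0 * ses * math.sqrt((n**2 - 1.0) / ((n - 3.0) * (n + 5.0)))


class TestFrequencies:
    @pytest.mark.parametrize(
        ("n_imb", "n_het", "cohort", "f_het", "f_cohort"),
        [
            (7, 22, 52, 31.8, 13.5),
            (19, 20, 52, 95.0, 36.5),
            (0, 10, 52, 0.0, 0.0),
        ],
    )
    def test_frequencies(self, n_imb, n_het, cohort, f_het, f_cohort):
        got_het, got_cohort = aei_frequencies(n_imb, n_het, cohort)
        assert round(got_het, 1) == f_het
        assert round(got_cohort, 1) == f_cohort

    def test_zero_het_undefined(self):
        with pytest.raises(ValueError, match="zero heterozygous"):
            aei_frequencies(0, 0, 52)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            aei_frequencies(8, 7, 52)

    @settings(deadline=None, derandomize=True)
    @given(
        n_het=st.integers(1, 52),
        n_imb=st.integers(0, 52),
        cohort=st.integers(52, 100),
    )
    def test_counts_recoverable_from_frequencies(self, n_het, n_imb, cohort):
        n_imb = min(n_imb, n_het)
        f_het, f_cohort = aei_frequencies(n_imb, n_het, cohort)
        assert round(f_het * n_het / 100) == n_imb
        assert round(f_cohort * cohort / 100) == n_imb


class TestOrientation:
    @pytest.mark.parametrize(
        ("ratio", "expected"), [(2.0, 0.5), (0.5, 0.5), (1.0, 1.0)]
    )
    def test_orient_ratio(self, ratio, expected):
        assert orient_ratio(ratio) == expected

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(1e-6, 1e6, allow_nan=False))
    def test_oriented_ratio_in_unit_interval(self, r):
        o = orient_ratio(r)
        assert 0 < o <= 1
        assert o == orient_ratio(1 / r)


class TestOrientedMeanSem:
    def test_symmetric_pair_collapses(self):
        oriented = [orient_ratio(0.5), orient_ratio(2.0)]
        mean, sem = oriented_mean_sem(oriented)
        assert (mean, sem) == (0.5, 0.0)

    def test_sem_is_sd_over_sqrt_n(self):
        # 7 values scaled to sample SD 0.1168: SEM must come out 0.0441,
        # the internally consistent SD-vs-SEM pairing for n = 7
        base = np.arange(1.0, 8.0)
        values = 0.3 + (base - base.mean()) * 0.1168 / base.std(ddof=1)
        assert np.std(values, ddof=1) == pytest.approx(0.1168)
        _, sem = oriented_mean_sem(values)
        assert round(sem, 4) == 0.0441

    def test_constant_ratios_have_zero_sem(self):
        assert oriented_mean_sem([0.4] * 5) == (pytest.approx(0.4), 0.0)

    def test_single_value_warns(self):
        with pytest.warns(UserWarning, match="single"):
            mean, sem = oriented_mean_sem([0.7])
        assert (mean, sem) == (0.7, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oriented_mean_sem([])


class TestRatioToPercent:
    def test_band_edges(self):
        upper = ratio_to_percent(1.5)
        assert (upper.minor_percent, upper.major_percent) == (40.0, 60.0)
        lower = ratio_to_percent(0.666)
        assert round(lower.minor_percent, 2) == 39.98
        assert round(lower.major_percent, 2) == 60.02

    def test_balanced(self):
        pair = ratio_to_percent(1.0)
        assert (pair.minor_percent, pair.major_percent) == (50.0, 50.0)

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(1e-4, 1e4, allow_nan=False))
    def test_percent_pair_inverts_to_oriented_ratio(self, r):
        pair = ratio_to_percent(r)
        assert pair.minor_percent + pair.major_percent == pytest.approx(100.0)
        assert pair.minor_percent / pair.major_percent == pytest.approx(
            orient_ratio(r), rel=1e-9
        )


class TestKurtosis:
    def test_matches_brute_force_formula(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert excess_kurtosis(values) == pytest.approx(
            brute_force_g2(values), abs=1e-12
        )

    def test_large_normal_sample_near_zero(self, rng):
        draws = rng.standard_normal(10_000)
        assert abs(excess_kurtosis(draws)) < 0.15

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    def test_affine_invariance(self, a, b):
        values = np.array([0.1, 0.5, 0.9, 1.7, 2.4, 0.3, 1.1])
        assert excess_kurtosis(a * values + b) == pytest.approx(
            excess_kurtosis(values), rel=1e-8
        )

    @pytest.mark.parametrize("values", [[1.0, 2.0, 3.0], [2.0, 2.0, 2.0, 2.0]])
    def test_undefined_cases_warn_and_return_nan(self, values):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(excess_kurtosis(values))


class TestSek:
    def test_reference_sample_sizes(self):
        assert round(sek(7), 4) == 1.5875
        assert round(sek(6), 4) == 1.7408

    def test_matches_independent_form_over_range(self):
        for n in range(6, 1001):
            assert sek(n) == pytest.approx(brute_force_sek(n), abs=1e-12)

    def test_large_n_limit(self):
        assert sek(10_000) == pytest.approx(math.sqrt(24 / 10_000), rel=0.01)

    def test_small_n_undefined(self):
        with pytest.warns(UserWarning, match="SEK undefined"):
            assert math.isnan(sek(5))


def _call_from_linear_ratios(site_factory, ratios):
    srs = []
    for i, r in enumerate(ratios):
        sr = SampleRatio(
            sample_id=f"S{i}",
            linear_ratio=r,
            log_ratio=math.log(r),
            is_moderate=(r < 0.666 or r > 1.5),
        )
        srs.append(sr)
    return AeiCall(site=site_factory(), ratios=srs)


class TestSummarizeVariant:
    def test_directional_counts_and_frequencies(self, site_factory):
        call = _call_from_linear_ratios(site_factory, [2.0, 1.9, 1.0, 1.0])
        s = summarize_variant(call, cohort_size=52)
        assert (s.n_above, s.n_below, s.n_imbalanced) == (2, 0, 2)
        assert round(s.freq_het, 1) == 50.0
        assert round(s.freq_cohort, 1) == 3.8
        assert s.orientation_fraction == 1.0
        assert s.abs_mean_ratio == pytest.approx(
            (orient_ratio(2.0) + orient_ratio(1.9)) / 2
        )

    def test_directional_split_sums_to_imbalanced(self, site_factory):
        call = _call_from_linear_ratios(
            site_factory, [0.5, 0.3, 2.0, 1.0, 1.2, 0.9]
        )
        s = summarize_variant(call, cohort_size=52)
        assert s.n_below + s.n_above == s.n_imbalanced == 3
        assert s.orientation_fraction == pytest.approx(2 / 3)

    def test_no_moderate_samples_yields_missing_statistics(self, site_factory):
        call = _call_from_linear_ratios(site_factory, [1.0, 1.1, 0.9])
        s = summarize_variant(call, cohort_size=52)
        assert s.n_imbalanced == 0
        assert math.isnan(s.abs_mean_ratio)
        assert math.isnan(s.kurtosis)

    def test_kurtosis_defined_only_from_four_imbalanced(self, site_factory):
        ratios = [2.0, 2.2, 1.8, 2.5, 1.9, 2.1]
        s = summarize_variant(
            _call_from_linear_ratios(site_factory, ratios), cohort_size=52
        )
        oriented = [orient_ratio(r) for r in ratios]
        assert s.kurtosis == pytest.approx(brute_force_g2(oriented), abs=1e-10)
        assert s.sek == pytest.approx(brute_force_sek(6), abs=1e-12)

    def test_requires_het_samples(self, site_factory):
        with pytest.raises(ValueError):
            summarize_variant(AeiCall(site=site_factory()), cohort_size=52)


class TestFrequencyFilter:
    def _summary_with_freq(self, site_factory, n_imb, n_het):
        call = _call_from_linear_ratios(
            site_factory, [2.0] * n_imb + [1.0] * (n_het - n_imb)
        )
        return summarize_variant(call, cohort_size=52)

    def test_strictly_above_threshold_kept(self, site_factory):
        s = self._summary_with_freq(site_factory, 6, 20)  # 11.5% of 52
        assert frequency_filter([s], 10.0) == [s]

    def test_exactly_at_threshold_dropped(self, site_factory):
        # 5.2 imbalanced of 52 is impossible; use threshold equal to value
        s = self._summary_with_freq(site_factory, 13, 26)  # 25.0% of 52
        assert frequency_filter([s], 25.0) == []

    def test_empty_input(self):
        assert frequency_filter([], 10.0) == []
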