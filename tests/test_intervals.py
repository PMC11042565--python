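"""Statistical kernel: summary statistics, multipliers, the four PI
scenarios and the confidence interval, checked against hand-computed
oracle values for the glucose worked examples."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from labpi import (
    MeasurementSeries,
    Provenance,
    confidence_interval,
    pi_scenario1,
    pi_scenario2,
    pi_scenario3,
    pi_scenario4,
    select_scenario,
    summarize,
    t_quantile,
    z_quantile,
)

finite_means = st.floats(min_value=0.1, max_value=1e3)
small_sds = st.floats(min_value=0.0, max_value=50.0)
levels = st.floats(min_value=0.5, max_value=0.999)


class TestSummarize:
    def test_iqc_collection_run_matches_printed_summary(self, table1):
        stats = summarize(table1)
        assert stats.n == 30
        assert round(stats.mean, 2) == 4.21
        assert round(stats.sd, 2) == 0.07

    def test_patient_series_at_full_precision(self, table5_glucose):
        # hand-computed from the ten printed values: mean 4.2910, sd 0.1585
        stats = summarize(table5_glucose)
        assert stats.mean == pytest.approx(4.2910, abs=5e-5)
        assert stats.sd == pytest.approx(0.1585, abs=5e-5)

    def test_constant_series_has_zero_dispersion(self):
        stats = summarize(MeasurementSeries("c", (5.0, 5.0, 5.0)))
        assert (stats.mean, stats.sd, stats.cv_percent) == (5.0, 0.0, 0.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            summarize(MeasurementSeries("one", (4.2,)))
        with pytest.raises(ValueError):
            summarize(MeasurementSeries("zero-mean", (-1.0, 1.0)))


class TestMultipliers:
    @pytest.mark.parametrize(
        "level, expected",
        [(0.95, 1.96), (0.6827, 1.00), (0.99, 2.5758)],
    )
    def test_normal_quantiles(self, level, expected):
        decimals = len(str(expected).split(".")[1])
        assert round(z_quantile(level), decimals) == expected

    @pytest.mark.parametrize(
        "df, expected",
        [(9, 2.26), (4, 2.776), (29, 2.04), (19, 2.09), (10**6, 1.96)],
    )
    def test_t_table_values(self, df, expected):
        # printed t tables list three decimals (e.g. 2.045 at df 29); the
        # desk value keeps two of them
        decimals = len(str(expected).split(".")[1])
        assert round(round(t_quantile(df, 0.95), 3), decimals) == expected

    @pytest.mark.parametrize("df, pct", [(29, 4.1), (19, 6.6)])
    def test_t_vs_z_relative_difference_at_table_precision(self, df, pct):
        # the small-sample penalty quoted for n = 30 and n = 20 uses the
        # 2-decimal table values (2.04, 2.09 vs 1.96)
        t = round(round(t_quantile(df, 0.95), 3), 2)
        z = round(z_quantile(0.95), 2)
        assert round(100.0 * (t - z) / z, 1) == pct

    def test_t_strictly_decreasing_in_df_toward_z(self):
        values = [t_quantile(df, 0.95) for df in range(1, 200)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] > z_quantile(0.95)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_level_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            z_quantile(bad)
        with pytest.raises(ValueError):
            t_quantile(10, bad)

    def test_df_domain_enforced(self):
        with pytest.raises(ValueError):
            t_quantile(0, 0.95)


class TestScenarioFormulas:
    def test_scenario1_reproduces_established_iqc_limits(self):
        iv = pi_scenario1(4.21, 0.07, 0.95)
        assert iv.rounded(2).lower == 4.07
        assert iv.rounded(2).upper == 4.35
        assert iv.scenario_number == 1

    def test_scenario1_full_precision_from_raw_collection_run(self, table1):
        stats = summarize(table1)
        iv = pi_scenario1(stats.mean, stats.sd, 0.95)
        assert iv.lower == pytest.approx(4.0718, abs=2e-4)
        assert iv.upper == pytest.approx(4.3562, abs=2e-4)

    def test_scenario2_reproduces_cvi_based_prri(self):
        iv = pi_scenario2(4.21, 0.21, 4, 0.95)
        assert (iv.rounded(2).lower, iv.rounded(2).upper) == (3.75, 4.67)

    def test_scenario2_full_precision_sd_from_cvi(self):
        # sd = 5.00% CV_I x mean 4.21 = 0.2105
        iv = pi_scenario2(4.21, 0.2105, 4, 0.95)
        assert iv.lower == pytest.approx(3.7487, abs=2e-4)
        assert iv.upper == pytest.approx(4.6713, abs=2e-4)

    def test_scenario2_converges_to_scenario1_for_large_n(self):
        small_n = pi_scenario2(4.21, 0.21, 10**9, 0.95)
        ref = pi_scenario1(4.21, 0.21, 0.95)
        assert small_n.lower == pytest.approx(ref.lower, abs=1e-6)
        assert small_n.upper == pytest.approx(ref.upper, abs=1e-6)

    def test_scenario3_default_matches_peer_group_example(self):
        iv = pi_scenario3(4.20, 0.05, 10, 0.95)
        assert (iv.rounded(2).lower, iv.rounded(2).upper) == (4.09, 4.31)

    def test_scenario3_inflated_variant_is_wider(self):
        plain = pi_scenario3(4.20, 0.05, 10, 0.95)
        wide = pi_scenario3(4.20, 0.05, 10, 0.95, inflate=True)
        assert (wide.rounded(2).lower, wide.rounded(2).upper) == (4.08, 4.32)
        assert wide.half_width == pytest.approx(
            plain.half_width * math.sqrt(1.1)
        )

    @pytest.mark.parametrize(
        "mean, sd, n, lo, hi",
        [
            # verification-phase IQC run: t(13)·0.07·sqrt(15/14)
            (4.24, 0.07, 14, 4.08, 4.40),
            # patient's own-data glucose series: t(9)·0.16·sqrt(1.1)
            (4.29, 0.16, 10, 3.91, 4.67),
        ],
    )
    def test_scenario4_hand_checked_examples(self, mean, sd, n, lo, hi):
        iv = pi_scenario4(mean, sd, n, 0.95)
        assert (iv.rounded(2).lower, iv.rounded(2).upper) == (lo, hi)

    def test_confidence_interval_hand_checked(self):
        # 4.29 +/- t(9)·0.16/sqrt(10)
        iv = confidence_interval(4.29, 0.16, 10, 0.95)
        assert (iv.rounded(2).lower, iv.rounded(2).upper) == (4.18, 4.40)
        assert iv.kind == "confidence"

    @pytest.mark.parametrize(
        "fn, args",
        [
            (pi_scenario1, (4.2, 0.0, 0.95)),
            (pi_scenario2, (4.2, 0.0, 7, 0.95)),
            (pi_scenario3, (4.2, 0.0, 7, 0.95)),
            (pi_scenario4, (4.2, 0.0, 7, 0.95)),
            (confidence_interval, (4.2, 0.0, 7, 0.95)),
        ],
    )
    def test_zero_dispersion_gives_degenerate_interval(self, fn, args):
        iv = fn(*args)
        assert iv.lower == iv.upper == 4.2

    @pytest.mark.parametrize(
        "fn, args",
        [
            (pi_scenario1, (4.2, -0.1, 0.95)),
            (pi_scenario2, (4.2, 0.1, 0, 0.95)),
            (pi_scenario3, (4.2, 0.1, 1, 0.95)),
            (pi_scenario4, (4.2, 0.1, 1, 0.95)),
            (confidence_interval, (4.2, 0.1, 1, 0.95)),
        ],
    )
    def test_precondition_violations_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestScenarioDispatch:
    @pytest.mark.parametrize(
        "mp, vp, number, family",
        [
            ("population", "population", 1, "z"),
            ("sample", "population", 2, "z"),
            ("population", "sample", 3, "t"),
            ("sample", "sample", 4, "t"),
        ],
    )
    def test_provenance_pair_bijection(self, mp, vp, number, family):
        spec = select_scenario(mp, vp)
        assert spec.scenario_number == number
        assert spec.multiplier_family == family
        assert spec.mean_provenance is Provenance(mp)

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            select_scenario("guess", "sample")


class TestIntervalProperties:
    @given(mean=finite_means, sd=small_sds, n=st.integers(2, 500),
           level=levels)
    def test_all_intervals_symmetric_about_mean(self, mean, sd, n, level):
        for iv in (
            pi_scenario1(mean, sd, level),
            pi_scenario2(mean, sd, n, level),
            pi_scenario3(mean, sd, n, level),
            pi_scenario4(mean, sd, n, level),
            confidence_interval(mean, sd, n, level),
        ):
            assert iv.center == pytest.approx(mean, rel=1e-12)
            assert iv.lower <= iv.upper

    @given(mean=finite_means, sd=st.floats(min_value=1e-3, max_value=50.0),
           level=levels)
    def test_scenario4_half_width_strictly_decreasing_in_n(self, mean, sd,
                                                           level):
        widths = [
            pi_scenario4(mean, sd, n, level).half_width for n in (2, 5, 20, 100)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    @given(mean=finite_means, sd=st.floats(min_value=1e-3, max_value=50.0),
           n=st.integers(2, 500), level=levels)
    def test_ci_strictly_narrower_than_pi(self, mean, sd, n, level):
        ci = confidence_interval(mean, sd, n, level)
        pi = pi_scenario4(mean, sd, n, level)
        assert ci.half_width < pi.half_width

    def test_summarize_then_scenario4_matches_direct_formula(self,
                                                             table5_glucose):
        # brute-force oracle on the 10-value series
        stats = summarize(table5_glucose)
        iv = pi_scenario4(stats.mean, stats.sd, stats.n, 0.95)
        half = t_quantile(9, 0.95) * stats.sd * math.sqrt(1 + 1 / 10)
        assert iv.lower == pytest.approx(stats.mean - half, rel=1e-12)
        assert iv.upper == pytest.approx(stats.mean + half, rel=1e-12)
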