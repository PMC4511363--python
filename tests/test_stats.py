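"""Summary arithmetic: replicates, calibration fits, enrichment, qPCR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qconkit.stats import (
    CalibrationSeries,
    QPCRRecord,
    apply_normalization,
    compare_methods,
    delta_ct_expression,
    enrichment_factor,
    fit_linearity,
    group_stats,
    replicate_summary,
    sd_percent_of_mean,
)


class TestReplicateSummary:
    def test_three_healthy_sera_dcr3(self):
        s = replicate_summary([29.89, 24.95, 26.87])
        assert s.mean == pytest.approx(27.23, abs=0.01)
        assert s.sd == pytest.approx(2.49, abs=0.005)
        assert s.cv_percent == pytest.approx(9.14, abs=0.01)

    def test_three_healthy_sera_gdf15(self):
        s = replicate_summary([97.96, 98.66, 97.72])
        assert s.mean == pytest.approx(98.11, abs=0.005)
        assert s.sd == pytest.approx(0.49, abs=0.005)
        assert s.cv_percent == pytest.approx(0.5, abs=0.005)

    def test_identical_values_have_zero_spread(self):
        s = replicate_summary([5.0, 5.0, 5.0])
        assert s.sd == 0.0 and s.cv_percent == 0.0

    def test_single_value_flags_undefined_sd(self):
        s = replicate_summary([5.0])
        assert not s.sd_defined and math.isnan(s.sd)

    @settings(max_examples=100, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=0.1, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=30,
        )
    )
    def test_matches_two_pass_textbook_oracle(self, values):
        s = replicate_summary(values)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.sd == pytest.approx(math.sqrt(var), rel=1e-9, abs=1e-12)


class TestSdPercentOfMean:
    @pytest.mark.parametrize(
        "sd, mean, expected",
        [
            (79.31, 164.44, 48.2),
            (411.78, 378.1, 108.9),
            (39.25, 62.59, 62.7),
            (0.0, 10.0, 0.0),
        ],
    )
    def test_variability_figures(self, sd, mean, expected):
        assert sd_percent_of_mean(sd, mean) == pytest.approx(expected, abs=0.05)


class TestEnrichmentFactor:
    def test_nominal_bookkeeping(self):
        assert enrichment_factor(94.9, 97.6) == pytest.approx(92.62, abs=0.005)

    def test_full_recovery_is_identity(self):
        assert enrichment_factor(94.9, 100.0) == pytest.approx(94.9)

    def test_strict_mode_uses_concentration_ratio(self):
        assert enrichment_factor(94.9, 100.0, mode="strict") == pytest.approx(
            19.61, abs=0.005
        )

    def test_strict_mode_total_depletion_is_infinite(self):
        assert math.isinf(enrichment_factor(100.0, 50.0, mode="strict"))

    def test_nominal_mode_linear_in_recovery(self):
        f1 = enrichment_factor(94.9, 40.0)
        f2 = enrichment_factor(94.9, 80.0)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)


class TestNormalization:
    def test_albumin_normalisation(self):
        assert apply_normalization(2000.0, 14.52) == pytest.approx(137.74, abs=0.005)

    def test_unit_factor_is_identity(self):
        assert apply_normalization(123.4, 1.0) == 123.4

    def test_round_trip_exact(self):
        assert apply_normalization(137.741, 14.52) * 14.52 == pytest.approx(
            137.741, rel=1e-12
        )


class TestDeltaCt:
    def test_equal_cycles_give_unity(self):
        assert delta_ct_expression(QPCRRecord(ct_target=25.0, ct_reference=25.0)) == 1.0

    def test_one_cycle_earlier_reference_doubles(self):
        assert delta_ct_expression(QPCRRecord(ct_target=24.0, ct_reference=25.0)) == 2.0

    def test_late_target_attenuates(self):
        rec = QPCRRecord(ct_target=28.32, ct_reference=25.0)
        assert delta_ct_expression(rec) == pytest.approx(0.1, abs=0.001)


class TestFitLinearity:
    def test_perfect_proportionality(self):
        series = CalibrationSeries(levels=(10, 30, 100, 300), ratios=((0.2,), (0.6,), (2.0,), (6.0,)))
        fit = fit_linearity(series)
        assert fit.r == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_series(self):
        series = CalibrationSeries(levels=(1, 2, 3), ratios=((3.0,), (2.0,), (1.0,)))
        assert fit_linearity(series).r == pytest.approx(-1.0)

    def test_requires_three_levels(self):
        with pytest.raises(ValueError):
            fit_linearity(CalibrationSeries(levels=(1, 2), ratios=((1.0,), (2.0,))))

    def test_r_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(0)
        levels = (10.0, 30.0, 100.0, 300.0)
        ratios = tuple((l * 0.02 + rng.normal(0, 0.01),) for l in levels)
        base = fit_linearity(CalibrationSeries(levels=levels, ratios=ratios)).r
        scaled = fit_linearity(
            CalibrationSeries(
                levels=tuple(3 * l + 7 for l in levels),
                ratios=tuple((5 * r[0] - 2,) for r in ratios),
            )
        ).r
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_on_means_option(self):
        series = CalibrationSeries(
            levels=(10, 30, 100), ratios=((0.1, 0.3), (0.6,), (2.0,))
        )
        fit = fit_linearity(series, on_means=True)
        assert fit.r == pytest.approx(1.0, abs=0.05)


class TestCompareMethods:
    def test_identical_vectors_perfectly_correlated(self):
        r, _ = compare_methods([1, 2, 3, 4], [1, 2, 3, 4], method="pearson")
        assert r == pytest.approx(1.0)

    def test_spearman_sees_monotone_nonlinear_as_perfect(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [math.exp(v) for v in x]
        rho, _ = compare_methods(x, y, method="spearman")
        r, _ = compare_methods(x, y, method="pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_recovers_generating_correlation(self):
        rng = np.random.default_rng(42)
        n = 200
        shared = rng.normal(size=n)
        x = shared + rng.normal(scale=1.0, size=n)
        y = shared + rng.normal(scale=1.0, size=n)
        r, p = compare_methods(x, y, method="pearson")
        assert r == pytest.approx(0.5, abs=0.15)  # true r = 1/2
        assert p < 0.001

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([1, 1, 1], [1, 2, 3])


class TestGroupStats:
    def test_median_of_one_to_nine(self):
        assert group_stats(range(1, 10)).median == 5.0

    def test_single_value_degenerates(self):
        g = group_stats([7.0])
        assert g.median == g.mean == g.q1 == g.q3 == 7.0
        assert not g.sd_defined

    def test_quartile_ordering_and_whiskers(self):
        rng = np.random.default_rng(1)
        g = group_stats(rng.normal(100, 15, size=50))
        assert g.q1 <= g.median <= g.q3
        assert g.whisker_low == pytest.approx(g.mean - g.sd)
        assert g.whisker_high == pytest.approx(g.mean + g.sd)

    def test_simulated_tumour_group_exceeds_healthy(self):
        from qconkit.simulate import CohortGroup, _truncated_normal

        rng = np.random.default_rng(7)
        healthy = [_truncated_normal(rng, 27.23, 9.47) for _ in range(20)]
        tumour = [_truncated_normal(rng, 116.94, 57.37) for _ in range(20)]
        assert group_stats(tumour).mean > group_stats(healthy).mean
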