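"""Config loading, validation, normalization and triangular sampling."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stroke_cea.parameters import (
    IntervalWarning,
    MRSDistribution,
    ParameterError,
    SchemaError,
    TriangularParam,
    ValidationError,
    default_config_text,
    default_parameter_set,
    draw_parameter_set,
    load_parameter_set,
    normalize_mrs_distribution,
    parameter_report,
    sample_triangular,
    serialize_parameter_set,
    triangular_ppf,
)

USUAL_CARE_ROW = [0.09, 0.19, 0.18, 0.23, 0.13, 0.09, 0.08]  # sums to 0.99
IVT_ROW = [0.32, 0.24, 0.16, 0.11, 0.08, 0.03, 0.06]  # sums to 1.00


def _default_dict():
    return yaml.safe_load(default_config_text())


class TestLoading:
    def test_default_config_headline_values(self, params):
        assert params.short_term.p_accurate_women.mode == 0.29
        assert params.short_term.p_accurate_men.mode == 0.35
        assert params.short_term.p_ivt_within_60min == 0.41
        assert params.short_term.p_adverse_event == 0.02
        assert params.markov.p_death_given_recurrence == 0.0866
        assert params.markov.discount_rate == 0.05
        assert params.markov.horizon_years == 50
        assert params.markov.start_age == 57.8
        assert params.markov.cohort_size == 5513
        assert params.utilities.year1[2].mode == 0.67
        assert params.utilities.later[2].mode == 0.70
        assert params.costs.year1[3].medical.base == 76626
        assert params.extrapolation.annual_hospitalisations == 7471

    def test_every_probability_in_unit_interval(self, params):
        st_ = params.short_term
        probs = [
            st_.p_accurate_women.mode,
            st_.p_accurate_men.mode,
            st_.p_ivt_within_60min,
            st_.p_adverse_event,
            params.markov.p_recurrent_year1.mode,
            params.markov.p_recurrent_later.mode,
            params.markov.p_death_given_recurrence,
            params.markov.p_allcause_mortality_12m.mode,
        ]
        for dist in (st_.dist_ivt, st_.dist_adverse, st_.dist_usual_care):
            probs.extend(dist.modes)
            assert abs(dist.normalized().sum() - 1.0) < 1e-9
        for u in params.utilities.year1 + params.utilities.later:
            probs.append(u.mode)
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_missing_field_names_the_field(self):
        cfg = _default_dict()
        del cfg["short_term"]["p_accurate_women"]
        with pytest.raises(SchemaError, match="p_accurate_women"):
            load_parameter_set(cfg)

    def test_probability_out_of_range_rejected(self):
        cfg = _default_dict()
        cfg["short_term"]["p_adverse_event"] = 1.3
        with pytest.raises(ValidationError, match="p_adverse_event"):
            load_parameter_set(cfg)

    def test_inverted_interval_rejected(self):
        cfg = _default_dict()
        cfg["short_term"]["p_accurate_women"] = {"mode": 0.29, "low": 0.30, "high": 0.28}
        with pytest.raises(ValidationError, match="inverted"):
            load_parameter_set(cfg)

    def test_all_zero_distribution_rejected(self):
        cfg = _default_dict()
        cfg["short_term"]["dist_usual_care"] = [0.0] * 7
        with pytest.raises(ValidationError):
            load_parameter_set(cfg)

    def test_utility_ordering_enforced(self):
        cfg = _default_dict()
        cfg["utilities"]["later"][3] = {"mode": 0.95, "low": 0.9, "high": 1.0}
        with pytest.raises(ValidationError, match="non-increasing"):
            load_parameter_set(cfg)

    def test_published_base_outside_interval_warns_not_fails(self):
        # e.g. the year-1 mRS 5 non-medical cost: base 93 225, interval 52 065-78 688
        with pytest.warns(IntervalWarning):
            ps = load_parameter_set(default_config_text())
        assert ps.costs.year1[5].non_medical.base == 93225

    def test_round_trip_through_serialization(self, params):
        reloaded = load_parameter_set(serialize_parameter_set(params))
        assert reloaded == params
        assert serialize_parameter_set(reloaded) == serialize_parameter_set(params)

    def test_report_lists_every_block(self, params):
        report = parameter_report(params)
        for key in ("p_accurate_women", "dist_usual_care[mrs6]", "utilities.later[mrs5]",
                    "costs.year1[mrs3].medical", "ivt_cost", "ischaemic_fraction"):
            assert key in report


class TestNormalization:
    def test_usual_care_row_rescaled_by_its_sum(self):
        result = normalize_mrs_distribution(USUAL_CARE_ROW)
        expected = np.array(USUAL_CARE_ROW) / sum(USUAL_CARE_ROW)
        np.testing.assert_array_equal(result, expected)
        assert result.sum() == pytest.approx(1.0, abs=1e-12)

    def test_already_normalized_row_unchanged(self):
        result = normalize_mrs_distribution(IVT_ROW)
        np.testing.assert_allclose(result, IVT_ROW, atol=1e-15)

    def test_sum_outside_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="sums to"):
            normalize_mrs_distribution([0.5, 0, 0, 0, 0, 0, 0])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            normalize_mrs_distribution([-0.1, 0.3, 0.2, 0.2, 0.2, 0.1, 0.1])


class TestTriangular:
    def test_degenerate_always_returns_the_point(self):
        p = TriangularParam.fixed(0.41)
        rng = np.random.default_rng(0)
        assert all(sample_triangular(p, rng) == 0.41 for _ in range(10))

    def test_ppf_boundaries_exact(self):
        p = TriangularParam(mode=0.29, low=0.28, high=0.30)
        assert triangular_ppf(p, 0.0) == 0.28
        assert triangular_ppf(p, 1.0) == 0.30
        # the CDF value at the mode maps back to the mode
        fc = (p.mode - p.low) / (p.high - p.low)
        assert triangular_ppf(p, fc) == pytest.approx(p.mode, abs=1e-12)

    def test_sample_mean_matches_closed_form(self):
        p = TriangularParam(mode=0.29, low=0.28, high=0.30)
        rng = np.random.default_rng(2024)
        n = 10**6
        draws = np.array([sample_triangular(p, rng) for _ in range(n)])
        var = (p.low**2 + p.mode**2 + p.high**2
               - p.low * p.mode - p.low * p.high - p.mode * p.high) / 18.0
        se = math.sqrt(var / n)
        assert abs(draws.mean() - p.mean) < 3 * se
        assert p.mean == pytest.approx((0.28 + 0.29 + 0.30) / 3)

    def test_empirical_cdf_matches_analytic(self):
        p = TriangularParam(mode=0.29, low=0.28, high=0.30)
        rng = np.random.default_rng(7)
        draws = np.array([sample_triangular(p, rng) for _ in range(10**5)])
        ks = stats.kstest(draws, stats.triang(c=0.5, loc=0.28, scale=0.02).cdf)
        assert ks.statistic < 0.01

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_samples_always_inside_support(self, a, b, c, u):
        lo, mid, hi = sorted((a, b, c))
        p = TriangularParam(mode=mid, low=lo, high=hi)
        x = triangular_ppf(p, u)
        assert lo <= x <= hi

    def test_inverted_support_rejected(self):
        with pytest.raises(ParameterError):
            TriangularParam(mode=0.5, low=0.9, high=0.1)


class TestDraws:
    def test_fixed_parameters_never_move(self, params):
        rng = np.random.default_rng(5)
        drawn = draw_parameter_set(params, rng)
        assert drawn.short_term.p_ivt_within_60min == 0.41
        assert drawn.short_term.p_adverse_event == 0.02
        assert drawn.markov.p_death_given_recurrence == 0.0866
        # published without a distribution -> fixed
        np.testing.assert_array_equal(
            drawn.short_term.dist_adverse.modes, params.short_term.dist_adverse.modes
        )
        # zero-width interval -> fixed
        assert drawn.markov.p_recurrent_later.mode == 0.02

    def test_drawn_set_respects_invariants(self, params):
        rng = np.random.default_rng(17)
        for _ in range(25):
            drawn = draw_parameter_set(params, rng)
            for dist in (drawn.short_term.dist_ivt, drawn.short_term.dist_usual_care):
                assert abs(dist.modes.sum() - 1.0) < 1e-9
            for u, base in zip(drawn.utilities.year1, params.utilities.year1):
                assert base.low <= u.mode <= base.high
            assert 0.28 <= drawn.short_term.p_accurate_women.mode <= 0.30

    def test_draws_reproducible_given_seed(self, params):
        a = draw_parameter_set(params, np.random.default_rng(99))
        b = draw_parameter_set(params, np.random.default_rng(99))
        assert serialize_parameter_set(a) == serialize_parameter_set(b)
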