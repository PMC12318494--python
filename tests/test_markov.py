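"""Markov engine: transition construction, cohort propagation and accrual."""

import numpy as np
import pytest

from stroke_cea.lifetable import LifeTable
from stroke_cea.markov import (
    EngineOptions,
    accrue_outcomes,
    build_cycle_matrix,
    recurrence_transition,
    residual_year1_mortality,
    run_cohort,
)
from stroke_cea.parameters import DEAD_STATE, TriangularParam, ValidationError
from stroke_cea.tree import evaluate_tree


def _quiet(params, discount=0.0, horizon=50):
    """Copy of the default set with no recurrence and no first-year mortality."""
    ps = params.copy()
    ps.markov.p_recurrent_year1 = TriangularParam.fixed(0.0)
    ps.markov.p_recurrent_later = TriangularParam.fixed(0.0)
    ps.markov.p_allcause_mortality_12m = TriangularParam.fixed(0.0)
    ps.markov.discount_rate = discount
    ps.markov.horizon_years = horizon
    return ps


def _unit_vector(state):
    v = np.zeros(7)
    v[state] = 1.0
    return v


class TestRecurrenceTransition:
    def test_from_best_state_splits_equally_over_worse(self):
        out = recurrence_transition(0, 0.0866)
        assert out[DEAD_STATE] == 0.0866
        np.testing.assert_allclose(out[1:6], (1 - 0.0866) / 5)
        assert out[0] == 0.0

    def test_from_mrs5_survivors_stay(self):
        out = recurrence_transition(5, 0.0866)
        assert out[DEAD_STATE] == 0.0866
        assert out[5] == pytest.approx(0.9134)

    def test_from_mrs4_single_worse_state(self):
        out = recurrence_transition(4, 0.0866)
        assert out[5] == pytest.approx(0.9134)
        assert out[4] == 0.0

    def test_dead_state_rejected(self):
        with pytest.raises(ValidationError):
            recurrence_transition(6, 0.1)

    @pytest.mark.parametrize("state", range(6))
    def test_rows_are_distributions(self, state):
        out = recurrence_transition(state, 0.0866)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out >= 0)
        # mass only on strictly-worse states (or self for mRS 5) and death
        assert np.all(out[:state] == 0)


class TestCycleMatrix:
    def test_no_events_is_identity(self, params, immortal_lifetable):
        ps = _quiet(params)
        m = build_cycle_matrix(2, ps.markov, immortal_lifetable, 60.0)
        np.testing.assert_array_equal(m, np.eye(7))

    def test_certain_background_death_absorbs_everyone(self, params):
        ps = _quiet(params)
        lt = LifeTable("female", np.array([60, 61]), np.array([1.0, 1.0]))
        m = build_cycle_matrix(2, ps.markov, lt, 60.0)
        np.testing.assert_allclose(m[:, DEAD_STATE], 1.0)

    def test_hand_expanded_row(self, params):
        """p_recur 0.02, background q 0.01, case fatality 0.0866: the mRS 0 row."""
        ps = params.copy()
        ps.markov.p_recurrent_later = TriangularParam.fixed(0.02)
        lt = LifeTable("female", np.array([60, 61]), np.array([0.01, 0.01]))
        m = build_cycle_matrix(2, ps.markov, lt, 60.0)
        assert m[0, 0] == pytest.approx(0.98 * 0.99)  # 0.9702
        assert m[0, DEAD_STATE] == pytest.approx(0.02 * 0.0866 + 0.98 * 0.01)  # 0.011532
        np.testing.assert_allclose(m[0, 1:6], 0.02 * (1 - 0.0866) / 5)
        assert m[0].sum() == pytest.approx(1.0)

    def test_rows_stochastic_for_default_inputs(self, params, lifetable):
        for cycle, age in ((1, 57.8), (2, 58.8), (30, 86.8)):
            m = build_cycle_matrix(cycle, params.markov, lifetable, age, d90=0.08 if cycle == 1 else None)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(m >= 0)

    def test_age_below_table_rejected(self, params):
        lt = LifeTable("female", np.array([60, 61]), np.array([0.01, 0.01]))
        with pytest.raises(Exception):
            build_cycle_matrix(2, params.markov, lt, 30.0)


class TestResidualYear1Mortality:
    def test_tops_up_to_the_twelve_month_total(self):
        q = residual_year1_mortality(0.12, 0.08)
        assert q == pytest.approx((0.12 - 0.08) / (1 - 0.08))

    def test_never_negative(self):
        assert residual_year1_mortality(0.05, 0.10) == 0.0


class TestRunCohort:
    def test_all_dead_initially_accrues_nothing_alive(self, params, lifetable):
        trace = run_cohort(_unit_vector(DEAD_STATE), params, lifetable)
        res = accrue_outcomes(trace, params.utilities, params.costs, params.markov)
        assert res.life_years == 0.0
        assert res.qalys == 0.0
        # only the one-off first-year death cost is charged
        death = params.costs.death_year1
        expected = death.medical.base + death.non_medical.base + death.indirect.base
        assert res.total_cost == pytest.approx(expected)
        assert np.all(trace.cost[1:] == 0)

    def test_immortal_cohort_accrues_full_horizon(self, params, immortal_lifetable):
        ps = _quiet(params, discount=0.0)
        trace = run_cohort(_unit_vector(0), ps, immortal_lifetable)
        res = accrue_outcomes(
            trace, ps.utilities, ps.costs, ps.markov, EngineOptions(half_cycle=False)
        )
        assert res.life_years == pytest.approx(50.0)

    def test_discounted_immortal_cohort_is_annuity_due(self, params, immortal_lifetable):
        ps = _quiet(params, discount=0.05)
        trace = run_cohort(_unit_vector(0), ps, immortal_lifetable)
        res = accrue_outcomes(
            trace, ps.utilities, ps.costs, ps.markov, EngineOptions(half_cycle=False)
        )
        expected = sum(1.05 ** -(t - 1) for t in range(1, 51))  # 19.1687...
        assert res.life_years == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(19.1687, abs=5e-5)

    def test_probability_conserved_and_death_monotone(self, params, lifetable):
        tree = evaluate_tree(0.29, params.short_term)
        trace = run_cohort(tree.mrs_distribution, params, lifetable)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, DEAD_STATE]) >= -1e-12)

    def test_unnormalized_initial_rejected(self, params, lifetable):
        with pytest.raises(ValidationError):
            run_cohort(np.full(7, 0.2), params, lifetable)


class TestAccrual:
    def test_unit_utilities_make_qalys_equal_life_years(self, params, lifetable):
        ps = params.copy()
        one = TriangularParam.fixed(1.0)
        ps.utilities.year1 = (one,) * 6
        ps.utilities.later = (one,) * 6
        tree = evaluate_tree(0.29, ps.short_term)
        trace = run_cohort(tree.mrs_distribution, ps, lifetable)
        res = accrue_outcomes(trace, ps.utilities, ps.costs, ps.markov)
        assert res.qalys == pytest.approx(res.life_years, abs=1e-12)

    def test_two_cycle_utility_phases(self, params, immortal_lifetable):
        """Year-1 utility applies in cycle 1 only; mRS 2: 0.67 then 0.70."""
        ps = _quiet(params, discount=0.0, horizon=2)
        trace = run_cohort(_unit_vector(2), ps, immortal_lifetable)
        res = accrue_outcomes(
            trace, ps.utilities, ps.costs, ps.markov, EngineOptions(half_cycle=False)
        )
        assert res.qalys == pytest.approx(0.67 + 0.70)

    def test_half_cycle_boundary_contributes_half(self, params):
        """A cohort fully alive at cycle start and dead at cycle end earns 0.5 LY."""
        ps = _quiet(params, discount=0.0, horizon=1)
        lt = LifeTable("female", np.array([57, 58]), np.array([0.0, 0.0]))
        ps.markov.p_allcause_mortality_12m = TriangularParam.fixed(1.0)
        trace = run_cohort(_unit_vector(0), ps, lt)
        assert trace.occupancy[1, DEAD_STATE] == pytest.approx(1.0)
        res = accrue_outcomes(
            trace, ps.utilities, ps.costs, ps.markov, EngineOptions(half_cycle=True)
        )
        assert res.life_years == pytest.approx(0.5)

    def test_discounting_monotone_in_rate(self, params, lifetable):
        results = []
        for rate in (0.0, 0.03, 0.05, 0.08):
            ps = params.copy()
            ps.markov.discount_rate = rate
            tree = evaluate_tree(0.29, ps.short_term)
            trace = run_cohort(tree.mrs_distribution, ps, lifetable)
            results.append(accrue_outcomes(trace, ps.utilities, ps.costs, ps.markov))
        for a, b in zip(results, results[1:]):
            assert b.life_years < a.life_years
            assert b.qalys < a.qalys
            assert b.total_cost < a.total_cost

    def test_discounted_never_exceeds_undiscounted(self, params, lifetable):
        tree = evaluate_tree(0.29, params.short_term)
        trace = run_cohort(tree.mrs_distribution, params, lifetable)
        res = accrue_outcomes(trace, params.utilities, params.costs, params.markov)
        assert np.all(trace.ly_disc <= trace.ly + 1e-15)
        assert res.life_years <= res.life_years_undiscounted
        assert res.qalys <= res.life_years

    def test_end_convention_discounts_every_cycle_once_more(self, params, lifetable):
        tree = evaluate_tree(0.29, params.short_term)
        results = {}
        for conv in ("start", "end"):
            trace = run_cohort(tree.mrs_distribution, params, lifetable)
            results[conv] = accrue_outcomes(
                trace, params.utilities, params.costs, params.markov,
                EngineOptions(discount_convention=conv),
            )
        ratio = results["end"].life_years / results["start"].life_years
        assert ratio == pytest.approx(1 / 1.05, abs=1e-12)

    def test_trace_export_has_one_row_per_cycle(self, params, lifetable):
        tree = evaluate_tree(0.29, params.short_term)
        trace = run_cohort(tree.mrs_distribution, params, lifetable)
        accrue_outcomes(trace, params.utilities, params.costs, params.markov)
        df = trace.to_frame()
        assert len(df) == params.markov.horizon_years
        for col in ("mrs0", "mrs6", "age", "ly", "ly_disc", "qaly_disc", "cost_disc"):
            assert col in df.columns
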