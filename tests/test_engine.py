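"""Transition-matrix assembly and cohort iteration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfcea.engine import (
    IDX_DEAD_CV,
    IDX_DEAD_NONCV,
    build_cycle_matrix,
    cumulative_event_rates,
    median_survival,
    run_cohort,
    survival_curve,
)
from hfcea.params import paper_default_params


def _no_mortality(defaults):
    p = defaults.copy()
    for arm in p.arms.values():
        arm.cv_death_per_cycle = 0.0
    from hfcea.params import AgeMortalityTable

    p.noncv_mortality = AgeMortalityTable(((0.0, 200.0, 0.0),))
    return p


class TestBuildCycleMatrix:
    def test_no_mortality_limit_recovers_nyha_block(self, defaults):
        p = _no_mortality(defaults)
        mat = build_cycle_matrix(
            p.strategy("dapagliflozin"), p.nyha_matrix, p.noncv_mortality, 66.0
        )
        assert np.allclose(mat[:4, :4], defaults.nyha_matrix.rows)
        assert np.allclose(mat[:4, 4:], 0.0)

    def test_certain_death_limit(self, defaults):
        p = defaults.copy()
        p.arms["dapagliflozin"].cv_death_per_cycle = 1.0
        from hfcea.params import AgeMortalityTable

        p.noncv_mortality = AgeMortalityTable(((0.0, 200.0, 0.0),))
        mat = build_cycle_matrix(
            p.strategy("dapagliflozin"), p.nyha_matrix, p.noncv_mortality, 66.0
        )
        assert np.allclose(mat[:4, IDX_DEAD_CV], 1.0)
        assert np.allclose(mat[:4, :4], 0.0)

    def test_dapagliflozin_row_hand_computed(self, defaults):
        # survivors share = 1 - 0.01650 - 0.00243 = 0.98107; NYHA II row of the
        # class-transition table scaled by it, death entries appended
        mat = build_cycle_matrix(
            defaults.strategy("dapagliflozin"),
            defaults.nyha_matrix,
            defaults.noncv_mortality,
            66.0,
        )
        expected = [0.00784856, 0.96242967, 0.0098107, 0.00098107]
        assert np.allclose(mat[1, :4], expected, atol=1e-12)
        assert mat[1, IDX_DEAD_CV] == pytest.approx(0.01650)
        assert mat[1, IDX_DEAD_NONCV] == pytest.approx(0.00243)

    def test_death_rows_absorbing_and_rows_stochastic(self, defaults):
        for age in (66.0, 72.0, 78.0, 90.0):
            mat = build_cycle_matrix(
                defaults.strategy("control2"),
                defaults.nyha_matrix,
                defaults.noncv_mortality,
                age,
            )
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
            assert mat[IDX_DEAD_CV, IDX_DEAD_CV] == 1.0
            assert mat[IDX_DEAD_NONCV, IDX_DEAD_NONCV] == 1.0

    def test_excess_mortality_rejected(self, defaults):
        p = defaults.copy()
        p.arms["control1"].cv_death_per_cycle = 0.999
        from hfcea.params import AgeMortalityTable

        p.noncv_mortality = AgeMortalityTable(((0.0, 200.0, 0.5),))
        with pytest.raises(ValueError):
            build_cycle_matrix(
                p.strategy("control1"), p.nyha_matrix, p.noncv_mortality, 66.0
            )


class TestRunCohort:
    def test_zero_horizon(self, defaults):
        trace = run_cohort(defaults, "dapagliflozin", horizon_years=0.0)
        assert trace.n_cycles == 0
        assert trace.occupancy.shape == (1, 6)
        assert trace.expected_hospitalizations.size == 0

    def test_initial_distribution_placed_on_nyha_states(self, defaults):
        trace = run_cohort(defaults, "control1")
        assert np.allclose(
            trace.occupancy[0, :4], defaults.settings.initial_distribution
        )
        assert trace.occupancy[0, 4:].sum() == 0.0

    def test_conservation_and_monotone_death(self, defaults):
        for name in defaults.arms:
            trace = run_cohort(defaults, name)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(trace.occupancy >= -1e-15)
            dead = trace.occupancy[:, 4:].sum(axis=1)
            assert np.all(np.diff(dead) >= -1e-15)
            alive = trace.alive()
            assert np.all(np.diff(alive) <= 1e-15)

    def test_no_mortality_conserves_alive(self, defaults):
        p = _no_mortality(defaults)
        trace = run_cohort(p, "dapagliflozin")
        assert np.allclose(trace.alive(), 1.0, atol=1e-12)

    def test_readmissions_proportional_to_hospitalizations(self, defaults):
        trace = run_cohort(defaults, "empagliflozin")
        assert np.allclose(
            trace.expected_readmissions,
            trace.expected_hospitalizations * defaults.readmit_per_hosp,
        )

    def test_hospitalizations_at_risk_is_alive_at_cycle_start(self, defaults):
        trace = run_cohort(defaults, "control2")
        alive_start = trace.alive()[:-1]
        assert np.allclose(
            trace.expected_hospitalizations,
            alive_start * defaults.strategy("control2").hosp_per_cycle,
        )

    def test_unknown_strategy(self, defaults):
        with pytest.raises(KeyError):
            run_cohort(defaults, "placebo")

    def test_dataframe_export_schema(self, defaults):
        df = run_cohort(defaults, "dapagliflozin").to_dataframe()
        assert len(df) == 41
        assert {"strategy", "cycle", "time_years", "age", "alive",
                "NYHA2", "DEAD_CV"} <= set(df.columns)
        assert df["age"].iloc[-1] == pytest.approx(76.0)


class TestSurvivalSummaries:
    def test_survival_curve_starts_at_one_and_declines(self, defaults):
        curve = survival_curve(run_cohort(defaults, "dapagliflozin"))
        assert curve[0, 1] == pytest.approx(1.0)
        assert np.all(np.diff(curve[:, 1]) <= 1e-15)

    def test_median_censored_when_no_mortality(self, defaults):
        trace = run_cohort(_no_mortality(defaults), "dapagliflozin")
        assert math.isinf(median_survival(trace))

    def test_median_immediate_crossing(self, defaults):
        p = defaults.copy()
        p.arms["control1"].cv_death_per_cycle = 0.6
        trace = run_cohort(p, "control1")
        assert median_survival(trace) == 0.25

    def test_cumulative_rates_zero_at_time_zero(self, defaults):
        trace = run_cohort(defaults, "dapagliflozin")
        assert cumulative_event_rates(trace, 0.0) == (0.0, 0.0, 0.0)

    def test_cumulative_rates_zero_for_eventless_cohort(self, defaults):
        p = _no_mortality(defaults)
        for arm in p.arms.values():
            arm.hosp_per_cycle = 0.0
        trace = run_cohort(p, "empagliflozin")
        assert cumulative_event_rates(trace, 18.0) == (0.0, 0.0, 0.0)

    def test_cumulative_rates_range_checks(self, defaults):
        trace = run_cohort(defaults, "dapagliflozin")
        with pytest.raises(ValueError):
            cumulative_event_rates(trace, 121.0)
        with pytest.raises(ValueError):
            cumulative_event_rates(trace, 17.0)  # not a cycle multiple


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    cv=st.floats(0.0, 0.2),
    hosp=st.floats(0.0, 0.3),
    horizon=st.sampled_from([1.0, 2.5, 10.0]),
)
def test_occupancy_conserved_for_arbitrary_inputs(cv, hosp, horizon):
    p = paper_default_params()
    p.arms["dapagliflozin"].cv_death_per_cycle = cv
    p.arms["dapagliflozin"].hosp_per_cycle = hosp
    trace = run_cohort(p, "dapagliflozin", horizon_years=horizon)
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(np.diff(trace.alive()) <= 1e-15)
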