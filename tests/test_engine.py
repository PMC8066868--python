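"""Markov cohort engine: transition construction, recursion, accounting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prscreen import (
    ValidationError,
    accumulate,
    diagnosis_probability,
    mix_arms,
    run_cohort,
    run_strategy,
    transition_matrix,
)
from prscreen.engine import DEAD, HEALTHY, ArmOutcomes, run_arm
from prscreen.parameters import STAGES, baseline_parameters
from prscreen.strategies import ScreeningSchedule, build_current_strategy, build_tailored_strategy
from prscreen.synthetic import SyntheticSpec, generate_parameter_set

EMPTY_SCHEDULE = ScreeningSchedule(screen_ages=(), modality_by_age={})


def zero_rate_params(params):
    """All incidence and mortality switched off."""
    return dataclasses.replace(
        params,
        asir=dataclasses.replace(
            params.asir, bands=tuple((lo, hi, 0.0) for lo, hi, _ in params.asir.bands)
        ),
        mortality=dataclasses.replace(
            params.mortality, stage_rate={s: 0.0 for s in STAGES}, all_cause=0.0
        ),
    )


class TestDiagnosisProbability:
    def test_screen_detection_is_product_of_table_inputs(self, params):
        # 0.001775 x 0.53 x 0.8 x 2
        p = diagnosis_probability(52, "I", 2.0, True, params)
        assert p == pytest.approx(0.00150520, rel=1e-12)
        p = diagnosis_probability(37, "IV", 0.5, True, params)
        assert p == pytest.approx(0.000002468, rel=1e-12)

    def test_no_offscreen_detection_in_screen_only_mode(self, params):
        ps = params.replace_config(detection_mode="screen_only")
        assert diagnosis_probability(52, "I", 1.0, False, ps) == 0.0

    def test_interval_detection_uses_unscreened_mix_without_sensitivity(self, params):
        ps = params.replace_config(detection_mode="screen_plus_interval")
        p = diagnosis_probability(52, "II", 1.0, False, ps)
        assert p == pytest.approx(0.001775 * 0.57, rel=1e-12)

    def test_preentry_mode_detects_clinically_only_before_coverage(self, params):
        kw = dict(age=45, stage="II", multiplier=1.0, is_screen_cycle=False, params=params)
        assert diagnosis_probability(in_coverage=False, **kw) == pytest.approx(0.001733 * 0.57)
        assert diagnosis_probability(in_coverage=True, **kw) == 0.0

    def test_negative_multiplier_rejected(self, params):
        with pytest.raises(ValidationError):
            diagnosis_probability(52, "I", -1.0, True, params)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self, params):
        for age in (35, 52, 74):
            for screen in (True, False):
                m = transition_matrix(age, 1.0, screen, params)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert (m >= 0).all()

    def test_dead_row_absorbing(self, params):
        m = transition_matrix(52, 1.0, True, params)
        assert m[DEAD].tolist() == [0, 0, 0, 0, 0, 1]

    def test_stage_iv_row_combines_cause_specific_and_background_mortality(self, params):
        m = transition_matrix(52, 1.0, True, params)
        assert m[4, DEAD] == pytest.approx(0.268 + 0.002896)
        assert m[4, 4] == pytest.approx(1 - 0.268 - 0.002896)

    def test_healthy_row_without_detection(self, params):
        ps = params.replace_config(detection_mode="screen_only")
        m = transition_matrix(52, 1.0, False, ps)
        assert m[HEALTHY, HEALTHY] == pytest.approx(1 - 0.002896)
        assert m[HEALTHY, DEAD] == pytest.approx(0.002896)

    def test_infeasible_exit_mass_raises(self, params):
        bands = tuple((lo, hi, 1.0) for lo, hi, _ in params.asir.bands)
        ps = dataclasses.replace(params, asir=dataclasses.replace(params.asir, bands=bands))
        ps = ps.replace_config(detection_mode="screen_plus_interval")
        from prscreen import InfeasibleParametersError

        with pytest.raises(InfeasibleParametersError):
            transition_matrix(52, 2.0, False, ps)


class TestRunCohort:
    def test_all_rates_zero_stays_healthy(self, params):
        trace = run_cohort(EMPTY_SCHEDULE, 1.0, zero_rate_params(params))
        assert trace.occupancy[:, HEALTHY] == pytest.approx(1.0)
        assert trace.new_diagnoses.sum() == 0.0

    def test_flat_hazard_death_closed_form(self, params):
        # no screens + screen-only detection: only the flat background hazard acts
        ps = params.replace_config(detection_mode="screen_only")
        trace = run_cohort(EMPTY_SCHEDULE, 1.0, ps)
        q = params.mortality.all_cause
        expected = 1.0 - (1.0 - q) ** 40
        assert trace.occupancy[-1, DEAD] == pytest.approx(expected, rel=1e-12)

    def test_trace_covers_horizon(self, params, current):
        trace = run_cohort(current.arms[0].schedule, 1.0, params)
        assert trace.n_cycles == 40
        assert trace.ages[0] == 35 and trace.ages[-1] == 74

    def test_conservation_and_monotonicity(self, params, current):
        trace = run_cohort(current.arms[0].schedule, 1.0, params)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, DEAD]
        assert (np.diff(dead) >= -1e-15).all()
        assert (trace.new_diagnoses >= 0).all()


class TestAccumulate:
    def test_zero_discount_no_events_gives_full_life_years(self, params):
        ps = zero_rate_params(params).replace_config(discount_rate=0.0)
        trace = run_cohort(EMPTY_SCHEDULE, 1.0, ps)
        out = accumulate(trace, EMPTY_SCHEDULE, 0.0, ps)
        assert out.life_years == pytest.approx(40.0)
        assert out.qalys == pytest.approx(40.0)
        assert out.discounted_cost == 0.0

    def test_discount_factor_convention(self, params):
        # t=0 at entry: a full survivor's discounted LY is sum of 1.03^-t
        ps = zero_rate_params(params)
        trace = run_cohort(EMPTY_SCHEDULE, 1.0, ps)
        out = accumulate(trace, EMPTY_SCHEDULE, 0.0, ps)
        expected = sum(1.03 ** -t for t in range(40))
        assert out.life_years == pytest.approx(expected, rel=1e-12)

    def test_stage_cost_charged_once_at_diagnosis(self, params):
        # whole cohort diagnosed stage I in cycle 0 -> cost includes 63,983.00
        ps = params.replace_config(stage_cost_mode="once_at_diagnosis", discount_rate=0.0)
        trace = run_cohort(EMPTY_SCHEDULE, 1.0, ps)
        diag = np.zeros((40, 4))
        diag[0, 0] = 1.0  # everyone diagnosed stage I at entry
        trace = dataclasses.replace(trace, new_diagnoses=diag)
        out_cost = accumulate(trace, EMPTY_SCHEDULE, 0.0, ps).discounted_cost
        assert out_cost == pytest.approx(63983.00)

    def test_entry_costs_land_undiscounted(self, params):
        trace = run_cohort(EMPTY_SCHEDULE, 1.0, zero_rate_params(params))
        out = accumulate(trace, EMPTY_SCHEDULE, 212.0, zero_rate_params(params))
        assert out.discounted_cost == pytest.approx(212.0)

    def test_screen_costs_charged_to_healthy(self, params):
        ps = zero_rate_params(params).replace_config(discount_rate=0.0)
        sched = ScreeningSchedule((50, 52), {50: "mammogram", 52: "mammogram"})
        out = accumulate(run_cohort(sched, 1.0, ps), sched, 0.0, ps)
        assert out.discounted_cost == pytest.approx(2 * 110.0)


class TestMixArms:
    def test_single_arm_identity(self, params, current):
        out, _ = run_arm(current.arms[0], 0.0, params)
        assert mix_arms([(1.0, out)]) == out

    def test_mix_of_identical_arms_is_identity(self, params, current):
        out, _ = run_arm(current.arms[0], 0.0, params)
        assert mix_arms([(0.5, out), (0.5, out)]).qalys == pytest.approx(out.qalys)

    def test_weights_must_sum_to_one(self, params, current):
        out, _ = run_arm(current.arms[0], 0.0, params)
        with pytest.raises(ValidationError):
            mix_arms([(0.6, out), (0.2, out)])


class TestStrategyLevelProperties:
    @pytest.mark.parametrize("mode", ["screen_only", "screen_plus_interval", "screen_plus_preentry"])
    def test_qaly_never_exceeds_life_years(self, params, current, tailored, mode):
        ps = params.replace_config(detection_mode=mode)
        for strategy in (current, tailored):
            out = run_strategy(strategy, ps)
            assert out.qalys <= out.life_years + 1e-12

    def test_discounting_reduces_every_outcome(self, params, current, tailored):
        for strategy in (current, tailored):
            disc = run_strategy(strategy, params)
            undisc = run_strategy(strategy, params.replace_config(discount_rate=0.0))
            assert disc.discounted_cost <= undisc.discounted_cost
            assert disc.life_years <= undisc.life_years
            assert disc.qalys <= undisc.qalys

    def test_doubling_incidence_increases_cases(self, params, current):
        doubled = dataclasses.replace(
            params,
            asir=dataclasses.replace(
                params.asir,
                bands=tuple((lo, hi, 2 * r) for lo, hi, r in params.asir.bands),
            ),
        )
        assert (
            run_strategy(current, doubled).cases_per_1000
            > run_strategy(current, params).cases_per_1000
        )

    def test_half_cycle_correction_changes_but_preserves_order(self, params, current):
        out = run_strategy(current, params)
        hcc = run_strategy(current, params.replace_config(half_cycle_correction=True))
        assert hcc.life_years != out.life_years
        assert hcc.qalys <= hcc.life_years


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10**6), mode_ix=st.integers(0, 2))
def test_invariants_hold_on_random_parameter_sets(seed, mode_ix):
    """Conservation, dead-monotonicity and QALY<=LY for synthetic inputs."""
    mode = ("screen_only", "screen_plus_interval", "screen_plus_preentry")[mode_ix]
    ps = generate_parameter_set(SyntheticSpec(seed=seed)).replace_config(
        detection_mode=mode
    )
    strategy = build_tailored_strategy(ps.strat, ps.config)
    for arm in strategy.arms:
        trace = run_cohort(arm.schedule, arm.multiplier, ps, arm.coverage_start_age)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-15).all()
        out = accumulate(trace, arm.schedule, 0.0, ps)
        assert out.qalys <= out.life_years + 1e-12
        assert 0.0 <= out.death_probability <= 1.0
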