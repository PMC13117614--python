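import numpy as np
import pytest

from lcs_cea import (
    allocate_baseline,
    discount_factor,
    run_arm,
    run_deterministic,
    state_from_baseline,
    step_cohort,
)
from lcs_cea.markov_engine import N_STATES, STATE_NAMES, CohortState

from conftest import make_toy_params

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class TestDiscountFactor:
    def test_known_values(self):
        assert discount_factor(0.0, 0.03) == 1.0
        assert discount_factor(1.0, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(7.5, 0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.25, 0.03)


def _state(masses: dict, age: float) -> CohortState:
    occ = np.zeros(N_STATES)
    for name, m in masses.items():
        occ[_IDX[name]] = m
    return CohortState(cycle_index=0, age=age, occupancy=occ)


class TestStepCohort:
    def test_hand_computed_undiagnosed_transitions(self):
        """Event order: other-cause death, then diagnosis, then progression."""
        params = make_toy_params(
            p_progress=(0.2, 0.0, 0.0), p_diagnose=(0.3, 0.0, 0.0, 0.0)
        )
        for sex in params.transitions.p_oc_death_3m:
            params.transitions.p_oc_death_3m[sex] = {
                **{a: 0.1 for a in range(55, 100)}, 100: 1.0
            }
        state = _state({"undiag_I": 1.0}, age=80.0)
        nxt = step_cohort(state, params, params.strata[0], "standard_care")
        assert nxt["dead_other"] == pytest.approx(0.1)
        assert nxt["diag_I_slot0"] == pytest.approx(0.9 * 0.3)
        assert nxt["undiag_II"] == pytest.approx(0.9 * 0.7 * 0.2)
        assert nxt["undiag_I"] == pytest.approx(0.9 * 0.7 * 0.8)
        assert nxt.age == pytest.approx(80.25)
        assert nxt.occupancy.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dead_state_is_absorbing(self, toy_params):
        state = _state({"dead_other": 1.0}, age=80.0)
        nxt = step_cohort(state, toy_params, toy_params.strata[0], "standard_care")
        assert nxt["dead_other"] == 1.0
        assert nxt.alive == 0.0

    def test_zero_probabilities_leave_occupancy_unchanged(self):
        params = make_toy_params(
            p_progress=(0.0, 0.0, 0.0), p_diagnose=(0.0, 0.0, 0.0, 0.0)
        )
        state = _state({"no_lc": 0.5, "undiag_III": 0.5}, age=70.0)
        nxt = step_cohort(state, params, params.strata[0], "standard_care")
        assert nxt["no_lc"] == 0.5
        assert nxt["undiag_III"] == 0.5
        assert nxt.cycle_index == 1

    def test_tunnel_slots_advance_and_cap(self, toy_params):
        state = _state({"diag_II_slot3": 0.4, "diag_II_slot20": 0.6}, age=70.0)
        nxt = step_cohort(state, toy_params, toy_params.strata[0], "screening")
        assert nxt["diag_II_slot4"] == pytest.approx(0.4)
        assert nxt["diag_II_slot20"] == pytest.approx(0.6)

    def test_screening_arm_rejects_undiagnosed_mass(self, toy_params):
        state = _state({"undiag_I": 1.0}, age=70.0)
        with pytest.raises(ValueError, match="undiagnosed"):
            step_cohort(state, toy_params, toy_params.strata[0], "screening")

    def test_matches_vectorised_engine(self, calibrated_params):
        """Scalar stepping and the vectorised kernel stay in lockstep."""
        stratum = calibrated_params.stratum("female:70-74")
        baseline = allocate_baseline(stratum, calibrated_params, "standard_care")
        res = run_arm(baseline, calibrated_params, stratum, trace=True)
        state = state_from_baseline(baseline, stratum)
        for cycle in range(12):
            row = res.trace.iloc[cycle]
            np.testing.assert_allclose(
                state.occupancy,
                row[STATE_NAMES].to_numpy(dtype=float),
                atol=1e-12,
                err_msg=f"cycle {cycle}",
            )
            state = step_cohort(state, calibrated_params, stratum, "standard_care")


class TestRunArm:
    def test_life_expectancy_closed_form(self):
        """No mortality until forced death at 100, utility 1, no discounting:
        life years equal 100 minus starting age, within half a cycle."""
        params = make_toy_params(prevalence=0.0, oc_annual=0.0, discount=0.0)
        stratum = params.strata[0]  # enters at exactly age 80
        baseline = allocate_baseline(stratum, params, "standard_care")
        res = run_arm(baseline, params, stratum)
        assert abs(res.life_years - (100 - 80)) <= 0.125 + 1e-9
        assert res.qalys == pytest.approx(res.life_years)

    def test_dead_cohort_accrues_only_oneoff_costs(self, toy_params):
        stratum = toy_params.strata[0]
        baseline = allocate_baseline(stratum, toy_params, "screening")
        baseline.occupancy = {k: 0.0 for k in baseline.occupancy}
        state = state_from_baseline(baseline, stratum)
        assert state.alive == 0.0  # a fully dead cohort has no dynamics left

    def test_discounted_totals_not_larger_than_undiscounted(self, calibrated_params):
        p0 = calibrated_params.copy_deep()
        p0.econ.annual_discount_rate = 0.0
        stratum = calibrated_params.strata[2]
        for arm in ("screening", "standard_care"):
            baseline = allocate_baseline(stratum, calibrated_params, arm)
            disc = run_arm(baseline, calibrated_params, stratum)
            undisc = run_arm(allocate_baseline(stratum, p0, arm), p0, stratum)
            assert disc.life_years <= undisc.life_years + 1e-12
            assert disc.qalys <= undisc.qalys + 1e-12

    def test_lifetime_deaths_partition(self, calibrated_params):
        for stratum in calibrated_params.strata[::4]:
            for arm in ("screening", "standard_care"):
                baseline = allocate_baseline(stratum, calibrated_params, arm)
                res = run_arm(baseline, calibrated_params, stratum)
                assert res.lc_deaths + res.oc_deaths == pytest.approx(1.0, abs=1e-9)
                assert res.qalys <= res.life_years + 1e-12

    def test_screening_trace_has_no_undiagnosed_mass(self, calibrated_params):
        stratum = calibrated_params.strata[0]
        baseline = allocate_baseline(stratum, calibrated_params, "screening")
        res = run_arm(baseline, calibrated_params, stratum, trace=True)
        undiag_cols = [c for c in res.trace.columns if c.startswith("undiag_")]
        assert res.trace[undiag_cols].to_numpy().max() == 0.0

    def test_zero_discount_no_half_cycle_equals_riemann_sum(self):
        """Regression guard: the correction code reduces to the plain
        end-of-cycle Riemann sum when both features are off."""
        params = make_toy_params(
            oc_annual=0.10, lc_death=0.05, prevalence=0.05,
            discount=0.0, half_cycle=False,
        )
        stratum = params.strata[0]
        baseline = allocate_baseline(stratum, params, "standard_care")
        res = run_arm(baseline, params, stratum, trace=True)
        alive_cols = ["no_lc"] + [
            c for c in res.trace.columns
            if c.startswith(("undiag_", "diag_"))
        ]
        alive = res.trace[alive_cols].sum(axis=1).to_numpy()
        riemann = 0.25 * alive[1:].sum()  # end-of-cycle occupancy
        assert res.life_years == pytest.approx(riemann, abs=1e-10)

    def test_stage_shift_drives_the_qaly_gain(self, calibrated_params):
        """Removing the stage shift (screening stage distribution set to the
        standard-care one) weakly reduces the incremental QALYs."""
        base = run_deterministic(calibrated_params, recalibrate=False)
        no_shift = calibrated_params.copy_deep()
        no_shift.screening.stage_dist_screen = (
            calibrated_params.screening.stage_dist_standard.model_copy()
        )
        shifted = run_deterministic(no_shift, recalibrate=False)
        assert shifted.pooled.d_qalys <= base.pooled.d_qalys + 1e-12
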