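import numpy as np
import pytest

from lcs_cea import (
    CalibrationTarget,
    StageDistribution,
    calibrate_diagnosis_probs,
    calibrate_paramset,
    make_random_paramset,
    simulate_stage_at_diagnosis,
)

from conftest import make_toy_params


def geometric_toy():
    """Two-stage chain: SI with p_diag 0.5 and p_progress 0.5, SII absorbing
    into diagnosis with certainty; no deaths."""
    return make_toy_params(
        p_progress=(0.5, 0.0, 0.0),
        p_diagnose=(0.5, 1.0, 1.0, 1.0),
        oc_annual=0.0,
        stage_dist_screen=(1.0, 0.0, 0.0, 0.0),
    )


class TestSimulateStageAtDiagnosis:
    def test_geometric_series_closed_form(self):
        """P(diagnosed at SI) = sum_k 0.25^k * 0.5 = 2/3."""
        params = geometric_toy()
        dist = simulate_stage_at_diagnosis([0.5, 1.0, 1.0], params, params.strata[0])
        assert dist.p_I == pytest.approx(2.0 / 3.0, abs=1e-8)
        assert dist.p_II == pytest.approx(1.0 / 3.0, abs=1e-8)

    def test_no_progression_returns_baseline_distribution(self):
        params = make_toy_params(
            p_progress=(0.0, 0.0, 0.0),
            p_diagnose=(0.3, 0.2, 0.4, 0.5),
            oc_annual=0.0,
            stage_dist_screen=(0.4, 0.3, 0.2, 0.1),
        )
        dist = simulate_stage_at_diagnosis([0.3, 0.2, 0.4], params, params.strata[0])
        # the age-100 rule truncates ~0.8^80 of undiagnosed mass
        assert dist.as_tuple() == pytest.approx((0.4, 0.3, 0.2, 0.1), abs=1e-7)

    def test_certain_diagnosis_returns_baseline_distribution(self):
        params = make_toy_params(
            p_progress=(0.4, 0.5, 0.6),
            p_diagnose=(1.0, 1.0, 1.0, 1.0),
            oc_annual=0.05,
            stage_dist_screen=(0.4, 0.3, 0.2, 0.1),
        )
        dist = simulate_stage_at_diagnosis([1.0, 1.0, 1.0], params, params.strata[0])
        assert dist.as_tuple() == pytest.approx((0.4, 0.3, 0.2, 0.1), abs=1e-10)

    def test_agrees_with_absorbing_chain_linear_algebra(self):
        """Fundamental-matrix solution of the time-homogeneous sub-chain."""
        q = 0.02  # constant 3-month other-cause death probability
        d = np.array([0.30, 0.35, 0.45, 0.60])
        prog = np.array([0.25, 0.30, 0.40])
        pi = np.array([0.5, 0.2, 0.2, 0.1])
        params = make_toy_params(
            p_progress=tuple(prog),
            p_diagnose=tuple(d),
            stage_dist_screen=tuple(pi),
            age_group="80",
        )
        for sex in params.transitions.p_oc_death_3m:
            params.transitions.p_oc_death_3m[sex] = {
                **{a: q for a in range(55, 100)}, 100: 1.0
            }

        Q = np.zeros((4, 4))
        for s in range(4):
            stay = (1 - q) * (1 - d[s])
            p = prog[s] if s < 3 else 0.0
            Q[s, s] = stay * (1 - p)
            if s < 3:
                Q[s, s + 1] = stay * p
        absorb = np.linalg.solve(np.eye(4) - Q.T, pi) * (1 - q) * d
        expected = absorb / absorb.sum()

        dist = simulate_stage_at_diagnosis(d[:3], params, params.strata[0])
        assert dist.as_tuple() == pytest.approx(tuple(expected), abs=1e-8)


class TestCalibration:
    def test_toy_inverse_recovers_half(self):
        """Targeting P(SI) = 2/3 in the two-stage toy recovers p_diag_I = 0.5."""
        params = geometric_toy()
        ctarget = CalibrationTarget(
            target_dist=StageDistribution.from_sequence([2 / 3, 1 / 3, 0, 0]),
            tolerance=1e-6,
        )
        probs, record = calibrate_diagnosis_probs(
            ctarget, params, params.strata[0], x0=[0.2, 1.0, 1.0]
        )
        assert record.converged
        assert probs["I"] == pytest.approx(0.5, abs=1e-4)

    def test_self_consistency_roundtrip_default(self, default_params):
        truth = [0.10, 0.07, 0.25]
        target = simulate_stage_at_diagnosis(truth, default_params)
        ctarget = CalibrationTarget(target_dist=target, tolerance=1e-6)
        probs, record = calibrate_diagnosis_probs(
            ctarget, default_params, x0=[0.3, 0.3, 0.3]
        )
        assert record.converged
        recovered = simulate_stage_at_diagnosis(
            [probs["I"], probs["II"], probs["III"]], default_params
        )
        assert np.abs(
            np.array(recovered.as_tuple()) - np.array(target.as_tuple())
        ).max() <= 1e-6

    def test_monotone_stage_I_share_in_p_diag_I(self, default_params):
        shares = []
        for p1 in (0.02, 0.05, 0.1, 0.3, 0.8):
            dist = simulate_stage_at_diagnosis([p1, 0.1, 0.2], default_params)
            shares.append(dist.p_I)
        assert all(b >= a for a, b in zip(shares, shares[1:]))

    def test_calibrate_paramset_hits_standard_care_distribution(self, calibrated_params):
        dist = simulate_stage_at_diagnosis(
            [calibrated_params.transitions.p_diagnose_3m[s] for s in ("I", "II", "III")],
            calibrated_params,
        )
        target = calibrated_params.screening.stage_dist_standard
        assert np.abs(
            np.array(dist.as_tuple()) - np.array(target.as_tuple())
        ).max() <= 1e-4

    def test_nonconvergence_is_flagged_not_silent(self):
        # an unreachable target: all mass diagnosed at stage I is impossible
        # when the baseline has stage-IV mass that can only be diagnosed at IV
        params = make_toy_params(
            p_progress=(0.0, 0.0, 0.0),
            p_diagnose=(0.5, 0.5, 0.5, 0.5),
            oc_annual=0.0,
            stage_dist_screen=(0.5, 0.0, 0.0, 0.5),
        )
        ctarget = CalibrationTarget(
            target_dist=StageDistribution.from_sequence([1.0, 0.0, 0.0, 0.0]),
            tolerance=1e-4,
            max_iterations=30,
        )
        probs, record = calibrate_diagnosis_probs(ctarget, params, params.strata[0])
        assert not record.converged
        assert record.max_abs_dev > 1e-4

    def test_validation_of_inputs(self, default_params):
        with pytest.raises(ValueError):
            simulate_stage_at_diagnosis([0.5, 1.2, 0.1], default_params)
        with pytest.raises(ValueError):
            CalibrationTarget(
                target_dist=StageDistribution.from_sequence([1, 0, 0, 0]),
                tolerance=0.0,
            )

    def test_roundtrip_on_random_paramsets(self):
        rng = np.random.default_rng(11)
        for seed in range(8):
            params = make_random_paramset(seed)
            truth = rng.uniform(0.05, 0.6, size=3)
            target = simulate_stage_at_diagnosis(truth, params)
            ctarget = CalibrationTarget(target_dist=target, tolerance=1e-5)
            probs, record = calibrate_diagnosis_probs(
                ctarget, params, x0=[0.3, 0.3, 0.3]
            )
            assert record.converged, f"seed {seed}"
            recovered = simulate_stage_at_diagnosis(
                [probs[s] for s in ("I", "II", "III")], params
            )
            assert np.abs(
                np.array(recovered.as_tuple()) - np.array(target.as_tuple())
            ).max() <= 1e-5, f"seed {seed}"
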