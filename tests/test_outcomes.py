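import numpy as np
import pytest

from lcs_cea import (
    ICER,
    aggregate_subgroups,
    fp_surgeries,
    incremental,
    overdiagnosis_fraction,
    run_deterministic,
    scale_per_10k,
)
from lcs_cea.markov_engine import ArmResult
from lcs_cea.outcomes import IncrementalResult

from conftest import make_toy_params


def _arm(arm, **kw):
    defaults = dict(
        life_years=10.0, qalys=8.0, cost_detection=0.0, cost_false_positive=0.0,
        cost_dx_tx=0.0, lc_deaths=0.1, oc_deaths=0.9,
    )
    defaults.update(kw)
    return ArmResult(arm=arm, stratum_key="male:65-69", **defaults)


def _inc(d_cost=0.0, d_qalys=0.0, **kw):
    defaults = dict(
        d_life_years=0.0, d_qalys=d_qalys, d_lc_deaths=0.0,
        d_cost_detection=d_cost, d_cost_false_positive=0.0, d_cost_dx_tx=0.0,
    )
    defaults.update(kw)
    return IncrementalResult(**defaults)


class TestIncremental:
    def test_identical_arms_all_deltas_zero(self):
        inc = incremental(_arm("screening"), _arm("standard_care"))
        assert inc.d_qalys == 0.0
        assert inc.d_cost_total == 0.0
        assert inc.icer_per_qaly.label == "undefined"

    def test_cost_components_sum_to_total(self):
        """The printed component arithmetic: 164 + 66 - 121 = 109."""
        scr = _arm("screening", cost_detection=164.0, cost_false_positive=66.0,
                   cost_dx_tx=0.0)
        soc = _arm("standard_care", cost_dx_tx=121.0)
        inc = incremental(scr, soc)
        assert inc.d_cost_total == pytest.approx(109.0)

    def test_icer_on_unrounded_deltas(self):
        scr = _arm("screening", qalys=8.0395, cost_detection=109.0)
        soc = _arm("standard_care")
        inc = incremental(scr, soc)
        assert float(inc.icer_per_qaly) == pytest.approx(109.0 / 0.0395)
        assert float(inc.icer_per_qaly) == pytest.approx(2759.4937, abs=1e-3)

    def test_mismatched_strata_rejected(self):
        soc = _arm("standard_care")
        soc.stratum_key = "female:80"
        with pytest.raises(ValueError):
            incremental(_arm("screening"), soc)

    @pytest.mark.parametrize(
        "d_cost, d_eff, label",
        [
            (-5.0, 0.01, "dominant"),
            (5.0, -0.01, "dominated"),
            (5.0, 0.01, "ratio"),
            (-5.0, -0.01, "ratio"),
            (5.0, 0.0, "undefined"),
        ],
    )
    def test_dominance_labels_match_ce_plane_quadrant(self, d_cost, d_eff, label):
        assert ICER.from_deltas(d_cost, d_eff).label == label


class TestAggregation:
    def test_single_subgroup_identity(self):
        inc = _inc(d_cost=100.0, d_qalys=0.02)
        agg = aggregate_subgroups([(1.0, inc)])
        assert agg.d_cost_total == pytest.approx(100.0)
        assert float(agg.icer_per_qaly) == pytest.approx(float(inc.icer_per_qaly))

    def test_ratio_of_averages_not_average_of_ratios(self):
        a = _inc(d_cost=100.0, d_qalys=0.01)
        b = _inc(d_cost=200.0, d_qalys=0.03)
        agg = aggregate_subgroups([(0.5, a), (0.5, b)])
        assert agg.d_cost_total == pytest.approx(150.0)
        assert agg.d_qalys == pytest.approx(0.02)
        assert float(agg.icer_per_qaly) == pytest.approx(7500.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            aggregate_subgroups([(0.5, _inc()), (0.4, _inc())])

    def test_pooled_run_equals_weighted_stratum_results(self, calibrated_params):
        det = run_deterministic(calibrated_params, recalibrate=False)
        weights = {s.key: s.weight for s in calibrated_params.strata}
        manual = sum(weights[k] * det.by_stratum[k].d_qalys for k in det.by_stratum)
        assert det.pooled.d_qalys == pytest.approx(manual, abs=1e-9)
        manual_cost = sum(
            weights[k] * det.by_stratum[k].d_cost_total for k in det.by_stratum
        )
        assert det.pooled.d_cost_total == pytest.approx(manual_cost, abs=1e-9)


class TestScaling:
    def test_per_10k_reporting(self):
        inc = _inc(d_cost=109.0, d_qalys=0.0395,
                   d_life_years=0.0481, d_lc_deaths=-0.0039)
        table = scale_per_10k(inc)
        assert table["qalys_gained"] == 395
        assert table["life_years_saved"] == 481
        assert table["lc_deaths_averted"] == 39
        assert table["incremental_total_cost"] == 1_090_000

    def test_rounding_half_away_from_zero(self):
        inc = _inc(d_qalys=0.00005, d_lc_deaths=0.00005)
        table = scale_per_10k(inc)
        assert table["qalys_gained"] == 1
        assert table["lc_deaths_averted"] == -1


class TestFpSurgeries:
    def test_printed_example(self, default_params):
        """10,000 screened x 18.0% false positives x 0.8% surgery = 14."""
        assert fp_surgeries(10_000, default_params) == 14

    def test_zero_fp_probability(self, default_params):
        p = default_params.copy_deep()
        p.screening.p_fp_ldct_by_ageband = {"lt65": 0.0, "ge65": 0.0}
        assert fp_surgeries(10_000, p) == 0

    def test_direct_product(self):
        params = make_toy_params()
        params.screening.p_fp_ldct_by_ageband = {"lt65": 0.5, "ge65": 0.5}
        params.screening.p_surgery_given_fp = 0.1
        assert fp_surgeries(1_000, params) == 50


class TestOverdiagnosis:
    def test_zero_other_cause_mortality(self):
        params = make_toy_params(oc_annual=0.0, age_group="55-59")
        # keep the horizon short of the age-100 forced death
        assert overdiagnosis_fraction(params, params.strata[0]) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_certain_diagnosis_leaves_one_cycle_exposure(self):
        """With diagnosis certain in the first cycle, only that cycle's
        other-cause deaths are overdiagnosed-in-waiting."""
        params = make_toy_params(p_diagnose=(1.0, 1.0, 1.0, 1.0))
        q = 0.08
        for sex in params.transitions.p_oc_death_3m:
            params.transitions.p_oc_death_3m[sex] = {
                **{a: q for a in range(55, 100)}, 100: 1.0
            }
        assert overdiagnosis_fraction(params, params.strata[0]) == pytest.approx(q)

    def test_weakly_increasing_in_other_cause_mortality(self, calibrated_params):
        values = []
        for k in (0.5, 1.0, 2.0):
            p = calibrated_params.copy_deep()
            for sex in p.transitions.p_oc_death_3m:
                p.transitions.p_oc_death_3m[sex] = {
                    age: min(1.0, v * k) if age < 100 else 1.0
                    for age, v in p.transitions.p_oc_death_3m[sex].items()
                }
            values.append(overdiagnosis_fraction(p))
        assert values[0] <= values[1] <= values[2]
        assert values[2] > values[0]


def test_deterministic_pipeline_outputs_are_coherent(calibrated_params):
    det = run_deterministic(calibrated_params, recalibrate=False)
    inc = det.pooled
    assert inc.d_cost_total == pytest.approx(
        inc.d_cost_detection + inc.d_cost_false_positive + inc.d_cost_dx_tx, abs=1e-9
    )
    assert inc.overdiagnosis_per_10k is not None and inc.overdiagnosis_per_10k >= 0
    assert inc.fp_surgeries_per_10k == 14
    assert np.isfinite(float(inc.icer_per_qaly))
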