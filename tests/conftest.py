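from __future__ import annotations

import pytest

from lcs_cea import (
    CostParams,
    EconSettings,
    ParamSet,
    ScreeningParams,
    StageDistribution,
    Stratum,
    TransitionParams,
    UtilityParams,
    calibrate_paramset,
    make_default_paramset,
)
from lcs_cea.param_model import MORTALITY_BANDS, SEXES, STAGES


@pytest.fixture(scope="session")
def default_params() -> ParamSet:
    return make_default_paramset()


@pytest.fixture(scope="session")
def calibrated_params(default_params) -> ParamSet:
    params, record = calibrate_paramset(default_params)
    assert record.converged
    return params


def make_toy_params(
    p_progress=(0.5, 0.0, 0.0),
    p_diagnose=(0.5, 1.0, 1.0, 1.0),
    oc_annual: float = 0.0,
    prevalence: float = 0.02,
    stage_dist_screen=(1.0, 0.0, 0.0, 0.0),
    stage_dist_standard=(0.25, 0.25, 0.25, 0.25),
    lc_death: float = 0.0,
    utility: float = 1.0,
    discount: float = 0.0,
    half_cycle: bool = True,
    age_group: str = "80",
) -> ParamSet:
    """Single-stratum parameter set with hand-checkable dynamics."""
    from lcs_cea.param_model import to_cycle_prob

    oc = {age: to_cycle_prob(oc_annual, 4) for age in range(55, 100)}
    oc[100] = 1.0
    lc_table = {
        sex: {
            band: {stage: [lc_death] * 5 for stage in STAGES}
            for band in MORTALITY_BANDS
        }
        for sex in SEXES
    }
    stratum = Stratum(sex="male", age_group=age_group, weight=1.0)
    return ParamSet(
        strata=[stratum],
        screening=ScreeningParams(
            overall_prevalence=prevalence,
            prevalence_by_stratum={stratum.key: prevalence},
            stage_dist_screen=StageDistribution.from_sequence(stage_dist_screen),
            stage_dist_standard=StageDistribution.from_sequence(stage_dist_standard),
            p_fp_ldct_by_ageband={"lt65": 0.1, "ge65": 0.1},
            p_fp_xray=0.05,
            p_checkup_year1=0.1,
            p_surgery_given_fp=0.01,
        ),
        transitions=TransitionParams(
            p_progress_3m=dict(zip(("I", "II", "III"), p_progress)),
            p_diagnose_3m=dict(zip(STAGES, p_diagnose)),
            p_lc_death_3m_y1to5=lc_table,
            p_lc_death_3m_post5=lc_death,
            p_oc_death_3m={sex: dict(oc) for sex in SEXES},
        ),
        utilities=UtilityParams(
            u_no_lc={sex: {b: utility for b in ("55-64", "65-74", "75+")} for sex in SEXES},
            u_lc_stageI=utility,
            ratio_II=1.0,
            ratio_III=1.0,
            ratio_IV=1.0,
            disutility_screen=0.0,
            disutility_fp=0.0,
        ),
        costs=CostParams(
            c_detection_screen=179.0,
            c_checkup_standard=140.0,
            c_fp_ldct=385.0,
            c_fp_xray=180.0,
            c_dx_tx_by_stage={s: 1000.0 for s in STAGES},
        ),
        econ=EconSettings(
            annual_discount_rate=discount, half_cycle_correction=half_cycle
        ),
    )


@pytest.fixture
def toy_params() -> ParamSet:
    return make_toy_params()
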