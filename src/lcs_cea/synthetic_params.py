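"""Synthetic default and random parameter sets.

The original analysis drew its inputs from regional registries and an
(unpublished) appendix; only a handful of aggregates are public.  This module
constructs a fully specified synthetic parameterisation that reproduces those
aggregates by construction — overall screen-detectable prevalence 0.0253,
mean LDCT false-positive probability 0.180, surgery-in-false-positive
probability 0.008, detection costs of EUR 179 (screening) and EUR 14
(standard care, first year), a 3% discount rate — and plausible values
everywhere else.  It also generates random valid parameter sets for
property-based testing.  No claim is made that synthetic defaults equal the
unpublished source values.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .param_model import (
    AGE_GROUPS,
    FP_BANDS,
    MORTALITY_BANDS,
    SEXES,
    STAGES,
    UTILITY_BANDS,
    CostParams,
    EconSettings,
    ParamSet,
    ScreeningParams,
    StageDistribution,
    Stratum,
    TransitionParams,
    UtilityParams,
    stratum_key,
    to_cycle_prob,
    validate_params,
)


class CalibrationError(ValueError):
    pass


class SyntheticSpec(BaseModel):
    """Targets and shape constraints for the default synthetic parameter set."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    overall_prevalence_target: float = 0.0253
    fp_ldct_mean_target: float = 0.180
    surgery_given_fp: float = 0.008
    detection_cost_screen: float = 179.0
    detection_cost_standard_y1: float = 14.0
    discount: float = 0.03
    psa_iterations: int = 2000
    #: relative screen-detectable prevalence by age group: rises from 55-59
    #: through 75-79, dips at 80 (mirroring general-population incidence)
    prevalence_age_profile: Dict[str, float] = {
        "55-59": 0.40,
        "60-64": 0.65,
        "65-69": 1.00,
        "70-74": 1.35,
        "75-79": 1.55,
        "80": 1.25,
    }

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        for name in ("overall_prevalence_target", "fp_ldct_mean_target",
                     "surgery_given_fp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        prof = self.prevalence_age_profile
        rising = [prof[a] for a in AGE_GROUPS[:-1]]
        if any(b <= a for a, b in zip(rising, rising[1:])):
            raise ValueError("prevalence profile must increase from 55-59 to 75-79")
        if not (prof["80"] < prof["70-74"] and prof["80"] < prof["75-79"]):
            raise ValueError("prevalence at 80 must be below the 70-74 and 75-79 values")
        return self


#: registry-inspired stratum weights: older-skewed, mostly male (synthetic)
_AGE_SHARES: Dict[str, float] = {
    "55-59": 0.10, "60-64": 0.14, "65-69": 0.18,
    "70-74": 0.22, "75-79": 0.22, "80": 0.14,
}
_SEX_SHARES: Dict[str, float] = {"male": 0.70, "female": 0.30}


def _default_strata() -> list[Stratum]:
    return [
        Stratum(sex=sex, age_group=age, weight=_SEX_SHARES[sex] * _AGE_SHARES[age])
        for sex in SEXES
        for age in AGE_GROUPS
    ]


def _lc_death_table() -> Dict[str, Dict[str, Dict[str, list[float]]]]:
    # annual LC death probability in year 1 by stage, declining by year since
    # diagnosis; worse for later stages, males, and the older age band
    base_y1 = {"I": 0.07, "II": 0.22, "III": 0.50, "IV": 0.85}
    year_decline = 0.70
    sex_factor = {"male": 1.05, "female": 0.95}
    band_factor = {"55-69": 0.90, "70-84": 1.15}
    table: Dict[str, Dict[str, Dict[str, list[float]]]] = {}
    for sex in SEXES:
        table[sex] = {}
        for band in MORTALITY_BANDS:
            table[sex][band] = {}
            for stage in STAGES:
                years = []
                for y in range(5):
                    annual = min(
                        0.98,
                        base_y1[stage] * year_decline**y
                        * sex_factor[sex] * band_factor[band],
                    )
                    years.append(to_cycle_prob(annual, 4))
                table[sex][band][stage] = years
    return table


def _oc_death_table() -> Dict[str, Dict[int, float]]:
    # asbestos-adjusted all-other-cause annual mortality, stepwise on 5-year
    # bands; death certain at 100
    male_annual = {55: 0.010, 60: 0.016, 65: 0.026, 70: 0.042, 75: 0.068,
                   80: 0.110, 85: 0.180, 90: 0.290, 95: 0.430}
    table: Dict[str, Dict[int, float]] = {}
    for sex, factor in (("male", 1.0), ("female", 0.62)):
        ages = {}
        for age in range(55, 100):
            band = 55 + 5 * ((age - 55) // 5)
            ages[age] = to_cycle_prob(min(0.98, male_annual[band] * factor), 4)
        ages[100] = 1.0
        table[sex] = ages
    return table


def make_default_paramset(spec: SyntheticSpec | None = None) -> ParamSet:
    """Build the default synthetic ParamSet.

    By construction the returned set hits every aggregate in ``spec``:
    population-weighted prevalence, population-weighted LDCT false-positive
    probability, detection costs and discount rate; the screening-arm stage
    distribution stochastically dominates the standard-care one toward
    earlier stages.
    """
    spec = spec or SyntheticSpec()
    strata = _default_strata()

    # prevalence: scale the age profile to hit the weighted-mean target
    # (the profile is sex-independent, so sex shares drop out)
    prof = spec.prevalence_age_profile
    denom = sum(_AGE_SHARES[a] * prof[a] for a in AGE_GROUPS)
    scale = spec.overall_prevalence_target / denom if denom > 0 else 0.0
    prevalence = {
        stratum_key(sex, age): scale * prof[age]
        for sex in SEXES for age in AGE_GROUPS
    }
    if any(p > 1.0 or p < 0.0 for p in prevalence.values()):
        raise CalibrationError(
            "prevalence age profile cannot reach the weighted-mean target "
            "with per-stratum values in [0, 1]"
        )

    # LDCT false positives: <65 vs >=65 bands; older band 25% higher, scaled
    # so the population-weighted mean equals the target exactly
    w_lt = sum(_AGE_SHARES[a] for a in ("55-59", "60-64"))
    w_ge = 1.0 - w_lt
    ratio = 1.25
    p_lt = spec.fp_ldct_mean_target / (w_lt + w_ge * ratio)
    fp_bands = {"lt65": p_lt, "ge65": p_lt * ratio}

    p_checkup = 0.10
    screening = ScreeningParams(
        overall_prevalence=spec.overall_prevalence_target,
        prevalence_by_stratum=prevalence,
        # earlier-stage distribution under screening (one-off round)...
        stage_dist_screen=StageDistribution(p_I=0.60, p_II=0.12, p_III=0.14, p_IV=0.14),
        # ...versus clinical presentation under standard care
        stage_dist_standard=StageDistribution(p_I=0.17, p_II=0.08, p_III=0.25, p_IV=0.50),
        p_fp_ldct_by_ageband=fp_bands,
        p_fp_xray=0.086,
        p_checkup_year1=p_checkup,
        p_surgery_given_fp=spec.surgery_given_fp,
    )

    transitions = TransitionParams(
        p_progress_3m={"I": 0.22, "II": 0.33, "III": 0.45},
        # I-III are provisional; the calibration module replaces them so that
        # the standard-care stage distribution at diagnosis matches
        # stage_dist_standard.  IV is fixed from its source model.
        p_diagnose_3m={"I": 0.08, "II": 0.18, "III": 0.35, "IV": 0.55},
        p_lc_death_3m_y1to5=_lc_death_table(),
        p_lc_death_3m_post5=to_cycle_prob(0.02, 4),
        p_oc_death_3m=_oc_death_table(),
        max_age=100.0,
    )

    utilities = UtilityParams(
        u_no_lc={
            "male": {"55-64": 0.84, "65-74": 0.80, "75+": 0.75},
            "female": {"55-64": 0.81, "65-74": 0.77, "75+": 0.72},
        },
        u_lc_stageI=0.70,
        ratio_II=0.95,
        ratio_III=0.87,
        ratio_IV=0.75,
        disutility_screen=0.0010,
        disutility_fp=0.0080,
    )

    costs = CostParams(
        c_detection_screen=spec.detection_cost_screen,
        # attendance x visit cost reproduces the year-1 standard-care target
        c_checkup_standard=spec.detection_cost_standard_y1 / p_checkup,
        c_fp_ldct=385.0,
        c_fp_xray=180.0,
        c_dx_tx_by_stage={"I": 23_000.0, "II": 19_000.0, "III": 28_000.0, "IV": 34_000.0},
    )

    econ = EconSettings(annual_discount_rate=spec.discount)

    params = ParamSet(
        strata=strata, screening=screening, transitions=transitions,
        utilities=utilities, costs=costs, econ=econ,
    )
    validate_params(params).raise_if_invalid()
    return params


def make_random_paramset(rng_seed: int) -> ParamSet:
    """Draw a random valid ParamSet from wide-but-plausible ranges.

    Deterministic given the seed; every draw passes :func:`validate_params`
    by construction.  Orderings needed by the model's comparative statics are
    preserved: LC mortality is non-decreasing in stage, LC utilities
    non-increasing in stage, no-LC utilities non-increasing in age.
    """
    rng = np.random.default_rng(rng_seed)

    weights = rng.dirichlet(np.full(12, 4.0))
    strata = [
        Stratum(sex=sex, age_group=age, weight=float(w))
        for (sex, age), w in zip(
            ((s, a) for s in SEXES for a in AGE_GROUPS), weights
        )
    ]

    prevalence = {s.key: float(rng.uniform(0.004, 0.06)) for s in strata}
    overall = float(sum(s.weight * prevalence[s.key] for s in strata))

    def dirichlet_dist(conc: float) -> StageDistribution:
        return StageDistribution.from_sequence(rng.dirichlet(np.full(4, conc)))

    p_lt = float(rng.uniform(0.05, 0.30))
    screening = ScreeningParams(
        overall_prevalence=overall,
        prevalence_by_stratum=prevalence,
        stage_dist_screen=dirichlet_dist(5.0),
        stage_dist_standard=dirichlet_dist(5.0),
        p_fp_ldct_by_ageband={"lt65": p_lt, "ge65": float(np.clip(p_lt * rng.uniform(1.0, 1.6), 0, 1))},
        p_fp_xray=float(rng.uniform(0.02, 0.20)),
        p_checkup_year1=float(rng.uniform(0.02, 0.40)),
        p_surgery_given_fp=float(rng.uniform(0.0, 0.05)),
    )

    lc_table: Dict[str, Dict[str, Dict[str, list[float]]]] = {}
    for sex in SEXES:
        lc_table[sex] = {}
        for band in MORTALITY_BANDS:
            base = np.sort(rng.uniform(0.02, 0.30, size=4))  # per-stage y1, increasing
            decline = rng.uniform(0.6, 0.95)
            lc_table[sex][band] = {
                stage: [float(min(0.99, base[i] * decline**y)) for y in range(5)]
                for i, stage in enumerate(STAGES)
            }

    oc_table: Dict[str, Dict[int, float]] = {}
    for sex in SEXES:
        p = rng.uniform(0.001, 0.004)
        ages: Dict[int, float] = {}
        for age in range(55, 100):
            if age > 55 and (age - 55) % 5 == 0:
                p = min(0.5, p * rng.uniform(1.3, 1.8))
            ages[age] = float(p)
        ages[100] = 1.0
        oc_table[sex] = ages

    transitions = TransitionParams(
        p_progress_3m={s: float(rng.uniform(0.05, 0.5)) for s in ("I", "II", "III")},
        p_diagnose_3m={
            "I": float(rng.uniform(0.05, 0.5)),
            "II": float(rng.uniform(0.05, 0.6)),
            "III": float(rng.uniform(0.1, 0.7)),
            "IV": float(rng.uniform(0.3, 0.8)),
        },
        p_lc_death_3m_y1to5=lc_table,
        p_lc_death_3m_post5=float(rng.uniform(0.002, 0.02)),
        p_oc_death_3m=oc_table,
        max_age=100.0,
    )

    u_no: Dict[str, Dict[str, float]] = {}
    min_base = 1.0
    for sex in SEXES:
        top = rng.uniform(0.72, 0.92)
        drop1, drop2 = rng.uniform(0.01, 0.06, size=2)
        u_no[sex] = {
            "55-64": float(top),
            "65-74": float(top - drop1),
            "75+": float(top - drop1 - drop2),
        }
        min_base = min(min_base, top)
    ratios = np.sort(rng.uniform(0.55, 1.0, size=3))[::-1]  # II >= III >= IV
    utilities = UtilityParams(
        u_no_lc=u_no,
        u_lc_stageI=float(rng.uniform(0.45, min_base)),
        ratio_II=float(ratios[0]),
        ratio_III=float(ratios[1]),
        ratio_IV=float(ratios[2]),
        disutility_screen=float(rng.uniform(0.0, 0.004)),
        disutility_fp=float(rng.uniform(0.0, 0.02)),
    )

    dx = np.sort(rng.uniform(8_000, 45_000, size=4))
    costs = CostParams(
        c_detection_screen=float(rng.uniform(80, 400)),
        c_checkup_standard=float(rng.uniform(50, 300)),
        c_fp_ldct=float(rng.uniform(100, 900)),
        c_fp_xray=float(rng.uniform(50, 400)),
        # stage IV dearest, III next; I vs II order randomised
        c_dx_tx_by_stage={
            "I": float(dx[rng.integers(0, 2)]),
            "II": float(dx[0] if rng.random() < 0.5 else dx[1]),
            "III": float(dx[2]),
            "IV": float(dx[3]),
        },
    )

    params = ParamSet(
        strata=strata,
        screening=screening,
        transitions=transitions,
        utilities=utilities,
        costs=costs,
        econ=EconSettings(),
    )
    validate_params(params).raise_if_invalid()
    return params
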