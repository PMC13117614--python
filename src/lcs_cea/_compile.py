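"""Internal: compile a ParamSet into dense numpy arrays for the cohort engine.

Everything age-dependent (other-cause mortality, LC mortality age band,
utility age band) is pre-resolved per stratum and per cycle so that the
cycle loop is pure elementwise arithmetic.  Not part of the public API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .param_model import (
    SEXES,
    STAGES,
    ParamSet,
    fp_band,
    mortality_band,
    utility_band,
)

N_STAGES = 4
N_SLOTS = 21  # quarterly tunnel slots: years 1-5 (20) + absorbing 6+ slot
#: year-since-diagnosis index per tunnel slot (5 = post-year-5)
YEAR_OF_SLOT = np.array([y // 4 for y in range(20)] + [5], dtype=np.intp)

_MIN_AGE = 55


def _oc_prob(params: ParamSet, sex: str, age: float) -> float:
    """3-month other-cause death probability at a given exact age.

    Stepwise on single years of age; the last tabulated value is carried
    forward, and death is forced from max_age (default 100) onward.
    """
    tr = params.transitions
    if age >= tr.max_age - 1e-9:
        return 1.0
    table = tr.p_oc_death_3m[sex]
    a = int(np.floor(age))
    if a in table:
        return table[a]
    lower = [k for k in table if k <= a]
    return table[max(lower)] if lower else table[min(table)]


def _lc_prob(params: ParamSet, sex: str, age: float, stage: str, year_idx: int) -> float:
    """3-month LC death probability; year_idx 0..4 = years 1..5, 5 = post-5."""
    tr = params.transitions
    if year_idx >= 5:
        return tr.p_lc_death_3m_post5
    return tr.p_lc_death_3m_y1to5[sex][mortality_band(age)][stage][year_idx]


def _u_no_lc(params: ParamSet, sex: str, age: float) -> float:
    return params.utilities.u_no_lc[sex][utility_band(age)]


def _u_lc(params: ParamSet, sex: str, age: float, stage: str) -> float:
    """Diagnosed-LC utility: stage utility with a multiplicative age decline.

    The decline mirrors the sex-specific no-LC utility profile relative to
    the 55-64 band, capped at the concurrent no-LC utility.
    """
    ut = params.utilities
    base_band = ut.u_no_lc[sex]["55-64"]
    decline = ut.u_no_lc[sex][utility_band(age)] / base_band if base_band > 0 else 1.0
    u = ut.u_lc_stageI * ut.stage_ratio(stage) * decline
    return min(u, _u_no_lc(params, sex, age))


@dataclass
class CompiledModel:
    params: ParamSet
    keys: list[str]            # stratum keys, model order
    weights: np.ndarray        # (n,)
    start_age: np.ndarray      # (n,)
    prevalence: np.ndarray     # (n,)
    p_fp_ldct: np.ndarray      # (n,) band resolved at screening age
    T: int                     # number of cycles
    p_oc: np.ndarray           # (n, T) per-cycle other-cause death prob
    p_lc: np.ndarray           # (n, T, 4, 6) LC death by stage x year idx
    u_no: np.ndarray           # (n, T+1) no-LC utility at cycle boundaries
    u_diag: np.ndarray         # (n, T+1, 4) diagnosed utility by stage
    u_post5: np.ndarray        # (n, T+1, 4) utility in the 6+ tunnel slot
    p_prog: np.ndarray         # (3,)
    p_diag: np.ndarray         # (4,)
    dist_screen: np.ndarray    # (4,)
    dist_standard: np.ndarray  # (4,)
    c_dx_tx: np.ndarray        # (4,)
    df_mid: np.ndarray         # (T,) discount factor at cycle midpoints
    df_start: np.ndarray       # (T,) discount factor at cycle starts
    cycle_len: float
    half_cycle: bool

    def stratum_index(self, key: str) -> int:
        return self.keys.index(key)


def compile_params(params: ParamSet) -> CompiledModel:
    strata = params.strata
    n = len(strata)
    keys = [s.key for s in strata]
    weights = np.array([s.weight for s in strata])
    start_age = np.array([s.start_age for s in strata])
    sex_idx = np.array([SEXES.index(s.sex) for s in strata], dtype=np.intp)
    sc = params.screening
    prevalence = np.array([sc.prevalence_by_stratum[k] for k in keys])
    p_fp = np.array([sc.p_fp_ldct_by_ageband[fp_band(s.start_age)] for s in strata])

    dt = params.econ.cycle_length
    tr = params.transitions
    max_age = tr.max_age
    T = int(np.ceil((max_age - start_age.min()) / dt)) + 1

    ages = start_age[:, None] + dt * np.arange(T + 1)[None, :]  # (n, T+1)
    ages_t = ages[:, :T]
    yr = np.floor(ages_t).astype(np.intp)

    # other-cause mortality: dense per-sex lookup over integer ages
    max_yr = int(yr.max()) + 1
    oc_lut = np.zeros((2, max_yr + 1 - _MIN_AGE))
    for si, sex in enumerate(SEXES):
        table = tr.p_oc_death_3m[sex]
        tab_ages = sorted(table)
        vals = [table[a] for a in tab_ages]
        idx = np.searchsorted(tab_ages, np.arange(_MIN_AGE, max_yr + 1), side="right") - 1
        oc_lut[si] = np.array(vals)[np.clip(idx, 0, len(vals) - 1)]
    p_oc = oc_lut[sex_idx[:, None], np.clip(yr, _MIN_AGE, max_yr) - _MIN_AGE]
    p_oc = np.where(ages_t >= max_age - 1e-9, 1.0, p_oc)

    # LC mortality: (sex, band, stage, year idx) table gathered per cycle
    lc_tab = np.empty((2, 2, N_STAGES, 6))
    for si, sex in enumerate(SEXES):
        for bi, band in enumerate(("55-69", "70-84")):
            for j, stage in enumerate(STAGES):
                lc_tab[si, bi, j, :5] = tr.p_lc_death_3m_y1to5[sex][band][stage]
    lc_tab[:, :, :, 5] = tr.p_lc_death_3m_post5
    band_idx = (ages_t >= 70).astype(np.intp)  # ages >84 carry 70-84 forward
    p_lc = lc_tab[sex_idx[:, None], band_idx]  # (n, T, 4, 6)

    # utilities at cycle boundaries
    ut = params.utilities
    u_tab = np.array([
        [ut.u_no_lc[sex][b] for b in ("55-64", "65-74", "75+")] for sex in SEXES
    ])
    ub_idx = np.digitize(ages, [65, 75])  # (n, T+1) -> 0,1,2
    u_no = u_tab[sex_idx[:, None], ub_idx]
    ratios = np.array([1.0, ut.ratio_II, ut.ratio_III, ut.ratio_IV])
    base_band = u_tab[sex_idx, 0]  # (n,)
    with np.errstate(divide="ignore", invalid="ignore"):
        decline = np.where(base_band[:, None] > 0, u_no / base_band[:, None], 1.0)
    u_diag = np.minimum(
        ut.u_lc_stageI * ratios[None, None, :] * decline[:, :, None],
        u_no[:, :, None],
    )
    u_post5 = (np.repeat(u_no[:, :, None], N_STAGES, axis=2)
               if ut.u_post5_equals_no_lc else u_diag.copy())

    p_prog = np.array([tr.p_progress_3m[s] for s in ("I", "II", "III")])
    p_diag = np.array([tr.p_diagnose_3m[s] for s in STAGES])

    rate = params.econ.annual_discount_rate
    t_idx = np.arange(T)
    df_mid = (1.0 + rate) ** (-(t_idx + 0.5) * dt)
    df_start = (1.0 + rate) ** (-t_idx * dt)

    return CompiledModel(
        params=params,
        keys=keys,
        weights=weights,
        start_age=start_age,
        prevalence=prevalence,
        p_fp_ldct=p_fp,
        T=T,
        p_oc=p_oc,
        p_lc=p_lc,
        u_no=u_no,
        u_diag=u_diag,
        u_post5=u_post5,
        p_prog=p_prog,
        p_diag=p_diag,
        dist_screen=np.array(sc.stage_dist_screen.as_tuple()),
        dist_standard=np.array(sc.stage_dist_standard.as_tuple()),
        c_dx_tx=np.array([params.costs.c_dx_tx_by_stage[s] for s in STAGES]),
        df_mid=df_mid,
        df_start=df_start,
        cycle_len=dt,
        half_cycle=params.econ.half_cycle_correction,
    )
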