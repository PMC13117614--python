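"""Long-term Markov cohort engine.

States: no lung cancer; undiagnosed stage I-IV (standard-care arm only);
diagnosed stage I-IV with a years-since-diagnosis tunnel (20 quarterly slots
covering years 1-5 plus one absorbing 6+ slot); death from lung cancer;
death from other causes.  The cohort advances in 3-month cycles until
extinction, which the age-100 rule guarantees.

Within a cycle, competing events are applied in a fixed order: other-cause
death (all alive states), lung-cancer death (diagnosed states, tunnel- and
age-specific probability), diagnosis (undiagnosed states, entering the
year-1 tunnel of the same stage), then stage progression of the remaining
undiagnosed I-III.  Life years, QALYs and costs accrue per cycle with
trapezoidal half-cycle correction and annual discounting evaluated at cycle
midpoints; one-off diagnosis/treatment costs are discounted to the start of
the diagnosis cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from ._compile import N_SLOTS, N_STAGES, YEAR_OF_SLOT, CompiledModel, compile_params
from ._compile import _lc_prob, _oc_prob
from .decision_tree import BaselineAllocation
from .param_model import STAGES, ParamSet, Stratum

#: mass below which the cohort counts as extinct
EXTINCTION_TOL = 1e-12

STATE_NAMES: list[str] = (
    ["no_lc"]
    + [f"undiag_{s}" for s in STAGES]
    + [f"diag_{s}_slot{k}" for s in STAGES for k in range(N_SLOTS)]
    + ["dead_lc", "dead_other"]
)
N_STATES = len(STATE_NAMES)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class HorizonError(RuntimeError):
    pass


def discount_factor(t: float, annual_rate: float) -> float:
    """Present-value factor ``(1 + r)**(-t)`` for a time ``t`` in years."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return (1.0 + annual_rate) ** (-t)


# ---------------------------------------------------------------------------
# public single-stratum stepping API

@dataclass
class CohortState:
    """Occupancy snapshot of one stratum's cohort at a cycle boundary."""

    cycle_index: int
    age: float
    occupancy: np.ndarray  # (N_STATES,)

    def __getitem__(self, name: str) -> float:
        return float(self.occupancy[_IDX[name]])

    @property
    def alive(self) -> float:
        return float(self.occupancy[:-2].sum())

    def validate(self) -> None:
        if self.occupancy.shape != (N_STATES,):
            raise ValueError("occupancy has wrong length")
        if (self.occupancy < -1e-12).any():
            raise ValueError("negative occupancy")
        if abs(self.occupancy.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancy sums to {self.occupancy.sum()!r}")


def state_from_baseline(baseline: BaselineAllocation, stratum: Stratum) -> CohortState:
    occ = np.zeros(N_STATES)
    for name, mass in baseline.occupancy.items():
        if name.startswith("diag_"):
            occ[_IDX[name + "_slot0"]] = mass
        else:
            occ[_IDX[name]] = mass
    return CohortState(cycle_index=0, age=stratum.start_age, occupancy=occ)


def step_cohort(
    state: CohortState, params: ParamSet, stratum: Stratum, arm: str
) -> CohortState:
    """Advance one stratum's cohort by one 3-month cycle.

    Returns the next state; also exposed in vectorised form inside
    :func:`run_arm` (the two paths are kept numerically identical).
    """
    state.validate()
    if arm == "screening" and state.occupancy[1:5].sum() > 1e-12:
        raise ValueError("screening-arm chains contain no undiagnosed states")
    occ = state.occupancy.copy()
    sex, age = stratum.sex, state.age

    no_lc = occ[0]
    undiag = occ[1:5].copy()
    diag = occ[5:5 + N_STAGES * N_SLOTS].reshape(N_STAGES, N_SLOTS).copy()
    dead_lc, dead_other = occ[-2], occ[-1]

    # 1. other-cause death
    poc = _oc_prob(params, sex, age)
    alive = no_lc + undiag.sum() + diag.sum()
    dead_other += alive * poc
    no_lc *= 1.0 - poc
    undiag *= 1.0 - poc
    diag *= 1.0 - poc

    # 2. lung-cancer death with tunnel advance
    p_lc = np.array([
        [_lc_prob(params, sex, age, stage, int(YEAR_OF_SLOT[k])) for k in range(N_SLOTS)]
        for stage in STAGES
    ])
    dead_lc += float((diag * p_lc).sum())
    diag *= 1.0 - p_lc
    adv = np.zeros_like(diag)
    adv[:, 1:20] = diag[:, 0:19]
    adv[:, 20] = diag[:, 19] + diag[:, 20]

    # 3. diagnosis
    p_diag = np.array([params.transitions.p_diagnose_3m[s] for s in STAGES])
    newly = undiag * p_diag
    undiag -= newly
    adv[:, 0] += newly

    # 4. progression of remaining undiagnosed I-III
    p_prog = np.array([params.transitions.p_progress_3m[s] for s in ("I", "II", "III")])
    move = undiag[:3] * p_prog
    undiag[:3] -= move
    undiag[1:4] += move

    out = np.empty(N_STATES)
    out[0] = no_lc
    out[1:5] = undiag
    out[5:5 + N_STAGES * N_SLOTS] = adv.ravel()
    out[-2], out[-1] = dead_lc, dead_other
    dt = params.econ.cycle_length
    return CohortState(cycle_index=state.cycle_index + 1, age=age + dt, occupancy=out)


# ---------------------------------------------------------------------------
# vectorised cohort runner

@dataclass
class ArmResult:
    """Discounted lifetime results of one arm for one stratum (per person)."""

    arm: str
    stratum_key: str
    life_years: float
    qalys: float
    cost_detection: float
    cost_false_positive: float
    cost_dx_tx: float
    lc_deaths: float
    oc_deaths: float
    diagnoses_by_stage: Dict[str, float] = field(default_factory=dict)
    trace: Optional[pd.DataFrame] = None

    @property
    def cost_total(self) -> float:
        return self.cost_detection + self.cost_false_positive + self.cost_dx_tx


def _baseline_arrays(cm: CompiledModel, arm: str):
    """Vectorised baseline allocation and one-off accounting for all strata."""
    params = cm.params
    n = len(cm.keys)
    prev = cm.prevalence
    no_lc = 1.0 - prev
    undiag = np.zeros((n, N_STAGES))
    diag = np.zeros((n, N_STAGES, N_SLOTS))
    mass = prev[:, None] * cm.dist_screen[None, :]
    if arm == "screening":
        diag[:, :, 0] = mass
        fp = no_lc * cm.p_fp_ldct
        cost_fp = fp * params.costs.c_fp_ldct
        cost_det = np.full(n, params.costs.c_detection_screen)
        decrement = params.utilities.disutility_screen + params.utilities.disutility_fp * fp
        cost_dxtx = (mass * cm.c_dx_tx[None, :]).sum(axis=1)
        diagnoses = mass.copy()
    else:
        undiag[:] = mass
        sc = params.screening
        fp = no_lc * sc.p_checkup_year1 * sc.p_fp_xray
        cost_fp = fp * params.costs.c_fp_xray
        cost_det = np.full(n, sc.p_checkup_year1 * params.costs.c_checkup_standard)
        decrement = params.utilities.disutility_fp * fp
        cost_dxtx = np.zeros(n)
        diagnoses = np.zeros((n, N_STAGES))
    return no_lc, undiag, diag, cost_det, cost_fp, cost_dxtx, decrement, diagnoses


def run_all_strata(
    cm: CompiledModel, arm: str, trace_row: int | None = None
) -> Dict[str, np.ndarray]:
    """Run one arm for every stratum at once; returns per-stratum arrays."""
    if arm not in ("screening", "standard_care"):
        raise ValueError(f"unknown arm {arm!r}")
    params = cm.params
    n = len(cm.keys)
    (no_lc, undiag, diag, cost_det, cost_fp, cost_dxtx,
     decrement, diagnoses) = _baseline_arrays(cm, arm)
    dead_lc = np.zeros(n)
    dead_other = np.zeros(n)

    dt = cm.cycle_len
    rate = params.econ.annual_discount_rate
    df_flow = cm.df_mid if cm.half_cycle else cm.df_start * (1.0 + rate) ** (-dt)
    c_sc_diag = params.costs.c_checkup_standard
    cycles_y1 = round(1.0 / dt)

    ly = np.zeros(n)
    qaly = np.zeros(n)

    def boundary_utility(t: int) -> np.ndarray:
        in_years = diag[:, :, :20].sum(axis=2)
        return (
            (no_lc + undiag.sum(axis=1)) * cm.u_no[:, t]
            + (in_years * cm.u_diag[:, t]).sum(axis=1)
            + (diag[:, :, 20] * cm.u_post5[:, t]).sum(axis=1)
        )

    alive0 = no_lc + undiag.sum(axis=1) + diag.sum(axis=(1, 2))
    q0 = boundary_utility(0)
    trace_rows = []

    def record_trace(t: int) -> None:
        occ = np.empty(N_STATES)
        occ[0] = no_lc[trace_row]
        occ[1:5] = undiag[trace_row]
        occ[5:5 + N_STAGES * N_SLOTS] = diag[trace_row].ravel()
        occ[-2], occ[-1] = dead_lc[trace_row], dead_other[trace_row]
        trace_rows.append((t, cm.start_age[trace_row] + t * dt, occ))

    if trace_row is not None:
        record_trace(0)

    for t in range(cm.T):
        poc = cm.p_oc[:, t]
        dead_other += alive0 * poc
        keep = 1.0 - poc
        no_lc = no_lc * keep
        undiag *= keep[:, None]
        diag *= keep[:, None, None]

        p_lc = cm.p_lc[:, t][:, :, YEAR_OF_SLOT]  # (n, 4, 21)
        dead_lc += (diag * p_lc).sum(axis=(1, 2))
        diag *= 1.0 - p_lc
        adv = np.zeros_like(diag)
        adv[:, :, 1:20] = diag[:, :, 0:19]
        adv[:, :, 20] = diag[:, :, 19] + diag[:, :, 20]

        newly = undiag * cm.p_diag[None, :]
        undiag = undiag - newly
        adv[:, :, 0] += newly
        diag = adv
        diagnoses += newly
        cost_dxtx += (newly * cm.c_dx_tx[None, :]).sum(axis=1) * cm.df_start[t]
        if arm == "standard_care" and t >= cycles_y1:
            cost_det = cost_det + newly.sum(axis=1) * c_sc_diag * cm.df_start[t]

        move = undiag[:, :3] * cm.p_prog[None, :]
        undiag[:, :3] -= move
        undiag[:, 1:4] += move

        alive1 = no_lc + undiag.sum(axis=1) + diag.sum(axis=(1, 2))
        q1 = boundary_utility(t + 1)
        if cm.half_cycle:
            ly += dt * 0.5 * (alive0 + alive1) * df_flow[t]
            qaly += dt * 0.5 * (q0 + q1) * df_flow[t]
        else:
            ly += dt * alive1 * df_flow[t]
            qaly += dt * q1 * df_flow[t]
        alive0, q0 = alive1, q1
        if trace_row is not None:
            record_trace(t + 1)
        if alive1.max() < EXTINCTION_TOL:
            break
    else:
        if alive0.max() > 1e-9:
            raise HorizonError(
                f"cohort not extinct at the age cap (alive mass {alive0.max()!r})"
            )

    qaly -= decrement
    out = {
        "life_years": ly,
        "qalys": qaly,
        "cost_detection": cost_det,
        "cost_false_positive": cost_fp,
        "cost_dx_tx": cost_dxtx,
        "lc_deaths": dead_lc,
        "oc_deaths": dead_other,
        "diagnoses_by_stage": diagnoses,
    }
    if trace_row is not None:
        out["trace"] = pd.DataFrame(
            [
                {"cycle": t, "age": age, **dict(zip(STATE_NAMES, occ))}
                for t, age, occ in trace_rows
            ]
        )
    return out


def run_arm(
    baseline: BaselineAllocation,
    params: ParamSet,
    stratum: Stratum,
    arm: str | None = None,
    trace: bool = False,
    compiled: CompiledModel | None = None,
) -> ArmResult:
    """Run one arm to cohort extinction for one stratum.

    ``baseline`` must come from :func:`lcs_cea.decision_tree.allocate_baseline`
    with the same parameters; its one-off costs and disutilities are included
    in the returned totals at time zero.
    """
    arm = arm or baseline.arm
    cm = compiled if compiled is not None else compile_params(params)
    i = cm.stratum_index(stratum.key)
    res = run_all_strata(cm, arm, trace_row=i if trace else None)
    return ArmResult(
        arm=arm,
        stratum_key=stratum.key,
        life_years=float(res["life_years"][i]),
        qalys=float(res["qalys"][i]),
        cost_detection=float(res["cost_detection"][i]),
        cost_false_positive=float(res["cost_false_positive"][i]),
        cost_dx_tx=float(res["cost_dx_tx"][i]),
        lc_deaths=float(res["lc_deaths"][i]),
        oc_deaths=float(res["oc_deaths"][i]),
        diagnoses_by_stage={
            s: float(res["diagnoses_by_stage"][i, j]) for j, s in enumerate(STAGES)
        },
        trace=res.get("trace"),
    )
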