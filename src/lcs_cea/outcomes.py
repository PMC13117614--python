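"""Incremental outcomes: ICERs, overdiagnosis, false-positive surgeries.

All incremental quantities are screening minus standard care, per screening
participant; per-10,000 variants multiply by the programme size and round
half away from zero for reporting (internal values are never rounded).
ICERs are always computed on unrounded deltas, and aggregation across
subgroups is the ratio of weighted-average costs to weighted-average
effects, never an average of ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from ._compile import CompiledModel, compile_params
from .calibration import _subchain, calibrate_paramset
from .markov_engine import ArmResult, run_all_strata
from .param_model import STAGES, ParamSet, Stratum

WEIGHT_TOL = 1e-9


@dataclass
class ICER:
    """A cost-effectiveness ratio or its dominance label.

    ``value`` is EUR per unit of effect when the label is ``ratio``;
    ``dominant`` (cheaper and more effective) and ``dominated`` (dearer and
    less effective) carry no finite ratio, nor does ``undefined`` (zero
    incremental effect).
    """

    value: Optional[float]
    label: str  # ratio | dominant | dominated | undefined

    @classmethod
    def from_deltas(cls, d_cost: float, d_effect: float) -> "ICER":
        if d_effect == 0.0:
            return cls(None, "undefined")
        if d_cost < 0.0 and d_effect > 0.0:
            return cls(None, "dominant")
        if d_cost > 0.0 and d_effect < 0.0:
            return cls(None, "dominated")
        return cls(d_cost / d_effect, "ratio")

    def __float__(self) -> float:
        return self.value if self.value is not None else math.nan


@dataclass
class IncrementalResult:
    """Incremental (screening - standard care) results per participant."""

    d_life_years: float
    d_qalys: float
    d_lc_deaths: float
    d_cost_detection: float
    d_cost_false_positive: float
    d_cost_dx_tx: float
    icer_per_qaly: ICER = field(init=False)
    icer_per_ly: ICER = field(init=False)
    cost_per_death_averted: ICER = field(init=False)
    overdiagnosis_per_10k: Optional[float] = None
    fp_surgeries_per_10k: Optional[float] = None

    @property
    def d_cost_total(self) -> float:
        return self.d_cost_detection + self.d_cost_false_positive + self.d_cost_dx_tx

    def __post_init__(self) -> None:
        self.icer_per_qaly = ICER.from_deltas(self.d_cost_total, self.d_qalys)
        self.icer_per_ly = ICER.from_deltas(self.d_cost_total, self.d_life_years)
        self.cost_per_death_averted = ICER.from_deltas(self.d_cost_total, -self.d_lc_deaths)


def incremental(screen: ArmResult, soc: ArmResult) -> IncrementalResult:
    """Componentwise screening-minus-standard-care differences and ICERs."""
    if screen.stratum_key != soc.stratum_key:
        raise ValueError("arm results come from different strata")
    return IncrementalResult(
        d_life_years=screen.life_years - soc.life_years,
        d_qalys=screen.qalys - soc.qalys,
        d_lc_deaths=screen.lc_deaths - soc.lc_deaths,
        d_cost_detection=screen.cost_detection - soc.cost_detection,
        d_cost_false_positive=screen.cost_false_positive - soc.cost_false_positive,
        d_cost_dx_tx=screen.cost_dx_tx - soc.cost_dx_tx,
    )


def overdiagnosis_fraction(
    params: ParamSet,
    stratum: Optional[Stratum] = None,
    compiled: Optional[CompiledModel] = None,
) -> float:
    """Proportion of screen-detected cancers never diagnosed without screening.

    Runs the standard-care undiagnosed sub-chain on the screen-detected
    cohort and returns the mass absorbed by other-cause death before
    diagnosis.  Pooled over strata (weighted by screen-detected mass) when
    no stratum is given.  Requires calibrated diagnosis probabilities in
    ``params`` for a meaningful result.
    """
    cm = compiled if compiled is not None else compile_params(params)
    diag_full = cm.p_diag
    if stratum is not None:
        row = cm.stratum_index(stratum.key)
        _, oc_dead = _subchain(cm, diag_full, rows=np.array([row]))
        return float(oc_dead[0])
    _, oc_dead = _subchain(cm, diag_full)
    w = cm.weights * cm.prevalence  # screen-detected mass per stratum
    total = w.sum()
    return float((w * oc_dead).sum() / total) if total > 0 else 0.0


def fp_surgeries(n_screened: float, params: ParamSet) -> int:
    """Expected surgeries on false-positive benign nodules, for reporting."""
    cm = compile_params(params)
    mean_fp = float((cm.weights * cm.p_fp_ldct).sum() / cm.weights.sum())
    expected = n_screened * mean_fp * params.screening.p_surgery_given_fp
    return _round_half_away(expected)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def aggregate_subgroups(
    weighted: Iterable[Tuple[float, IncrementalResult]]
) -> IncrementalResult:
    """Population-level incremental result from weighted subgroup results."""
    weighted = list(weighted)
    total_w = sum(w for w, _ in weighted)
    if abs(total_w - 1.0) > WEIGHT_TOL:
        raise ValueError(f"subgroup weights sum to {total_w!r}, expected 1")

    def avg(attr: str) -> float:
        return sum(w * getattr(r, attr) for w, r in weighted)

    out = IncrementalResult(
        d_life_years=avg("d_life_years"),
        d_qalys=avg("d_qalys"),
        d_lc_deaths=avg("d_lc_deaths"),
        d_cost_detection=avg("d_cost_detection"),
        d_cost_false_positive=avg("d_cost_false_positive"),
        d_cost_dx_tx=avg("d_cost_dx_tx"),
    )
    if all(r.overdiagnosis_per_10k is not None for _, r in weighted):
        out.overdiagnosis_per_10k = avg("overdiagnosis_per_10k")
    if all(r.fp_surgeries_per_10k is not None for _, r in weighted):
        out.fp_surgeries_per_10k = avg("fp_surgeries_per_10k")
    return out


def scale_per_10k(result: IncrementalResult, n: int = 10_000) -> Dict[str, int]:
    """Per-10,000-screened reporting table (rounded half away from zero)."""
    return {
        "life_years_saved": _round_half_away(result.d_life_years * n),
        "qalys_gained": _round_half_away(result.d_qalys * n),
        "lc_deaths_averted": _round_half_away(-result.d_lc_deaths * n),
        "incremental_total_cost": _round_half_away(result.d_cost_total * n),
    }


# ---------------------------------------------------------------------------
# deterministic full pipeline

@dataclass
class DeterministicResult:
    pooled: IncrementalResult
    by_stratum: Dict[str, IncrementalResult]
    arm_results: Dict[str, Dict[str, ArmResult]]  # arm -> stratum key -> result
    params: ParamSet  # calibrated parameter set actually run


def run_deterministic(
    params: ParamSet,
    recalibrate: bool = True,
    calibration_tolerance: float = 1e-4,
) -> DeterministicResult:
    """Calibrate (optionally) and run both arms for every stratum.

    The pooled result also carries the overdiagnosis and false-positive
    surgery counts per 10,000 screened.
    """
    if recalibrate:
        params, record = calibrate_paramset(params, tolerance=calibration_tolerance)
        if not record.converged:
            raise RuntimeError(
                f"calibration failed (max deviation {record.max_abs_dev:.3g})"
            )
    cm = compile_params(params)
    res = {arm: run_all_strata(cm, arm) for arm in ("screening", "standard_care")}

    arm_results: Dict[str, Dict[str, ArmResult]] = {"screening": {}, "standard_care": {}}
    by_stratum: Dict[str, IncrementalResult] = {}
    weighted = []
    for i, key in enumerate(cm.keys):
        for arm in arm_results:
            r = res[arm]
            arm_results[arm][key] = ArmResult(
                arm=arm,
                stratum_key=key,
                life_years=float(r["life_years"][i]),
                qalys=float(r["qalys"][i]),
                cost_detection=float(r["cost_detection"][i]),
                cost_false_positive=float(r["cost_false_positive"][i]),
                cost_dx_tx=float(r["cost_dx_tx"][i]),
                lc_deaths=float(r["lc_deaths"][i]),
                oc_deaths=float(r["oc_deaths"][i]),
                diagnoses_by_stage={
                    s: float(r["diagnoses_by_stage"][i, j]) for j, s in enumerate(STAGES)
                },
            )
        inc = incremental(arm_results["screening"][key], arm_results["standard_care"][key])
        by_stratum[key] = inc
        weighted.append((float(cm.weights[i]), inc))

    pooled = aggregate_subgroups(weighted)
    overdiag = overdiagnosis_fraction(params, compiled=cm)
    pooled.overdiagnosis_per_10k = overdiag * float(
        (cm.weights * cm.prevalence).sum()
    ) * 10_000
    pooled.fp_surgeries_per_10k = float(fp_surgeries(10_000, params))
    return DeterministicResult(
        pooled=pooled, by_stratum=by_stratum, arm_results=arm_results, params=params
    )
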