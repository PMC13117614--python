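"""Short-term decision tree: baseline state allocation and one-off costs.

A single screening round (or its absence) splits each stratum's cohort at
time zero.  In the screening arm the screen-detectable prevalence enters the
diagnosed states directly (stage distribution of screen-detected cancers);
false negatives are not modelled, so the standard-care arm starts with the
same mass in the *undiagnosed* states with the same stage distribution — the
structural identity that makes the comparison incremental-only.  False
positives are costed once at time zero and thereafter indistinguishable from
people with no lung cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .param_model import (
    STAGES,
    ParamSet,
    Stratum,
    fp_band,
)

ARMS = ("screening", "standard_care")


@dataclass
class BaselineAllocation:
    """Cohort occupancy and one-off accounting at model start for one arm."""

    arm: str
    stratum_key: str
    #: proportions over {no_lc, undiag_I..IV, diag_I..IV}; screening has no
    #: undiagnosed mass, standard care no diagnosed mass
    occupancy: Dict[str, float]
    fp_fraction: float
    oneoff_cost: Dict[str, float] = field(default_factory=dict)
    oneoff_qaly_decrement: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.occupancy.values())


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def _fp_fraction(stratum: Stratum, params: ParamSet, arm: str) -> float:
    """Proportion of the stratum experiencing a false positive at baseline."""
    sc = params.screening
    p = sc.prevalence_by_stratum[stratum.key]
    if arm == "screening":
        return (1.0 - p) * sc.p_fp_ldct_by_ageband[fp_band(stratum.start_age)]
    return (1.0 - p) * sc.p_checkup_year1 * sc.p_fp_xray


def oneoff_detection_cost(stratum: Stratum, params: ParamSet, arm: str) -> float:
    """First-year detection cost per person (EUR) for the given arm.

    Standard care: check-up attendance within the first year times the cost
    of one check-up visit (so zero attendance means zero detection cost).
    """
    _check_arm(arm)
    if arm == "screening":
        return params.costs.c_detection_screen
    return params.screening.p_checkup_year1 * params.costs.c_checkup_standard


def oneoff_fp_cost_and_disutility(
    stratum: Stratum, params: ParamSet, arm: str
) -> tuple[float, float]:
    """One-off false-positive cost (EUR) and QALY decrement per person.

    The QALY decrement bundles screening anxiety (all screened participants)
    with the false-positive disutility (false positives only); both are
    applied once, undiscounted, at time zero.
    """
    _check_arm(arm)
    ut = params.utilities
    fp = _fp_fraction(stratum, params, arm)
    if arm == "screening":
        cost = fp * params.costs.c_fp_ldct
        decrement = ut.disutility_screen + ut.disutility_fp * fp
    else:
        cost = fp * params.costs.c_fp_xray
        decrement = ut.disutility_fp * fp
    return cost, decrement


def allocate_baseline(stratum: Stratum, params: ParamSet, arm: str) -> BaselineAllocation:
    """Distribute one stratum's cohort over health states at model start.

    Screening arm: prevalence ``p`` enters the diagnosed year-1 states with
    the screening stage distribution; everyone else is no-LC (false
    positives included, after their one-off cost).  Standard-care arm: the
    same mass ``p`` enters the undiagnosed states with the same stage
    distribution (screen-detectable but undetected), the rest is no-LC.
    """
    _check_arm(arm)
    sc = params.screening
    p = sc.prevalence_by_stratum[stratum.key]
    dist = sc.stage_dist_screen.as_tuple()

    occupancy = {"no_lc": 1.0 - p}
    for stage, share in zip(STAGES, dist):
        mass = p * share
        occupancy[f"undiag_{stage}"] = mass if arm == "standard_care" else 0.0
        occupancy[f"diag_{stage}"] = mass if arm == "screening" else 0.0

    fp = _fp_fraction(stratum, params, arm)
    fp_cost, decrement = oneoff_fp_cost_and_disutility(stratum, params, arm)
    return BaselineAllocation(
        arm=arm,
        stratum_key=stratum.key,
        occupancy=occupancy,
        fp_fraction=fp,
        oneoff_cost={
            "detection": oneoff_detection_cost(stratum, params, arm),
            "false_positive": fp_cost,
        },
        oneoff_qaly_decrement=decrement,
    )
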