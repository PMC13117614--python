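"""Parameter model: typed containers, validation, (de)serialisation.

The whole analysis is driven by one :class:`ParamSet` holding the cohort
strata, screening-test characteristics, transition probabilities, utilities,
costs and economic settings.  Probabilities are stored on the 3-month cycle
scale internally; parameter files may declare annual scales per block (see
:func:`load_params`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

logger = logging.getLogger(__name__)

Sex = Literal["male", "female"]
SEXES: tuple[str, ...] = ("male", "female")
AGE_GROUPS: tuple[str, ...] = ("55-59", "60-64", "65-69", "70-74", "75-79", "80")
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")
UTILITY_BANDS: tuple[str, ...] = ("55-64", "65-74", "75+")
MORTALITY_BANDS: tuple[str, ...] = ("55-69", "70-84")
FP_BANDS: tuple[str, ...] = ("lt65", "ge65")

#: representative model-entry age per age group (band midpoints; the open
#: "80" group enters at exactly 80).
START_AGE: Dict[str, float] = {
    "55-59": 57.5,
    "60-64": 62.5,
    "65-69": 67.5,
    "70-74": 72.5,
    "75-79": 77.5,
    "80": 80.0,
}

SUM_TOL = 1e-9
PREV_TOL = 1e-6


def stratum_key(sex: str, age_group: str) -> str:
    return f"{sex}:{age_group}"


def utility_band(age: float) -> str:
    if age < 65:
        return "55-64"
    if age < 75:
        return "65-74"
    return "75+"


def mortality_band(age: float) -> str:
    # ages above 84 carry the 70-84 band forward
    return "55-69" if age < 70 else "70-84"


def fp_band(age: float) -> str:
    return "lt65" if age < 65 else "ge65"


class _Model(BaseModel):
    model_config = ConfigDict(extra="ignore", validate_assignment=False)


class Stratum(_Model):
    sex: Sex
    age_group: str
    weight: float

    @property
    def key(self) -> str:
        return stratum_key(self.sex, self.age_group)

    @property
    def start_age(self) -> float:
        return START_AGE[self.age_group]


class StageDistribution(_Model):
    """Proportions over stages I-IV; must sum to one."""

    p_I: float
    p_II: float
    p_III: float
    p_IV: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_I, self.p_II, self.p_III, self.p_IV)

    @classmethod
    def from_sequence(cls, values) -> "StageDistribution":
        v = list(values)
        return cls(p_I=v[0], p_II=v[1], p_III=v[2], p_IV=v[3])


class ScreeningParams(_Model):
    overall_prevalence: float
    prevalence_by_stratum: Dict[str, float]
    stage_dist_screen: StageDistribution
    stage_dist_standard: StageDistribution
    p_fp_ldct_by_ageband: Dict[str, float]  # keys: lt65, ge65
    p_fp_xray: float
    p_checkup_year1: float
    p_surgery_given_fp: float


class TransitionParams(_Model):
    #: 3-month progression probabilities for undiagnosed stages I->II, II->III, III->IV
    p_progress_3m: Dict[str, float]
    #: 3-month diagnosis probabilities from undiagnosed stages I-IV
    #: (I-III are calibration outputs; IV is fixed from its source)
    p_diagnose_3m: Dict[str, float]
    #: lung-cancer death probabilities, years 1-5 since diagnosis:
    #: sex -> age band ("55-69"/"70-84") -> stage -> [year1..year5]
    p_lc_death_3m_y1to5: Dict[str, Dict[str, Dict[str, List[float]]]]
    #: single 3-month LC death probability from year 6 until death
    p_lc_death_3m_post5: float
    #: other-cause death, sex -> single year of age -> 3-month probability
    p_oc_death_3m: Dict[str, Dict[int, float]]
    max_age: float = 100.0


class UtilityParams(_Model):
    #: sex -> age band ("55-64"/"65-74"/"75+") -> utility without lung cancer
    u_no_lc: Dict[str, Dict[str, float]]
    u_lc_stageI: float
    ratio_II: float
    ratio_III: float
    ratio_IV: float
    disutility_screen: float
    disutility_fp: float
    #: scenario switch: from year 6 since diagnosis use the no-LC utility
    u_post5_equals_no_lc: bool = False

    def stage_ratio(self, stage: str) -> float:
        return {"I": 1.0, "II": self.ratio_II, "III": self.ratio_III, "IV": self.ratio_IV}[stage]


class CostParams(_Model):
    c_detection_screen: float
    #: cost of one standard-care check-up visit (respiratory tests + X-ray);
    #: the per-person year-1 detection cost is attendance x this, and the
    #: same visit cost attaches to each person diagnosed after year 1
    c_checkup_standard: float
    c_fp_ldct: float
    c_fp_xray: float
    c_dx_tx_by_stage: Dict[str, float]


class EconSettings(_Model):
    cycle_length: float = 0.25
    annual_discount_rate: float = 0.03
    wtp_threshold: float = 25_000.0
    half_cycle_correction: bool = True

    @property
    def cycles_per_year(self) -> int:
        return round(1.0 / self.cycle_length)


class ParamSet(_Model):
    strata: List[Stratum]
    screening: ScreeningParams
    transitions: TransitionParams
    utilities: UtilityParams
    costs: CostParams
    econ: EconSettings

    def stratum(self, key: str) -> Stratum:
        for s in self.strata:
            if s.key == key:
                return s
        raise KeyError(key)

    def copy_deep(self) -> "ParamSet":
        return self.model_copy(deep=True)


# ---------------------------------------------------------------------------
# validation

@dataclass
class Issue:
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


@dataclass
class ValidationReport:
    issues: List[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, path: str, message: str) -> None:
        self.issues.append(Issue(path, message))

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise ValueError(
                "invalid parameter set:\n" + "\n".join(str(i) for i in self.issues)
            )


def _check_prob(report: ValidationReport, path: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.add(path, f"probability {value!r} outside [0, 1]")


def _check_dist(report: ValidationReport, path: str, dist: StageDistribution) -> None:
    total = 0.0
    for stage, v in zip(STAGES, dist.as_tuple()):
        _check_prob(report, f"{path}.p_{stage}", v)
        total += v
    if abs(total - 1.0) > SUM_TOL:
        report.add(path, f"stage proportions sum to {total!r}, expected 1")


def validate_params(params: ParamSet) -> ValidationReport:
    """Check every numeric invariant of a structurally complete ParamSet.

    Returns a report listing one issue per violated invariant, with a dotted
    path to the offending field; an empty report means the set is valid.
    """
    r = ValidationReport()

    # strata -------------------------------------------------------------
    total_w = 0.0
    seen = set()
    for i, s in enumerate(params.strata):
        path = f"strata[{i}]"
        if s.age_group not in AGE_GROUPS:
            r.add(f"{path}.age_group", f"unknown age group {s.age_group!r}")
        if not (0.0 <= s.weight <= 1.0):
            r.add(f"{path}.weight", f"weight {s.weight!r} outside [0, 1]")
        if s.key in seen:
            r.add(path, f"duplicate stratum {s.key!r}")
        seen.add(s.key)
        total_w += s.weight
    if abs(total_w - 1.0) > SUM_TOL:
        r.add("strata", f"weights sum to {total_w!r}, expected 1")

    # screening ----------------------------------------------------------
    sc = params.screening
    _check_dist(r, "screening.stage_dist_screen", sc.stage_dist_screen)
    _check_dist(r, "screening.stage_dist_standard", sc.stage_dist_standard)
    for band in FP_BANDS:
        if band not in sc.p_fp_ldct_by_ageband:
            r.add(f"screening.p_fp_ldct_by_ageband.{band}", "missing band")
        else:
            _check_prob(r, f"screening.p_fp_ldct_by_ageband.{band}",
                        sc.p_fp_ldct_by_ageband[band])
    for name in ("p_fp_xray", "p_checkup_year1", "p_surgery_given_fp",
                 "overall_prevalence"):
        _check_prob(r, f"screening.{name}", getattr(sc, name))
    wmean = 0.0
    for i, s in enumerate(params.strata):
        p = sc.prevalence_by_stratum.get(s.key)
        if p is None:
            r.add(f"screening.prevalence_by_stratum.{s.key}", "missing stratum")
            continue
        _check_prob(r, f"screening.prevalence_by_stratum.{s.key}", p)
        wmean += s.weight * p
    if abs(wmean - sc.overall_prevalence) > PREV_TOL:
        r.add("screening.prevalence_by_stratum",
              f"weighted mean {wmean!r} != overall_prevalence "
              f"{sc.overall_prevalence!r}")

    # transitions --------------------------------------------------------
    tr = params.transitions
    for stage in ("I", "II", "III"):
        if stage not in tr.p_progress_3m:
            r.add(f"transitions.p_progress_3m.{stage}", "missing stage")
        else:
            _check_prob(r, f"transitions.p_progress_3m.{stage}", tr.p_progress_3m[stage])
    for stage in STAGES:
        if stage not in tr.p_diagnose_3m:
            r.add(f"transitions.p_diagnose_3m.{stage}", "missing stage")
        else:
            _check_prob(r, f"transitions.p_diagnose_3m.{stage}", tr.p_diagnose_3m[stage])
    for sex in SEXES:
        for band in MORTALITY_BANDS:
            for stage in STAGES:
                path = f"transitions.p_lc_death_3m_y1to5.{sex}.{band}.{stage}"
                try:
                    years = tr.p_lc_death_3m_y1to5[sex][band][stage]
                except KeyError:
                    r.add(path, "missing entry")
                    continue
                if len(years) != 5:
                    r.add(path, f"expected 5 yearly values, got {len(years)}")
                for y, v in enumerate(years, start=1):
                    _check_prob(r, f"{path}[year {y}]", v)
    _check_prob(r, "transitions.p_lc_death_3m_post5", tr.p_lc_death_3m_post5)
    for sex in SEXES:
        ages = tr.p_oc_death_3m.get(sex)
        if not ages:
            r.add(f"transitions.p_oc_death_3m.{sex}", "missing sex")
            continue
        for age, v in ages.items():
            _check_prob(r, f"transitions.p_oc_death_3m.{sex}[{age}]", v)
            if age >= tr.max_age and v < 1.0 - 1e-12:
                r.add(f"transitions.p_oc_death_3m.{sex}[{age}]",
                      f"death must be certain at age {tr.max_age}")
        if max(ages) < tr.max_age:
            r.add(f"transitions.p_oc_death_3m.{sex}",
                  f"no entry at max_age {tr.max_age}; death there must be certain")

    # utilities ----------------------------------------------------------
    ut = params.utilities
    for sex in SEXES:
        bands = ut.u_no_lc.get(sex, {})
        for band in UTILITY_BANDS:
            if band not in bands:
                r.add(f"utilities.u_no_lc.{sex}.{band}", "missing band")
            else:
                v = bands[band]
                if not (0.0 <= v <= 1.0):
                    r.add(f"utilities.u_no_lc.{sex}.{band}", f"utility {v!r} outside [0, 1]")
    if not (0.0 <= ut.u_lc_stageI <= 1.0):
        r.add("utilities.u_lc_stageI", f"utility {ut.u_lc_stageI!r} outside [0, 1]")
    for name in ("ratio_II", "ratio_III", "ratio_IV"):
        v = getattr(ut, name)
        if not (0.0 < v <= 1.0):
            r.add(f"utilities.{name}", f"ratio {v!r} outside (0, 1]")
    # LC utilities may never exceed the no-LC utility of the same sex; with
    # the multiplicative age decline the binding comparison is the youngest
    # band (stage I, ratio 1 being the largest LC utility).
    for sex in SEXES:
        base = ut.u_no_lc.get(sex, {}).get("55-64")
        if base is not None and ut.u_lc_stageI > base + 1e-12:
            r.add("utilities.u_lc_stageI",
                  f"stage-I utility {ut.u_lc_stageI!r} exceeds no-LC utility "
                  f"{base!r} for {sex}")
    for name in ("disutility_screen", "disutility_fp"):
        if getattr(ut, name) < 0:
            r.add(f"utilities.{name}", "disutility must be >= 0")

    # costs --------------------------------------------------------------
    co = params.costs
    for name in ("c_detection_screen", "c_checkup_standard",
                 "c_fp_ldct", "c_fp_xray"):
        if getattr(co, name) < 0:
            r.add(f"costs.{name}", "cost must be >= 0")
    for stage in STAGES:
        if stage not in co.c_dx_tx_by_stage:
            r.add(f"costs.c_dx_tx_by_stage.{stage}", "missing stage")
        elif co.c_dx_tx_by_stage[stage] < 0:
            r.add(f"costs.c_dx_tx_by_stage.{stage}", "cost must be >= 0")

    # econ ---------------------------------------------------------------
    if params.econ.cycle_length <= 0:
        r.add("econ.cycle_length", "cycle length must be > 0")
    if params.econ.annual_discount_rate < 0:
        r.add("econ.annual_discount_rate", "discount rate must be >= 0")

    return r


# ---------------------------------------------------------------------------
# probability scale conversion

def to_cycle_prob(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual probability to a per-cycle probability.

    Uses the constant-rate identity ``1 - (1 - p)**(1/n)``, the standard
    conversion in state-transition models.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability {p_annual!r} outside [0, 1]")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def to_annual_prob(p_cycle: float, cycles_per_year: int) -> float:
    """Inverse of :func:`to_cycle_prob`."""
    if not (0.0 <= p_cycle <= 1.0):
        raise ValueError(f"cycle probability {p_cycle!r} outside [0, 1]")
    return 1.0 - (1.0 - p_cycle) ** cycles_per_year


# ---------------------------------------------------------------------------
# serialisation

class ParamFileError(ValueError):
    pass


def _convert_scaled_blocks(node, cycles_per_year: int):
    """Recursively honour ``scale: annual|cycle`` tags on mapping blocks."""
    if isinstance(node, dict):
        scale = node.pop("scale", None)
        out = {k: _convert_scaled_blocks(v, cycles_per_year) for k, v in node.items()}
        if scale == "annual":
            out = _apply_to_leaves(out, lambda v: to_cycle_prob(v, cycles_per_year))
        elif scale not in (None, "cycle"):
            raise ParamFileError(f"unknown scale tag {scale!r}")
        return out
    if isinstance(node, list):
        return [_convert_scaled_blocks(v, cycles_per_year) for v in node]
    return node


def _apply_to_leaves(node, fn):
    if isinstance(node, dict):
        return {k: _apply_to_leaves(v, fn) for k, v in node.items()}
    if isinstance(node, list):
        return [_apply_to_leaves(v, fn) for v in node]
    if isinstance(node, bool) or not isinstance(node, (int, float)):
        return node
    return fn(float(node))


_TOP_KEYS = {"strata", "screening", "transitions", "utilities", "costs", "econ"}


def load_params(path: str | Path) -> ParamSet:
    """Load a ParamSet from a YAML (or JSON) parameter file.

    Probability blocks carrying ``scale: annual`` are converted to the
    3-month cycle scale on load.  Unknown keys are ignored with a logged
    warning; missing sections raise :class:`ParamFileError` naming the field.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParamFileError(f"parameter file {path} is not a mapping")
    cpy = 4
    econ = data.get("econ")
    if isinstance(econ, dict) and econ.get("cycle_length"):
        cpy = round(1.0 / float(econ["cycle_length"]))
    for key in set(data) - _TOP_KEYS:
        logger.warning("ignoring unknown key %r in %s", key, path)
    data = {k: v for k, v in data.items() if k in _TOP_KEYS}
    data = _convert_scaled_blocks(data, cpy)
    try:
        return ParamSet.model_validate(data)
    except ValidationError as exc:
        missing = [".".join(str(p) for p in e["loc"])
                   for e in exc.errors() if e["type"] == "missing"]
        if missing:
            raise ParamFileError(
                f"parameter file {path} is missing required field(s): "
                + ", ".join(missing)
            ) from exc
        raise ParamFileError(f"parameter file {path} failed to parse: {exc}") from exc


def save_params(params: ParamSet, path: str | Path, header: str | None = None) -> None:
    """Write a ParamSet to YAML; round-trips losslessly through load_params."""
    data = params.model_dump(mode="python")
    text = yaml.safe_dump(data, sort_keys=False, default_flow_style=False)
    if header:
        text = "".join(f"# {line}\n" for line in header.splitlines()) + text
    Path(path).write_text(text)
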