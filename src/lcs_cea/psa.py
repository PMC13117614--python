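"""Probabilistic sensitivity analysis.

Parameters are drawn independently per iteration: Beta distributions for
probabilities and utilities (method of moments around the base-case mean
with a configurable coefficient of variation), Gamma for costs, Dirichlet
for stage distributions, point mass for settings (discount rate, cycle
length) and for the registry-derived other-cause mortality.  Each iteration
re-calibrates the stage I-III diagnosis probabilities against its sampled
standard-care stage distribution (warm-started from the base-case solution),
runs both arms for every stratum, and aggregates with the stratum weights.
Results are summarised by means and 95% credible intervals (empirical
percentiles, linear interpolation between closest ranks) plus the
cost-effectiveness acceptability curve over a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from ._compile import compile_params
from .calibration import calibrate_paramset
from .markov_engine import run_all_strata
from .outcomes import ICER, IncrementalResult
from .param_model import MORTALITY_BANDS, SEXES, STAGES, UTILITY_BANDS, ParamSet, StageDistribution

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = (
    "d_life_years", "d_qalys", "d_lc_deaths",
    "d_cost_detection", "d_cost_false_positive", "d_cost_dx_tx", "d_cost_total",
)


class DistributionSpec(BaseModel):
    """Families and dispersion of the PSA parameter distributions."""

    model_config = ConfigDict(extra="forbid")

    cv_probability: float = 0.2
    cv_utility: float = 0.2
    cv_cost: float = 0.2
    dirichlet_concentration: float = 100.0
    #: global variance multiplier on the CVs; 0 collapses every draw to the
    #: base case (point mass)
    variance_scale: float = 1.0
    point_mass: bool = False

    def cv(self, kind: str) -> float:
        if self.point_mass:
            return 0.0
        return getattr(self, f"cv_{kind}") * self.variance_scale


def _beta(rng: np.random.Generator, mean, cv: float):
    """Beta draw(s) with the given mean and coefficient of variation."""
    m = np.asarray(mean, dtype=float)
    if cv <= 0:
        return m.item() if m.ndim == 0 else m
    var = (cv * m) ** 2
    cap = 0.95 * m * (1.0 - m)
    var = np.minimum(var, np.where(cap > 0, cap, np.inf))
    interior = (m > 0) & (m < 1) & (var > 0)
    nu = np.where(interior, m * (1.0 - m) / np.where(var > 0, var, 1.0) - 1.0, 1.0)
    a = np.where(interior, m * nu, 1.0)
    b = np.where(interior, (1.0 - m) * nu, 1.0)
    draw = rng.beta(a, b)
    out = np.where(interior, draw, m)
    return out.item() if out.ndim == 0 else out


def _gamma(rng: np.random.Generator, mean, cv: float):
    m = np.asarray(mean, dtype=float)
    if cv <= 0:
        return m.item() if m.ndim == 0 else m
    shape = 1.0 / cv**2
    draw = rng.gamma(shape, m / shape)
    out = np.where(m > 0, draw, 0.0)
    return out.item() if out.ndim == 0 else out


def _dirichlet(rng: np.random.Generator, dist: StageDistribution, conc: float) -> StageDistribution:
    if conc <= 0:
        return dist
    alpha = np.maximum(np.array(dist.as_tuple()) * conc, 1e-3)
    return StageDistribution.from_sequence(rng.dirichlet(alpha))


def draw_paramset(
    base: ParamSet, spec: DistributionSpec, rng_seed: int, iteration: int
) -> ParamSet:
    """Sample one valid ParamSet; deterministic given ``(rng_seed, iteration)``."""
    p = base.copy_deep()
    if spec.point_mass or spec.variance_scale == 0.0:
        return p
    rng = np.random.default_rng([int(rng_seed), int(iteration)])
    cvp, cvu, cvc = spec.cv("probability"), spec.cv("utility"), spec.cv("cost")
    conc = spec.dirichlet_concentration / max(spec.variance_scale, 1e-12) ** 2

    # screening block -----------------------------------------------------
    sc = p.screening
    new_overall = _beta(rng, sc.overall_prevalence, cvp)
    scale = new_overall / sc.overall_prevalence if sc.overall_prevalence > 0 else 0.0
    for k in sc.prevalence_by_stratum:
        sc.prevalence_by_stratum[k] = float(
            np.clip(sc.prevalence_by_stratum[k] * scale, 0.0, 1.0)
        )
    sc.overall_prevalence = float(
        sum(s.weight * sc.prevalence_by_stratum[s.key] for s in p.strata)
    )
    sc.stage_dist_screen = _dirichlet(rng, sc.stage_dist_screen, conc)
    sc.stage_dist_standard = _dirichlet(rng, sc.stage_dist_standard, conc)
    for band in sc.p_fp_ldct_by_ageband:
        sc.p_fp_ldct_by_ageband[band] = _beta(rng, sc.p_fp_ldct_by_ageband[band], cvp)
    sc.p_fp_xray = _beta(rng, sc.p_fp_xray, cvp)
    sc.p_checkup_year1 = _beta(rng, sc.p_checkup_year1, cvp)
    sc.p_surgery_given_fp = _beta(rng, sc.p_surgery_given_fp, cvp)

    # transitions (other-cause mortality stays fixed: registry-derived) ----
    tr = p.transitions
    for s in tr.p_progress_3m:
        tr.p_progress_3m[s] = _beta(rng, tr.p_progress_3m[s], cvp)
    tr.p_diagnose_3m["IV"] = _beta(rng, tr.p_diagnose_3m["IV"], cvp)
    for sex in SEXES:
        for band in MORTALITY_BANDS:
            for stage in STAGES:
                years = tr.p_lc_death_3m_y1to5[sex][band][stage]
                tr.p_lc_death_3m_y1to5[sex][band][stage] = [
                    float(v) for v in _beta(rng, np.array(years), cvp)
                ]
    tr.p_lc_death_3m_post5 = _beta(rng, tr.p_lc_death_3m_post5, cvp)

    # utilities ------------------------------------------------------------
    ut = p.utilities
    for sex in SEXES:
        for band in UTILITY_BANDS:
            ut.u_no_lc[sex][band] = _beta(rng, ut.u_no_lc[sex][band], cvu)
    cap = min(ut.u_no_lc[sex]["55-64"] for sex in SEXES)
    ut.u_lc_stageI = float(min(_beta(rng, ut.u_lc_stageI, cvu), cap))
    ut.ratio_II = float(np.clip(_beta(rng, ut.ratio_II, cvu), 1e-9, 1.0))
    ut.ratio_III = float(np.clip(_beta(rng, ut.ratio_III, cvu), 1e-9, 1.0))
    ut.ratio_IV = float(np.clip(_beta(rng, ut.ratio_IV, cvu), 1e-9, 1.0))
    ut.disutility_screen = _gamma(rng, ut.disutility_screen, cvu)
    ut.disutility_fp = _gamma(rng, ut.disutility_fp, cvu)

    # costs ----------------------------------------------------------------
    co = p.costs
    for name in ("c_detection_screen", "c_checkup_standard",
                 "c_fp_ldct", "c_fp_xray"):
        setattr(co, name, _gamma(rng, getattr(co, name), cvc))
    for stage in co.c_dx_tx_by_stage:
        co.c_dx_tx_by_stage[stage] = _gamma(rng, co.c_dx_tx_by_stage[stage], cvc)

    return p


# ---------------------------------------------------------------------------

def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical central credible interval (linear-interpolation percentiles)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a credible interval")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [tail, 100.0 - tail], method="linear")
    return float(lo), float(hi)


@dataclass
class PSAResult:
    n_iter: int
    n_failed: int
    seed: int
    iterations: pd.DataFrame  # one row per successful iteration
    summaries: Dict[str, Dict[str, float]]
    ceac: pd.DataFrame  # columns: threshold, probability
    icer_per_qaly: ICER
    mean_result: IncrementalResult

    @property
    def ce_plane(self) -> pd.DataFrame:
        return self.iterations[["d_qalys", "d_cost_total"]].copy()

    def ceac_at(self, threshold: float) -> float:
        it = self.iterations
        return float((threshold * it["d_qalys"] - it["d_cost_total"] >= 0).mean())


def _pooled_deltas(cm) -> Dict[str, float]:
    scr = run_all_strata(cm, "screening")
    soc = run_all_strata(cm, "standard_care")
    w = cm.weights

    def agg(name: str) -> float:
        return float((w * (scr[name] - soc[name])).sum())

    out = {
        "d_life_years": agg("life_years"),
        "d_qalys": agg("qalys"),
        "d_lc_deaths": agg("lc_deaths"),
        "d_cost_detection": agg("cost_detection"),
        "d_cost_false_positive": agg("cost_false_positive"),
        "d_cost_dx_tx": agg("cost_dx_tx"),
    }
    out["d_cost_total"] = (
        out["d_cost_detection"] + out["d_cost_false_positive"] + out["d_cost_dx_tx"]
    )
    return out


def default_thresholds() -> np.ndarray:
    return np.arange(0, 60_001, 1_000, dtype=float)


def run_psa(
    base: ParamSet,
    spec: Optional[DistributionSpec] = None,
    n_iter: int = 2000,
    seed: int = 0,
    recalibrate: bool = True,
    thresholds: Optional[np.ndarray] = None,
    calibration_tolerance: float = 1e-4,
) -> PSAResult:
    """Run the full pipeline over ``n_iter`` sampled parameter sets.

    Iterations whose calibration fails to converge are flagged, excluded and
    counted in ``n_failed``; they are never silently dropped.
    """
    spec = spec or DistributionSpec()
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds)

    warm = None
    if recalibrate:
        base_cal, rec = calibrate_paramset(base, tolerance=calibration_tolerance)
        if not rec.converged:
            raise RuntimeError("base-case calibration failed; PSA aborted")
        warm = [base_cal.transitions.p_diagnose_3m[s] for s in ("I", "II", "III")]

    rows = []
    n_failed = 0
    for i in range(n_iter):
        params_i = draw_paramset(base, spec, seed, i)
        if recalibrate:
            cm_pre = compile_params(params_i)
            params_i, rec = calibrate_paramset(
                params_i, tolerance=calibration_tolerance, x0=warm, compiled=cm_pre
            )
            if not rec.converged:
                n_failed += 1
                logger.warning("iteration %d: calibration failed, excluded", i)
                continue
        cm = compile_params(params_i)
        rows.append(_pooled_deltas(cm))

    iterations = pd.DataFrame(rows, columns=list(OUTCOME_COLUMNS))
    summaries: Dict[str, Dict[str, float]] = {}
    for col in OUTCOME_COLUMNS:
        x = iterations[col].to_numpy()
        lo, hi = credible_interval(x) if x.size >= 2 else (float("nan"), float("nan"))
        summaries[col] = {"mean": float(x.mean()), "ci_low": lo, "ci_high": hi}

    mean_result = IncrementalResult(
        d_life_years=summaries["d_life_years"]["mean"],
        d_qalys=summaries["d_qalys"]["mean"],
        d_lc_deaths=summaries["d_lc_deaths"]["mean"],
        d_cost_detection=summaries["d_cost_detection"]["mean"],
        d_cost_false_positive=summaries["d_cost_false_positive"]["mean"],
        d_cost_dx_tx=summaries["d_cost_dx_tx"]["mean"],
    )

    dq = iterations["d_qalys"].to_numpy()
    dc = iterations["d_cost_total"].to_numpy()
    ceac = pd.DataFrame({
        "threshold": thresholds,
        "probability": [
            float((lam * dq - dc >= 0).mean()) if dq.size else float("nan")
            for lam in thresholds
        ],
    })

    return PSAResult(
        n_iter=n_iter,
        n_failed=n_failed,
        seed=seed,
        iterations=iterations,
        summaries=summaries,
        ceac=ceac,
        icer_per_qaly=mean_result.icer_per_qaly,
        mean_result=mean_result,
    )
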