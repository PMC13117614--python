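"""Calibration of 3-month diagnosis probabilities for undiagnosed stages I-III.

The standard-care arm starts with screen-detectable (undiagnosed) cancers in
the screening stage distribution.  As the undiagnosed sub-chain runs
(other-cause death, diagnosis, stage progression; no lung-cancer death before
diagnosis), cancers drift to later stages before being found.  The
stage-I/II/III diagnosis probabilities are the free parameters tuned so that
the resulting distribution of stage *at diagnosis* matches the observed
standard-care distribution; the stage-IV diagnosis probability is fixed from
its source.

The solver is a damped multiplicative fixed-point iteration on stage shares
(update ``p_s <- p_s * (target_s / simulated_s)**0.5``), falling back to a
bounded derivative-free least-squares search if it fails to converge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from ._compile import CompiledModel, compile_params
from .param_model import ParamSet, StageDistribution, Stratum

logger = logging.getLogger(__name__)

_MASS_TOL = 1e-14


@dataclass
class CalibrationTarget:
    target_dist: StageDistribution
    tolerance: float = 1e-4
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ConvergenceRecord:
    iterations: int
    max_abs_dev: float
    converged: bool
    method: str
    diag_probs: dict[str, float]


def _subchain(
    cm: CompiledModel, diag_full: np.ndarray, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run the undiagnosed sub-chain from the screening stage distribution.

    Returns ``(diagnosed, oc_dead)`` where ``diagnosed`` is the (n, 4) mass
    ever diagnosed per stage and ``oc_dead`` the (n,) mass dying of other
    causes before diagnosis; each row starts with unit undiagnosed mass.
    """
    p_oc = cm.p_oc if rows is None else cm.p_oc[rows]
    n = p_oc.shape[0]
    undiag = np.tile(cm.dist_screen, (n, 1))
    diagnosed = np.zeros((n, 4))
    oc_dead = np.zeros(n)
    for t in range(cm.T):
        poc = p_oc[:, t]
        total = undiag.sum(axis=1)
        oc_dead += total * poc
        undiag *= (1.0 - poc)[:, None]
        newly = undiag * diag_full[None, :]
        diagnosed += newly
        undiag = undiag - newly
        move = undiag[:, :3] * cm.p_prog[None, :]
        undiag[:, :3] -= move
        undiag[:, 1:4] += move
        if undiag.sum(axis=1).max() < _MASS_TOL:
            break
    return diagnosed, oc_dead


def _pooled_shares(
    cm: CompiledModel, diag_full: np.ndarray, row: int | None
) -> np.ndarray:
    """Stage-at-diagnosis shares, pooled over strata or for a single one."""
    if row is None:
        diagnosed, _ = _subchain(cm, diag_full)
        mass = (cm.weights[:, None] * diagnosed).sum(axis=0)
    else:
        diagnosed, _ = _subchain(cm, diag_full, rows=np.array([row]))
        mass = diagnosed[0]
    total = mass.sum()
    if total <= 1e-12:
        logger.warning("degenerate stage-at-diagnosis distribution (no mass diagnosed)")
        out = np.zeros(4)
        out[3] = 1.0
        return out
    return mass / total


def simulate_stage_at_diagnosis(
    diag_probs,
    params: ParamSet,
    stratum: Optional[Stratum] = None,
    compiled: Optional[CompiledModel] = None,
) -> StageDistribution:
    """Distribution of stage at diagnosis under standard care.

    ``diag_probs`` are the stage I-III diagnosis probabilities; the stage-IV
    probability is taken from ``params``.  With ``stratum=None`` the
    stratum-weighted (pooled) distribution is returned.
    """
    cm = compiled if compiled is not None else compile_params(params)
    d = np.asarray(diag_probs, dtype=float)
    if d.shape != (3,) or ((d < 0) | (d > 1)).any():
        raise ValueError("diag_probs must be three probabilities in [0, 1]")
    diag_full = np.append(d, params.transitions.p_diagnose_3m["IV"])
    row = cm.stratum_index(stratum.key) if stratum is not None else None
    return StageDistribution.from_sequence(_pooled_shares(cm, diag_full, row))


def calibrate_diagnosis_probs(
    ctarget: CalibrationTarget,
    params: ParamSet,
    stratum: Optional[Stratum] = None,
    x0=None,
    damping: float = 0.5,
    compiled: Optional[CompiledModel] = None,
) -> tuple[dict[str, float], ConvergenceRecord]:
    """Find stage I-III diagnosis probabilities hitting the target distribution.

    Returns the probabilities and a convergence record; a failure to reach
    the tolerance is reported in the record (best-found values are still
    returned), never silently.
    """
    cm = compiled if compiled is not None else compile_params(params)
    p4 = params.transitions.p_diagnose_3m["IV"]
    target = np.array(ctarget.target_dist.as_tuple())
    row = cm.stratum_index(stratum.key) if stratum is not None else None

    if x0 is None:
        p = np.array([params.transitions.p_diagnose_3m[s] for s in ("I", "II", "III")])
    else:
        p = np.asarray(x0, dtype=float).copy()
    p = np.clip(p, 1e-6, 1.0)

    best_p, best_dev = p.copy(), np.inf
    n_eval = 0
    for it in range(ctarget.max_iterations):
        shares = _pooled_shares(cm, np.append(p, p4), row)
        n_eval += 1
        dev = float(np.abs(shares - target).max())
        if dev < best_dev:
            best_dev, best_p = dev, p.copy()
        if dev <= ctarget.tolerance:
            probs = {"I": float(p[0]), "II": float(p[1]), "III": float(p[2])}
            return probs, ConvergenceRecord(it + 1, dev, True, "fixed_point", probs)
        ratio = np.where(shares[:3] > 1e-12, target[:3] / np.maximum(shares[:3], 1e-12), 10.0)
        # where the target share is itself ~0 the probability is irrelevant;
        # leave it untouched to avoid drifting to the bounds
        ratio = np.where(target[:3] < 1e-12, 1.0, ratio)
        p = np.clip(p * ratio**damping, 1e-6, 1.0)

    # derivative-free fallback from the best fixed-point iterate
    def residuals(x):
        return _pooled_shares(cm, np.append(x, p4), row)[:3] - target[:3]

    sol = least_squares(
        residuals, np.clip(best_p, 1e-5, 1.0 - 1e-9),
        bounds=(1e-6, 1.0), diff_step=1e-6, xtol=1e-12, ftol=1e-12,
    )
    shares = _pooled_shares(cm, np.append(sol.x, p4), row)
    dev = float(np.abs(shares - target).max())
    if dev < best_dev:
        best_dev, best_p = dev, sol.x.copy()
    probs = {"I": float(best_p[0]), "II": float(best_p[1]), "III": float(best_p[2])}
    converged = best_dev <= ctarget.tolerance
    if not converged:
        logger.warning(
            "calibration did not converge: max deviation %.3g > tolerance %.3g",
            best_dev, ctarget.tolerance,
        )
    return probs, ConvergenceRecord(
        ctarget.max_iterations + sol.nfev, best_dev, converged, "least_squares", probs
    )


def calibrate_paramset(
    params: ParamSet,
    tolerance: float = 1e-4,
    max_iterations: int = 500,
    x0=None,
    compiled: Optional[CompiledModel] = None,
) -> tuple[ParamSet, ConvergenceRecord]:
    """Pooled calibration: write fitted diagnosis probabilities into a copy."""
    ctarget = CalibrationTarget(
        target_dist=params.screening.stage_dist_standard,
        tolerance=tolerance,
        max_iterations=max_iterations,
    )
    probs, record = calibrate_diagnosis_probs(
        ctarget, params, stratum=None, x0=x0, compiled=compiled
    )
    out = params.copy_deep()
    out.transitions.p_diagnose_3m.update(probs)
    return out, record
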