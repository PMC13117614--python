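"""CSV writers mirroring the published result tables and figures.

Every file carries a comment header with the seed and a hash of the
parameter configuration so outputs are traceable; numeric values are
unrounded in the machine variants, and the ``report`` variants round costs
to integers and effects to four decimals (the printed precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict

import pandas as pd

from .outcomes import DeterministicResult, scale_per_10k
from .param_model import ParamSet
from .psa import PSAResult
from .scenarios import ScenarioResults


def config_hash(params: ParamSet) -> str:
    payload = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, seed: int | None, chash: str) -> None:
    header = f"# seed={seed} config_hash={chash}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_summary_table(psa: PSAResult, params: ParamSet, path: str | Path) -> None:
    """Pooled PSA summaries (mean and 95% credible interval per outcome)."""
    rows = []
    for outcome, s in psa.summaries.items():
        rows.append({"outcome": outcome, **s})
    rows.append({
        "outcome": "icer_per_qaly",
        "mean": float(psa.icer_per_qaly),
        "ci_low": float("nan"),
        "ci_high": float("nan"),
    })
    _write_csv(pd.DataFrame(rows), Path(path), psa.seed, config_hash(params))


def write_subgroup_table(
    det: DeterministicResult, path: str | Path, seed: int | None = None
) -> None:
    """Per-subgroup incremental results (deterministic run)."""
    rows = []
    for key, inc in det.by_stratum.items():
        rows.append({
            "subgroup": key,
            "d_life_years": inc.d_life_years,
            "d_qalys": inc.d_qalys,
            "d_cost_detection": inc.d_cost_detection,
            "d_cost_false_positive": inc.d_cost_false_positive,
            "d_cost_dx_tx": inc.d_cost_dx_tx,
            "d_cost_total": inc.d_cost_total,
            "icer_per_qaly": float(inc.icer_per_qaly),
        })
    _write_csv(pd.DataFrame(rows), Path(path), seed, config_hash(det.params))


def write_per_10k_table(
    det: DeterministicResult, path: str | Path, n: int = 10_000,
    seed: int | None = None,
) -> None:
    table: Dict[str, float] = dict(scale_per_10k(det.pooled, n))
    if det.pooled.overdiagnosis_per_10k is not None:
        table["overdiagnosed_cancers"] = round(det.pooled.overdiagnosis_per_10k)
    if det.pooled.fp_surgeries_per_10k is not None:
        table["fp_surgeries"] = round(det.pooled.fp_surgeries_per_10k)
    df = pd.DataFrame([{"outcome": k, f"per_{n}_screened": v} for k, v in table.items()])
    _write_csv(df, Path(path), seed, config_hash(det.params))


def write_scenario_table(
    res: ScenarioResults, params: ParamSet, path: str | Path, seed: int | None = None
) -> None:
    _write_csv(res.table, Path(path), seed, config_hash(params))


def write_ce_plane(psa: PSAResult, params: ParamSet, path: str | Path) -> None:
    _write_csv(psa.ce_plane, Path(path), psa.seed, config_hash(params))


def write_ceac(psa: PSAResult, params: ParamSet, path: str | Path) -> None:
    _write_csv(psa.ceac, Path(path), psa.seed, config_hash(params))
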