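"""Tabular and JSON report writers for model results.

Reports mirror the study's result surface: per-arm costs of care, test
costs, totals, QALY loss, the incremental comparison, and the two threshold
prices (break-even, and the maximum test price at the willingness-to-pay).
Displayed values are rounded journal-style (whole EUR, two-decimal QALYs);
the JSON twin always carries the unrounded numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__, economics
from .parameters import ModelParameters


def base_case_report(result: economics.EconomicResult,
                     p: ModelParameters) -> dict[str, Any]:
    """Unrounded result mapping (the JSON twin of the printed table)."""
    care, geno = result.care_as_usual, result.genotyping
    return {
        "care_as_usual": _arm_dict(care),
        "genotyping": _arm_dict(geno),
        "delta_cost": result.delta_cost,
        "delta_qaly": result.delta_qaly,
        "care_savings": result.care_savings,
        "dominance": result.dominance,
        "icer": result.icer,
        "test_cost": result.test_cost,
        "wtp": p.wtp,
        "threshold_test_cost_at_wtp": economics.threshold_test_cost(
            p, p.wtp, result=result),
        "break_even_test_cost": economics.threshold_test_cost(
            p, 0.0, result=result),
        "discontinued": {
            "care_as_usual": care.trace.events["discontinued"],
            "genotyping": geno.trace.events["discontinued"],
        },
        "mean_length_of_stay": {
            "care_as_usual": _mean_los(care.trace),
            "genotyping": _mean_los(geno.trace),
        },
    }


def _arm_dict(arm: economics.ArmResult) -> dict[str, Any]:
    c = arm.costs
    return {"hospitalization": c.hospitalization, "monitoring": c.monitoring,
            "drugs": c.drugs, "genotyping": c.genotyping,
            "costs_of_care": c.care, "total_costs": c.total,
            "qaly_loss": arm.qaly_loss}


def _mean_los(trace) -> float:
    total = sum(trace.discharge_profile.values())
    return sum(los * n for los, n in trace.discharge_profile.items()) / total


def base_case_table(report: Mapping[str, Any]) -> pd.DataFrame:
    """Rounded, printable two-arm summary (rows follow the study's table)."""
    care, geno = report["care_as_usual"], report["genotyping"]
    rows = [
        ("Days of inpatient care (mean)",
         round(report["mean_length_of_stay"]["care_as_usual"], 2),
         round(report["mean_length_of_stay"]["genotyping"], 2)),
        ("Patients who stopped therapy (n)",
         round(report["discontinued"]["care_as_usual"]),
         round(report["discontinued"]["genotyping"])),
        ("Costs of care (EUR)", round(care["costs_of_care"]),
         round(geno["costs_of_care"])),
        ("Costs CYP2D6 genotyping (EUR)", round(care["genotyping"]),
         round(geno["genotyping"])),
        ("Total costs (EUR)", round(care["total_costs"]),
         round(geno["total_costs"])),
        ("QALY loss", round(care["qaly_loss"], 2), round(geno["qaly_loss"], 2)),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "care_as_usual", "genotyping"])
    df["difference"] = df["genotyping"] - df["care_as_usual"]
    return df


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output set."""

    command: str
    seed: int | None = None
    config_path: str | None = None
    config_hash: str | None = None
    scenario: str = "base"
    package_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S%z"))
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n",
                        encoding="utf-8")
        return path


def hash_config(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_json(data: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, indent=2, default=_jsonable) + "\n",
                    encoding="utf-8")
    return path


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
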