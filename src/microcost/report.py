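"""Report emission: breakdown and tornado tables in CSV/JSON form.

Values are carried unrounded through the model and rounded only here.
Reports use a period decimal separator regardless of locale. Currency is
USD by default; BRL output is derived through the catalog's fixed
exchange rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from .engine import COMPONENTS, CostBreakdown
from .resources import (
    MICROCOSTED_STEPS,
    PATHWAY_STEPS,
    REIMBURSED_STEPS,
    CurrencyRate,
    brl,
)

_COMPONENT_ROWS = {
    "consumables": "Consumables",
    "staff": "Staff",
    "equipment": "Equipment",
    "overhead": "Overhead",
}
_GENETIC_TOTAL_ROW = "Total Genetic Testing Cost per Exam"
_CLINICAL_ROW = "Clinical Evaluation"
_GRAND_TOTAL_ROW = "Total Cost per Exam"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ReportOptions:
    """Presentation options for emitted tables."""

    currency: str = "usd"  # "usd" or "brl"
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.currency not in ("usd", "brl"):
            raise ValueError("currency must be 'usd' or 'brl'")
        if self.decimals < 0:
            raise ValueError("decimals must be >= 0")


def _convert(value: float, options: ReportOptions, rate: CurrencyRate) -> float:
    out = brl(value, rate) if options.currency == "brl" else value
    return round(out, options.decimals)


def breakdown_frame(
    breakdown: CostBreakdown,
    options: ReportOptions = ReportOptions(),
    rate: Optional[CurrencyRate] = None,
) -> pd.DataFrame:
    """Step x component table with totals row and a Total column.

    Rows are the components, overhead, the genetic-testing total, the
    bundled clinical tariffs and the grand total; columns are the pathway
    steps in order plus a row-total column.
    """
    rate = rate or CurrencyRate()
    step_ids = [sc.step_id for sc in breakdown.per_step]
    columns = [PATHWAY_STEPS[s] for s in step_ids] + ["Total"]
    rows = {}
    for comp, label in _COMPONENT_ROWS.items():
        values = [getattr(sc, comp) for sc in breakdown.per_step]
        rows[label] = values + [breakdown.component_totals.get(comp, sum(values))]
    genetic = [
        sc.total if sc.step_id in MICROCOSTED_STEPS else 0.0
        for sc in breakdown.per_step
    ]
    clinical = [
        sc.total if sc.step_id in REIMBURSED_STEPS else 0.0
        for sc in breakdown.per_step
    ]
    rows[_GENETIC_TOTAL_ROW] = genetic + [breakdown.genetic_testing_total]
    rows[_CLINICAL_ROW] = clinical + [breakdown.clinical_total]
    rows[_GRAND_TOTAL_ROW] = [sc.total for sc in breakdown.per_step] + [
        breakdown.grand_total
    ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return frame.map(lambda v: _convert(v, options, rate))


def emit_breakdown(
    breakdown: CostBreakdown,
    options: ReportOptions = ReportOptions(),
    csv_path: Optional[Union[str, Path]] = None,
    json_path: Optional[Union[str, Path]] = None,
    rate: Optional[CurrencyRate] = None,
) -> pd.DataFrame:
    """Emit the breakdown table, optionally writing CSV and JSON twins."""
    frame = breakdown_frame(breakdown, options, rate)
    if csv_path is not None:
        frame.to_csv(csv_path, index_label="component")
    if json_path is not None:
        payload = {
            "scenario": breakdown.scenario_name,
            "currency": options.currency,
            "table": frame.to_dict(orient="index"),
            "component_shares": {
                c: breakdown.component_shares[c] for c in COMPONENTS
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
    return frame


def read_breakdown_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read back an emitted breakdown CSV (round-trip counterpart)."""
    return pd.read_csv(path, index_col="component")


def tornado_frame(
    results: Sequence, options: ReportOptions = ReportOptions()
) -> pd.DataFrame:
    """One row per scanned parameter with totals and percent impacts."""
    if not results:
        raise ValueError("no tornado results to emit")
    rows = []
    for r in results:
        rows.append(
            {
                "parameter": r.parameter,
                "baseline_total": round(r.baseline_total, options.decimals),
                "low_total": round(r.low_total, options.decimals),
                "high_total": round(r.high_total, options.decimals),
                "low_impact_pct": round(r.low_impact_pct, options.decimals),
                "high_impact_pct": round(r.high_impact_pct, options.decimals),
                "low_impact_pct_int": int(round_half_away(r.low_impact_pct)),
                "high_impact_pct_int": int(round_half_away(r.high_impact_pct)),
            }
        )
    return pd.DataFrame(rows)


def emit_tornado(
    results: Sequence,
    options: ReportOptions = ReportOptions(),
    csv_path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Emit the tornado table, optionally writing it to CSV."""
    frame = tornado_frame(results, options)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    return frame
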