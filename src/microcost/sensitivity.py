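"""One-way (tornado) deterministic sensitivity analysis and yield metrics.

Each scan multiplies one component's total by a low and a high factor
while every other component — including overhead — stays at its baseline
value; holding overhead fixed isolates the component's own contribution.
The overhead rate itself is scanned separately as an absolute range
applied to the unchanged direct costs. Results are ranked by impact
magnitude, ready for a tornado diagram.

``cost_per_positive_diagnosis`` divides the per-exam cost by the
diagnostic yield, the standard cost-per-diagnosis metric for genomic
testing programmes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, List, Sequence, Tuple

from .engine import COMPONENTS, CostBreakdown

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario
    from .resources import ResourceCatalog

_DIRECT_COMPONENTS = ("consumables", "staff", "equipment")


@dataclass(frozen=True)
class SensitivityRange:
    """Low/high multiplicative factors for one component.

    For ``parameter == "overhead_rate"`` the bounds are absolute rates,
    not factors.
    """

    parameter: str
    low_factor: float
    high_factor: float

    def __post_init__(self) -> None:
        if self.parameter not in _DIRECT_COMPONENTS + ("overhead_rate",):
            raise ValueError(f"unknown sensitivity parameter {self.parameter!r}")
        if self.low_factor > self.high_factor:
            raise ValueError("low factor must not exceed high factor")


#: Base-case scan ranges: consumables and staff +/-30%, equipment -20%/+100%,
#: overhead rate swept over the conventional 20-30% band.
DEFAULT_RANGES: Tuple[SensitivityRange, ...] = (
    SensitivityRange("consumables", 0.7, 1.3),
    SensitivityRange("staff", 0.7, 1.3),
    SensitivityRange("equipment", 0.8, 2.0),
)


@dataclass(frozen=True)
class TornadoResult:
    """Recomputed totals and percent impacts for one scanned parameter."""

    parameter: str
    baseline_total: float
    low_total: float
    high_total: float
    low_impact_pct: float
    high_impact_pct: float

    @property
    def impact_magnitude(self) -> float:
        return max(abs(self.low_impact_pct), abs(self.high_impact_pct))


def _scaled_total(breakdown: CostBreakdown, parameter: str, factor: float) -> float:
    baseline = breakdown.genetic_testing_total
    return baseline + breakdown.component_totals[parameter] * (factor - 1.0)


def tornado(
    breakdown: CostBreakdown,
    ranges: Sequence[SensitivityRange] = DEFAULT_RANGES,
    baseline_overhead_rate: float = 0.10,
) -> List[TornadoResult]:
    """Scan each parameter one at a time; sort descending by impact."""
    results: List[TornadoResult] = []
    baseline = breakdown.genetic_testing_total
    if baseline <= 0:
        raise ValueError("breakdown has no genetic-testing cost to scan")
    for rng in ranges:
        if rng.parameter == "overhead_rate":
            low, high = overhead_range(breakdown, rng.low_factor, rng.high_factor)
        else:
            low = _scaled_total(breakdown, rng.parameter, rng.low_factor)
            high = _scaled_total(breakdown, rng.parameter, rng.high_factor)
        results.append(
            TornadoResult(
                parameter=rng.parameter,
                baseline_total=baseline,
                low_total=low,
                high_total=high,
                low_impact_pct=(low - baseline) / baseline * 100.0,
                high_impact_pct=(high - baseline) / baseline * 100.0,
            )
        )
    results.sort(key=lambda r: abs(r.high_impact_pct), reverse=True)
    return results


def overhead_range(
    breakdown: CostBreakdown, rate_low: float, rate_high: float
) -> Tuple[float, float]:
    """Genetic-testing totals with the overhead rate swept over a band.

    Every microcosted step's overhead is recomputed at the new rate on
    unchanged direct costs, so the total collapses to
    ``direct_total x (1 + rate)``.
    """
    for rate in (rate_low, rate_high):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("overhead rates must lie in [0, 1]")
    direct = breakdown.direct_total
    return direct * (1.0 + rate_low), direct * (1.0 + rate_high)


def cost_per_positive_diagnosis(cost_per_exam: float, diagnostic_yield: float) -> float:
    """Per-diagnosis cost: per-exam cost over the fraction of conclusive exams."""
    if not 0.0 < diagnostic_yield <= 1.0:
        raise ValueError("diagnostic yield must lie in (0, 1]")
    return cost_per_exam / diagnostic_yield


def tornado_top_consumables(
    catalog: "ResourceCatalog",
    scenario: "Scenario",
    top_k: int,
    low_factor: float = 0.7,
    high_factor: float = 1.3,
) -> TornadoResult:
    """Item-subset scan: scale only the ``top_k`` costliest consumables.

    Published scans sometimes vary only the most expensive reagents rather
    than the whole consumable component; this recomputes the scenario with
    the batch prices of the top-k items (ranked by their baseline per-exam
    contribution) multiplied by each factor.
    """
    from .scenarios import run_scenario  # local import to avoid a cycle

    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n = scenario.horizon_samples()
    demand_n = n

    def per_exam_cost(item) -> float:
        import math

        batches = math.ceil(round(demand_n * item.units_per_exam / item.batch_size, 9))
        return batches * item.batch_price / demand_n

    ranked = sorted(catalog.consumables, key=per_exam_cost, reverse=True)
    chosen = {id(it) for it in ranked[:top_k]}

    def rescaled(factor: float) -> float:
        clone = catalog.model_copy(deep=True)
        for orig, item in zip(catalog.consumables, clone.consumables):
            if id(orig) in chosen:
                item.batch_price = orig.batch_price * factor
        return run_scenario(clone, scenario).breakdown.genetic_testing_total

    baseline = run_scenario(catalog, scenario).breakdown.genetic_testing_total
    low = rescaled(low_factor)
    high = rescaled(high_factor)
    return TornadoResult(
        parameter=f"consumables_top{top_k}",
        baseline_total=baseline,
        low_total=low,
        high_total=high,
        low_impact_pct=(low - baseline) / baseline * 100.0,
        high_impact_pct=(high - baseline) / baseline * 100.0,
    )
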