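"""Named scenario definitions and the horizon budget view.

A scenario bundles the demand basis, the equipment-utilisation rule and
the overhead rate. Two utilisation rules exist:

* ``shared`` — equipment serves many diseases; the per-exam denominator
  is each machine's own annual throughput times the horizon. This is the
  reference/alternative framing of a multi-disease sequencing hub.
* ``dedicated`` — equipment serves only this pathway's demand; the
  denominator is the pathway's horizon sample count. This is the
  worst-case, very-low-utilisation framing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

from . import demand as _demand
from . import engine as _engine
from .demand import DemandParams, SequencerSpec
from .logistics import TransportParams, TransportRoute
from .resources import PATHWAY_STEPS, ResourceCatalog
from .report import round_half_away


class Scenario(BaseModel):
    """One named model run: demand, utilisation basis and overhead rate."""

    name: str
    demand: Optional[DemandParams] = None
    fixed_horizon_samples: Optional[int] = Field(default=None, ge=1)
    utilization: Literal["dedicated", "shared"] = "shared"
    sequencer: Optional[SequencerSpec] = None
    overhead_rate: Optional[float] = Field(default=None, ge=0, le=1)
    horizon_years: int = Field(default=5, ge=1)
    routes: Optional[List[TransportRoute]] = None
    transport: Optional[TransportParams] = None

    @model_validator(mode="after")
    def _consistent(self) -> "Scenario":
        if self.demand is None and self.fixed_horizon_samples is None:
            raise ValueError("scenario needs demand parameters or a fixed sample count")
        if self.routes and self.transport is None:
            raise ValueError("transport routes given without transport parameters")
        return self

    def horizon_samples(self) -> int:
        """Exams over the whole horizon (the demand denominator)."""
        if self.fixed_horizon_samples is not None:
            return self.fixed_horizon_samples
        n = _demand.total_horizon_samples(self.demand)
        if n < 1:
            raise ValueError(f"scenario {self.name!r} has zero horizon demand")
        return n

    def annual_sample_schedule(self) -> Tuple[int, ...]:
        """Samples per model year."""
        if self.demand is not None:
            return tuple(
                _demand.annual_samples(self.demand, y)
                for y in range(1, self.horizon_years + 1)
            )
        # fixed sample count: spread evenly, remainder in year one
        base, extra = divmod(self.fixed_horizon_samples, self.horizon_years)
        return tuple(
            base + (extra if y == 0 else 0) for y in range(self.horizon_years)
        )


@dataclass(frozen=True)
class ScenarioResult:
    """Per-exam breakdown plus the budget view over the horizon."""

    scenario: Scenario
    breakdown: _engine.CostBreakdown
    per_year_budget: Tuple[float, ...]
    horizon_budget: float


@dataclass(frozen=True)
class ScenarioComparison:
    """Relative cost difference between two scenario runs."""

    baseline_total: float
    comparator_total: float
    relative_diff: float
    percent: int


def run_scenario(catalog: ResourceCatalog, scenario: Scenario) -> ScenarioResult:
    """Cost every pathway step under a scenario and build the budget view."""
    per_step = [
        _engine.step_cost(catalog, scenario, step_id) for step_id in PATHWAY_STEPS
    ]
    breakdown = _engine.aggregate(per_step, scenario_name=scenario.name)
    schedule = scenario.annual_sample_schedule()
    per_year = tuple(breakdown.grand_total * n for n in schedule)
    return ScenarioResult(
        scenario=scenario,
        breakdown=breakdown,
        per_year_budget=per_year,
        horizon_budget=sum(per_year),
    )


def compare(a: ScenarioResult, b: ScenarioResult) -> ScenarioComparison:
    """Relative saving of scenario ``b`` against baseline ``a``.

    Reported as (a - b) / a, rounded half-away-from-zero to an integer
    percent for the headline figure.
    """
    base = a.breakdown.genetic_testing_total
    comp = b.breakdown.genetic_testing_total
    if base == 0:
        raise ValueError("baseline scenario has zero genetic-testing cost")
    rel = (base - comp) / base
    return ScenarioComparison(
        baseline_total=base,
        comparator_total=comp,
        relative_diff=rel,
        percent=int(round_half_away(rel * 100.0)),
    )
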