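"""Bottom-up costing engine: per-exam step costs and the breakdown matrix.

Each microcosted step's per-exam cost is the sum of three direct
components — consumables (batch-constrained purchasing amortised over
horizon demand), staff (hands-on minutes times the hourly rate) and
equipment (horizon acquisition + maintenance cost, allocated pro rata by
usage share and divided by the utilisation denominator) — plus an
overhead markup applied to the direct cost of each step. Reimbursed
clinical steps carry only their bundled tariff, with no component split
and no overhead. The confirmatory Sanger step is probability-weighted by
the fraction of patients that need it.

The central output is a :class:`CostBreakdown`: the step x component
matrix with genetic-testing, clinical and grand totals plus component
shares of the genetic-testing cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterable, List, Mapping, Sequence, Tuple

from . import demand as _demand
from . import logistics as _logistics
from .resources import (
    MICROCOSTED_STEPS,
    PATHWAY_STEPS,
    REIMBURSED_STEPS,
    SANGER_STEP,
    ConsumableItem,
    EquipmentItem,
    ResourceCatalog,
    StaffRole,
    hourly_rate,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

#: Direct components plus overhead, in reporting order.
COMPONENTS: Tuple[str, ...] = ("consumables", "staff", "equipment", "overhead")


# ---------------------------------------------------------------------------
# Output containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepCost:
    """Per-exam cost of one pathway step, split by component."""

    step_id: str
    consumables: float = 0.0
    staff: float = 0.0
    equipment: float = 0.0
    overhead: float = 0.0
    reimbursement: float = 0.0

    @property
    def direct(self) -> float:
        """Direct microcosted cost: consumables + staff + equipment."""
        return self.consumables + self.staff + self.equipment

    @property
    def total(self) -> float:
        return self.direct + self.overhead + self.reimbursement


@dataclass(frozen=True)
class CostBreakdown:
    """Step x component matrix with totals and component shares."""

    scenario_name: str
    per_step: Tuple[StepCost, ...]
    genetic_testing_total: float
    clinical_total: float
    grand_total: float
    component_totals: Dict[str, float]
    component_shares: Dict[str, float]

    def step(self, step_id: str) -> StepCost:
        for sc in self.per_step:
            if sc.step_id == step_id:
                return sc
        raise KeyError(step_id)

    @property
    def direct_total(self) -> float:
        """Genetic-testing direct cost (total net of overhead)."""
        return self.genetic_testing_total - self.component_totals["overhead"]


# ---------------------------------------------------------------------------
# Component costing primitives
# ---------------------------------------------------------------------------


def consumable_cost_per_exam(
    items: Iterable[ConsumableItem], horizon_demand: int
) -> float:
    """Per-exam consumable cost under minimal-batch purchasing.

    For each item the number of batches bought is the ceiling of total
    horizon consumption over the batch size; one extra exam past a batch
    boundary forces a whole extra batch. The purchase bill is then spread
    over all exams in the horizon.
    """
    if horizon_demand < 1:
        raise ValueError("horizon demand must be >= 1 exam")
    total = 0.0
    for item in items:
        needed = horizon_demand * item.units_per_exam
        if needed == 0:
            continue
        batches = math.ceil(round(needed / item.batch_size, 9))
        total += batches * item.batch_price
    return total / horizon_demand


def equipment_horizon_cost(item: EquipmentItem, horizon_years: int) -> float:
    """Acquisition in year one plus maintenance in every horizon year.

    No depreciation schedule is applied; the full acquisition cost sits
    inside the horizon.
    """
    if horizon_years < 1:
        raise ValueError("horizon must be >= 1 year")
    return item.acquisition_cost * (1.0 + horizon_years * item.maintenance_rate)


def equipment_cost_per_exam(
    item: EquipmentItem,
    step_id: str,
    horizon_exams_through_equipment: float,
    horizon_years: int,
) -> float:
    """Pro-rata share of one machine's horizon cost, per exam.

    The denominator is the scenario's utilisation basis: every exam the
    machine processes over the horizon (multi-disease throughput under
    shared use, cataract-only demand under dedicated use).
    """
    share = item.step_shares.get(step_id, 0.0)
    if share == 0.0:
        return 0.0
    if horizon_exams_through_equipment < 1:
        raise ValueError("equipment utilisation basis must be >= 1 exam")
    return (
        equipment_horizon_cost(item, horizon_years)
        * share
        / horizon_exams_through_equipment
    )


def staff_cost_per_exam(role: StaffRole, step_id: str) -> float:
    """Hands-on time cost of one role for one exam of one step."""
    minutes = role.hands_on_minutes_per_exam.get(step_id, 0.0)
    if minutes == 0.0:
        return 0.0
    return hourly_rate(role) * minutes / 60.0


def apply_probability_weight(cost: float, fraction: float) -> float:
    """Expected per-patient cost of a step performed for a fraction of patients."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return cost * fraction


def overhead_for_step(direct_cost: float, overhead_rate: float) -> float:
    """Indirect-cost markup on one step's direct cost."""
    if direct_cost < 0:
        raise ValueError("direct cost must be >= 0")
    return overhead_rate * direct_cost


# ---------------------------------------------------------------------------
# Step costing and aggregation
# ---------------------------------------------------------------------------


def _utilization_exams(
    item: EquipmentItem, scenario: "Scenario", horizon_demand: int
) -> float:
    if scenario.utilization == "shared":
        return item.annual_throughput * scenario.horizon_years
    return float(horizon_demand)


def step_cost(catalog: ResourceCatalog, scenario: "Scenario", step_id: str) -> StepCost:
    """Cost one pathway step per exam under a scenario's assumptions."""
    if step_id not in PATHWAY_STEPS:
        raise ValueError(f"unknown pathway step {step_id!r}")

    if step_id in REIMBURSED_STEPS:
        price = sum(
            r.unit_price for r in catalog.reimbursements if r.step_id == step_id
        )
        return StepCost(step_id=step_id, reimbursement=price)

    horizon_demand = scenario.horizon_samples()
    cons = consumable_cost_per_exam(
        [i for i in catalog.consumables if i.step_id == step_id], horizon_demand
    )
    staff = sum(staff_cost_per_exam(r, step_id) for r in catalog.staff)
    equip = sum(
        equipment_cost_per_exam(
            item, step_id, _utilization_exams(item, scenario, horizon_demand),
            scenario.horizon_years,
        )
        for item in catalog.equipment
    )

    if step_id == "operation" and scenario.routes:
        fuel, driver = _logistics.annual_cost_components(
            scenario.routes, scenario.transport
        )
        # horizon transport bill spread over every exam of the horizon
        cons += fuel * scenario.horizon_years / horizon_demand
        staff += driver * scenario.horizon_years / horizon_demand

    if step_id == SANGER_STEP:
        f = catalog.constants.sanger_fraction
        cons = apply_probability_weight(cons, f)
        staff = apply_probability_weight(staff, f)
        equip = apply_probability_weight(equip, f)

    rate = (
        scenario.overhead_rate
        if scenario.overhead_rate is not None
        else catalog.constants.overhead_rate
    )
    direct = cons + staff + equip
    return StepCost(
        step_id=step_id,
        consumables=cons,
        staff=staff,
        equipment=equip,
        overhead=overhead_for_step(direct, rate),
    )


def aggregate(per_step: Sequence[StepCost], scenario_name: str = "") -> CostBreakdown:
    """Fold per-step costs into the breakdown matrix with totals and shares.

    Component shares are fractions of the genetic-testing total only; the
    bundled clinical tariffs are excluded from the share denominator.
    """
    seen = set()
    for sc in per_step:
        if sc.step_id in seen:
            raise ValueError(f"duplicate step id {sc.step_id!r}")
        seen.add(sc.step_id)

    genetic = [sc for sc in per_step if sc.step_id in MICROCOSTED_STEPS]
    clinical = [sc for sc in per_step if sc.step_id in REIMBURSED_STEPS]

    genetic_total = sum(sc.total for sc in genetic)
    clinical_total = sum(sc.total for sc in clinical)
    component_totals = {
        comp: sum(getattr(sc, comp) for sc in genetic) for comp in COMPONENTS
    }
    if genetic_total > 0:
        shares = {c: v / genetic_total for c, v in component_totals.items()}
    else:
        shares = {c: 0.0 for c in COMPONENTS}

    return CostBreakdown(
        scenario_name=scenario_name,
        per_step=tuple(per_step),
        genetic_testing_total=genetic_total,
        clinical_total=clinical_total,
        grand_total=genetic_total + clinical_total,
        component_totals=component_totals,
        component_shares=shares,
    )


def component_mode_ingest(
    component_table: Mapping[str, Mapping[str, float]],
    overhead_rate: float = 0.10,
) -> List[StepCost]:
    """Build step costs from pre-costed component values.

    ``component_table`` maps step id to either ``{"consumables": ...,
    "staff": ..., "equipment": ...}`` for microcosted steps or
    ``{"reimbursement": ...}`` for tariff steps. Overhead is always
    recomputed from the direct components at ``overhead_rate``, never read
    from the table, so the aggregation and markup layers are exercised
    even when raw resource lists are unavailable.
    """
    out: List[StepCost] = []
    for step_id, row in component_table.items():
        if step_id not in PATHWAY_STEPS:
            raise ValueError(f"unknown pathway step {step_id!r}")
        if step_id in REIMBURSED_STEPS:
            if "reimbursement" not in row:
                raise ValueError(f"step {step_id}: missing reimbursement value")
            out.append(
                StepCost(step_id=step_id, reimbursement=float(row["reimbursement"]))
            )
            continue
        missing = [c for c in ("consumables", "staff", "equipment") if c not in row]
        if missing:
            raise ValueError(f"step {step_id}: missing component(s) {missing}")
        cons = float(row["consumables"])
        staff = float(row["staff"])
        equip = float(row["equipment"])
        out.append(
            StepCost(
                step_id=step_id,
                consumables=cons,
                staff=staff,
                equipment=equip,
                overhead=overhead_for_step(cons + staff + equip, overhead_rate),
            )
        )
    return out
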