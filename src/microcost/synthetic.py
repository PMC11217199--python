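"""Synthetic catalogs and the published component-cost fixture.

The real supplementary price lists behind the cost model (per-step
reagent lists with batch constraints, job-class wages, equipment quotes)
are not published. Two stand-ins make every stage of the engine testable:

* :func:`generate_catalog` draws a structurally realistic random catalog
  — batch-constrained consumables over steps 2-7 and operation, staff
  roles with hands-on minutes, equipment with pro-rata step shares
  summing to one, tariffed clinical steps and a hospital transport
  network — deterministically from a seed.
* :func:`published_components` returns the published per-step component costs
  (consumables/staff/equipment in USD, plus the two clinical tariffs);
  overhead and totals are deliberately absent so the engine must
  recompute them.
* :func:`calibrated_catalog` inverts the engine: it builds a raw-resource
  catalog whose bottom-up costing reproduces a given component table,
  demonstrating that the full purchasing/wage/equipment path can realise
  the published figures.
"""

from __future__ import annotations

from importlib import resources as _ilres
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .demand import DemandParams
from .logistics import TransportParams, TransportRoute
from .resources import (
    MICROCOSTED_STEPS,
    REIMBURSED_STEPS,
    SANGER_STEP,
    ConsumableItem,
    EquipmentItem,
    ModelConstants,
    ReimbursementItem,
    ResourceCatalog,
    StaffRole,
)
from .scenarios import Scenario

_FIXTURE_SCENARIOS = ("reference", "alternative")

# annual full-time hours under the default employment assumptions
_ANNUAL_HOURS = 40.0 * 52.0
_DEFAULT_MULTIPLIER = 14.3


class GeneratorConfig(BaseModel):
    """Knobs for the random catalog generator (deterministic under seed)."""

    seed: int = 0
    n_consumables_per_step: Tuple[int, int] = (2, 6)
    batch_size_range: Tuple[int, int] = (1, 50)
    price_scale: float = Field(default=100.0, gt=0)
    n_staff_roles: int = Field(default=4, ge=0)
    wage_range: Tuple[float, float] = (2000.0, 12000.0)
    n_equipment: int = Field(default=6, ge=0)
    acquisition_range: Tuple[float, float] = (5_000.0, 900_000.0)
    n_hospitals: int = Field(default=12, ge=0)
    distance_range_km: Tuple[float, float] = (10.0, 120.0)
    tier_mix: Tuple[float, float, float] = (0.4, 0.4, 0.2)


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if hi < lo:
        raise ValueError("empty range")
    return float(rng.uniform(lo, hi))


def generate_catalog(config: GeneratorConfig) -> ResourceCatalog:
    """Draw a validating random catalog; identical for identical seeds."""
    rng = np.random.default_rng(config.seed)
    lo_n, hi_n = config.n_consumables_per_step
    if hi_n < lo_n:
        raise ValueError("empty consumable-count range")

    consumables: List[ConsumableItem] = []
    for step in MICROCOSTED_STEPS:
        for k in range(int(rng.integers(lo_n, hi_n + 1))):
            consumables.append(
                ConsumableItem(
                    name=f"consumable_{step}_{k}",
                    step_id=step,
                    units_per_exam=round(_uniform(rng, 0.1, 3.0), 3),
                    batch_size=int(
                        rng.integers(config.batch_size_range[0], config.batch_size_range[1] + 1)
                    ),
                    batch_price=round(_uniform(rng, 0.05, 1.0) * config.price_scale, 2),
                )
            )

    staff: List[StaffRole] = []
    for k in range(config.n_staff_roles):
        n_steps = int(rng.integers(1, len(MICROCOSTED_STEPS) + 1))
        chosen = rng.choice(len(MICROCOSTED_STEPS), size=n_steps, replace=False)
        minutes = {
            MICROCOSTED_STEPS[i]: round(_uniform(rng, 5.0, 120.0), 1) for i in chosen
        }
        staff.append(
            StaffRole(
                name=f"role_{k}",
                monthly_wage=round(_uniform(rng, *config.wage_range), 2),
                hands_on_minutes_per_exam=minutes,
            )
        )

    equipment: List[EquipmentItem] = []
    for k in range(config.n_equipment):
        n_steps = int(rng.integers(1, 5))
        chosen = rng.choice(len(MICROCOSTED_STEPS), size=n_steps, replace=False)
        raw = rng.dirichlet(np.ones(n_steps))
        raw = raw / raw.sum()  # exact renormalisation against float drift
        shares = {
            MICROCOSTED_STEPS[i]: float(w) for i, w in zip(chosen, raw)
        }
        # push any residual onto the largest share so the sum is exactly 1
        residual = 1.0 - sum(shares.values())
        top = max(shares, key=shares.get)
        shares[top] += residual
        equipment.append(
            EquipmentItem(
                name=f"equipment_{k}",
                acquisition_cost=round(_uniform(rng, *config.acquisition_range), 2),
                maintenance_rate=0.05,
                step_shares=shares,
                annual_throughput=float(rng.integers(1_000, 70_000)),
            )
        )

    reimbursements = [
        ReimbursementItem(
            name=f"tariff_step_{step}",
            step_id=step,
            unit_price=round(_uniform(rng, 50.0, 150.0), 2),
        )
        for step in REIMBURSED_STEPS
    ]

    return ResourceCatalog(
        consumables=consumables,
        equipment=equipment,
        staff=staff,
        reimbursements=reimbursements,
    )


def generate_network(
    config: GeneratorConfig,
) -> Tuple[List[TransportRoute], TransportParams]:
    """Random hospital-to-hub transport network (deterministic under seed)."""
    rng = np.random.default_rng(config.seed + 1)
    tiers = ("low", "moderate", "high")
    mix = np.asarray(config.tier_mix, dtype=float)
    mix = mix / mix.sum()
    routes = [
        TransportRoute(
            origin=f"hospital_{k}",
            destination="hub_A",
            round_trip_km=round(_uniform(rng, *config.distance_range_km), 1),
            activity_tier=tiers[int(rng.choice(3, p=mix))],
        )
        for k in range(config.n_hospitals)
    ]
    params = TransportParams(
        fuel_price_per_liter=round(_uniform(rng, 0.8, 1.5), 2),
        driver=StaffRole(
            name="driver",
            monthly_wage=round(_uniform(rng, 1500.0, 4000.0), 2),
        ),
    )
    return routes, params


# ---------------------------------------------------------------------------
# Published component fixture
# ---------------------------------------------------------------------------


def _fixture_frame() -> pd.DataFrame:
    with _ilres.files("microcost.data").joinpath("published_components.csv").open() as fh:
        return pd.read_csv(fh, dtype={"step_id": str})


def published_components(scenario_name: str) -> Dict[str, Dict[str, float]]:
    """Published per-step component costs (USD) for one scenario.

    Returns a mapping of step id to either the three direct components
    (microcosted steps) or the bundled tariff (clinical steps). Overhead
    and totals are not included; the engine recomputes them.
    """
    if scenario_name not in _FIXTURE_SCENARIOS:
        raise ValueError(
            f"unknown fixture scenario {scenario_name!r}; expected one of {_FIXTURE_SCENARIOS}"
        )
    frame = _fixture_frame()
    frame = frame[frame["scenario"] == scenario_name]
    table: Dict[str, Dict[str, float]] = {}
    for _, row in frame.iterrows():
        if row["mode"] == "reimbursement":
            table[row["step_id"]] = {"reimbursement": float(row["reimbursement"])}
        else:
            table[row["step_id"]] = {
                "consumables": float(row["consumables"]),
                "staff": float(row["staff"]),
                "equipment": float(row["equipment"]),
            }
    return table


# ---------------------------------------------------------------------------
# Calibration: component table -> raw-resource catalog
# ---------------------------------------------------------------------------


def calibration_scenario(
    demand: int,
    horizon_years: int = 5,
    overhead_rate: Optional[float] = None,
    name: str = "calibration",
) -> Scenario:
    """Scenario matching :func:`calibrated_catalog`'s assumptions.

    Dedicated utilisation with a fixed horizon sample count, so the
    equipment denominator equals ``demand`` exactly.
    """
    return Scenario(
        name=name,
        fixed_horizon_samples=demand,
        utilization="dedicated",
        overhead_rate=overhead_rate,
        horizon_years=horizon_years,
    )


def calibrated_catalog(
    target: Mapping[str, Mapping[str, float]],
    demand: int,
    horizon_years: int = 5,
    constants: Optional[ModelConstants] = None,
) -> ResourceCatalog:
    """Raw-resource catalog whose engine output reproduces ``target``.

    One consumable (unit batches, so no ceiling slack), one staff role and
    one equipment item are synthesised per microcosted step; clinical
    steps become tariff items. The confirmatory-sequencing step's
    resources are inflated by 1/sanger_fraction so the engine's
    probability weighting lands back on the target. Evaluate with
    :func:`calibration_scenario` at the same ``demand``.
    """
    if demand < 1:
        raise ValueError("demand must be >= 1")
    constants = constants or ModelConstants(horizon_years=horizon_years)
    consumables: List[ConsumableItem] = []
    staff: List[StaffRole] = []
    equipment: List[EquipmentItem] = []
    reimbursements: List[ReimbursementItem] = []

    for step_id, row in target.items():
        if step_id in REIMBURSED_STEPS or "reimbursement" in row:
            reimbursements.append(
                ReimbursementItem(
                    name=f"tariff_{step_id}",
                    step_id=step_id,
                    unit_price=float(row["reimbursement"]),
                )
            )
            continue
        scale = 1.0
        if step_id == SANGER_STEP:
            if constants.sanger_fraction == 0:
                raise ValueError(
                    "cannot calibrate the confirmatory step with a zero fraction"
                )
            scale = 1.0 / constants.sanger_fraction
        cons = float(row["consumables"]) * scale
        st = float(row["staff"]) * scale
        eq = float(row["equipment"]) * scale
        if min(cons, st, eq) < 0:
            raise ValueError(f"step {step_id}: negative component target")
        if cons > 0:
            consumables.append(
                ConsumableItem(
                    name=f"cal_consumable_{step_id}",
                    step_id=step_id,
                    units_per_exam=1.0,
                    batch_size=1,
                    batch_price=cons,
                )
            )
        if st > 0:
            # one hour hands-on at an hourly rate equal to the target cost
            staff.append(
                StaffRole(
                    name=f"cal_role_{step_id}",
                    monthly_wage=st * _ANNUAL_HOURS / _DEFAULT_MULTIPLIER,
                    hands_on_minutes_per_exam={step_id: 60.0},
                )
            )
        if eq > 0:
            # dedicated utilisation: horizon cost / demand = target
            equipment.append(
                EquipmentItem(
                    name=f"cal_equipment_{step_id}",
                    acquisition_cost=eq * demand,
                    maintenance_rate=0.0,
                    step_shares={step_id: 1.0},
                    annual_throughput=max(demand / horizon_years, 1.0),
                )
            )

    return ResourceCatalog(
        consumables=consumables,
        equipment=equipment,
        staff=staff,
        reimbursements=reimbursements,
        constants=constants,
    )
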