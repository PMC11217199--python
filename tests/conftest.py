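import math

import pytest
from hypothesis import HealthCheck, settings

import microcost as mc

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_breakdown() -> mc.CostBreakdown:
    table = mc.published_components("reference")
    return mc.aggregate(mc.component_mode_ingest(table), "reference")


@pytest.fixture(scope="session")
def alternative_breakdown() -> mc.CostBreakdown:
    table = mc.published_components("alternative")
    return mc.aggregate(mc.component_mode_ingest(table), "alternative")


@pytest.fixture()
def small_catalog() -> mc.ResourceCatalog:
    """Hand-built catalog with one resource of each kind, easy to check by hand."""
    return mc.ResourceCatalog(
        consumables=[
            mc.ConsumableItem(
                name="kit", step_id="4", units_per_exam=1.0, batch_size=30, batch_price=300.0
            )
        ],
        equipment=[
            mc.EquipmentItem(
                name="sequencer",
                acquisition_cost=100.0,
                maintenance_rate=0.05,
                step_shares={"5": 1.0},
                annual_throughput=25.0,
            )
        ],
        staff=[
            mc.StaffRole(
                name="tech",
                monthly_wage=1000.0,
                hands_on_minutes_per_exam={"2": 60.0},
            )
        ],
        reimbursements=[
            mc.ReimbursementItem(name="pretest", step_id="1", unit_price=104.53),
            mc.ReimbursementItem(name="posttest", step_id="8", unit_price=67.72),
        ],
    )


def brute_force_consumable_cost(items, demand: int) -> float:
    """Independent purchase simulator: buy batches one at a time until the
    horizon's unit consumption is covered, then spread the bill per exam."""
    total = 0.0
    for item in items:
        needed = demand * item.units_per_exam
        bought = 0.0
        batches = 0
        while bought < needed - 1e-9:
            batches += 1
            bought += item.batch_size
        total += batches * item.batch_price
    return total / demand
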