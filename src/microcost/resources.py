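"""Domain types and unit-cost primitives for priced resources.

The costing model distinguishes four kinds of priced input:

* **consumables** — disposable reagents and plasticware sold only in
  minimal batches, so purchasing is a ceiling function of demand;
* **equipment** — capital items shared across pathway steps, allocated
  pro rata by usage share, with annual maintenance as a fraction of the
  acquisition cost;
* **staff** — salaried roles whose hands-on time per exam is metered in
  minutes per pathway step, annualised under Brazilian labour rules
  (monthly wage x 14.3);
* **reimbursement items** — clinical procedures priced from the public
  payer's (SUS) fee schedule, whose tariff already bundles consumables,
  staff and equipment.

All monetary amounts are carried at full floating precision; rounding to
cents happens only in the reporting layer.
"""

from __future__ import annotations

from typing import Dict, List, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# Pathway definition
# ---------------------------------------------------------------------------

#: Ordered pathway: eight numbered diagnostic steps plus a distinguished
#: "operation" pseudo-step carrying administration and sample logistics.
PATHWAY_STEPS: Dict[str, str] = {
    "1": "Pretest Evaluation",
    "2": "Peripheral Blood Collection",
    "3": "DNA Extraction",
    "4": "Library",
    "5": "NGS",
    "6": "Analysis",
    "7": "Sanger Sequencing",
    "8": "Posttest Evaluation",
    "operation": "Operation",
}

#: Steps priced from the public reimbursement table (bundled tariff).
REIMBURSED_STEPS: tuple = ("1", "8")

#: Steps costed bottom-up from itemised resources.
MICROCOSTED_STEPS: tuple = ("2", "3", "4", "5", "6", "7", "operation")

#: The confirmatory sequencing step, performed only for a fraction of
#: patients; its expected per-patient cost is probability-weighted.
SANGER_STEP = "7"

_SHARE_TOL = 1e-9


def _check_step(step_id: str) -> str:
    if step_id not in PATHWAY_STEPS:
        raise ValueError(f"unknown pathway step {step_id!r}")
    return step_id


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


class CurrencyRate(BaseModel):
    """Fixed BRL/USD exchange rate used for display conversion."""

    brl_per_usd: float = Field(default=5.1686, gt=0)


class ConsumableItem(BaseModel):
    """A disposable item purchasable only in batches of ``batch_size`` units."""

    name: str
    step_id: str
    units_per_exam: float = Field(ge=0)
    batch_size: int = Field(ge=1)
    batch_price: float = Field(ge=0)

    @field_validator("step_id")
    @classmethod
    def _step(cls, v: str) -> str:
        return _check_step(v)


class EquipmentItem(BaseModel):
    """A capital item whose horizon cost is split pro rata across steps.

    ``step_shares`` maps step id -> fraction of this machine's use; shares
    must sum to 1 over the steps that use it. ``annual_throughput`` is the
    number of exams the unit can process per year at full utilisation and
    is the cost denominator under shared (multi-disease) use.
    """

    name: str
    acquisition_cost: float = Field(ge=0)
    maintenance_rate: float = Field(default=0.05, ge=0, le=1)
    step_shares: Dict[str, float]
    annual_throughput: float = Field(gt=0)

    @field_validator("step_shares")
    @classmethod
    def _shares(cls, v: Dict[str, float]) -> Dict[str, float]:
        if not v:
            raise ValueError("equipment must be used by at least one step")
        for step, share in v.items():
            _check_step(step)
            if step not in MICROCOSTED_STEPS:
                raise ValueError(
                    f"equipment shares may only reference microcosted steps, got {step!r}"
                )
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"share for step {step} outside [0, 1]")
        if abs(sum(v.values()) - 1.0) > _SHARE_TOL:
            raise ValueError("equipment step shares must sum to 1")
        return v


class StaffRole(BaseModel):
    """A salaried job class with hands-on minutes per exam per step."""

    name: str
    monthly_wage: float = Field(ge=0)
    annual_multiplier: float = Field(default=14.3, gt=0)
    weekly_hours: float = Field(default=40.0, gt=0)
    weeks_per_year: float = Field(default=52.0, gt=0)
    productive_hours_per_day: float = Field(default=6.0, gt=0)
    workdays_per_month: int = Field(default=22, ge=1)
    hands_on_minutes_per_exam: Dict[str, float] = Field(default_factory=dict)

    @field_validator("hands_on_minutes_per_exam")
    @classmethod
    def _minutes(cls, v: Dict[str, float]) -> Dict[str, float]:
        for step, minutes in v.items():
            _check_step(step)
            if minutes < 0:
                raise ValueError("hands-on minutes must be >= 0")
        return v

    @model_validator(mode="after")
    def _productive_within_workday(self) -> "StaffRole":
        if self.productive_hours_per_day > self.weekly_hours / 5.0 + _SHARE_TOL:
            raise ValueError(
                "productive hours per day cannot exceed the daily workload"
            )
        return self


class ReimbursementItem(BaseModel):
    """A clinical procedure priced by the payer's bundled tariff."""

    name: str
    step_id: str
    unit_price: float = Field(ge=0)

    @field_validator("step_id")
    @classmethod
    def _step(cls, v: str) -> str:
        return _check_step(v)


class ModelConstants(BaseModel):
    """Fixed model-wide assumptions.

    overhead_rate
        Indirect cost (utilities, administration, cleaning, internet) as a
        markup on each microcosted step's direct cost. The base-case 0.10
        reflects an already-existing facility; 0.20-0.30 is the usual range.
    sanger_fraction
        Fraction of patients needing confirmatory Sanger sequencing.
    horizon_years
        Budget horizon over which acquisition, maintenance and recurrent
        costs accumulate (five years per Brazilian budget-impact guidance).
    """

    overhead_rate: float = Field(default=0.10, ge=0, le=1)
    sanger_fraction: float = Field(default=0.5, ge=0, le=1)
    horizon_years: int = Field(default=5, ge=1)


class ResourceCatalog(BaseModel):
    """Every priced resource of the pathway plus the fixed constants."""

    consumables: List[ConsumableItem] = Field(default_factory=list)
    equipment: List[EquipmentItem] = Field(default_factory=list)
    staff: List[StaffRole] = Field(default_factory=list)
    reimbursements: List[ReimbursementItem] = Field(default_factory=list)
    constants: ModelConstants = Field(default_factory=ModelConstants)
    currency: CurrencyRate = Field(default_factory=CurrencyRate)


# ---------------------------------------------------------------------------
# Unit-cost primitives
# ---------------------------------------------------------------------------


def annualize_salary(monthly_wage: float, multiplier: float = 14.3) -> float:
    """Annual salary from a monthly wage.

    The default multiplier 14.3 bundles the statutory 13th salary, the
    vacation bonus (1/3 of a month) and cover for mandatory leave.
    """
    if monthly_wage < 0:
        raise ValueError("monthly wage must be >= 0")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    return monthly_wage * multiplier


def hourly_rate(role: StaffRole) -> float:
    """Cost of one hour of a role's time: annual salary over annual hours."""
    return annualize_salary(role.monthly_wage, role.annual_multiplier) / (
        role.weekly_hours * role.weeks_per_year
    )


def usd(amount_brl: float, rate: Optional[CurrencyRate] = None) -> float:
    """Convert a BRL amount to USD at the model's fixed exchange rate."""
    rate = rate or CurrencyRate()
    return amount_brl / rate.brl_per_usd


def brl(amount_usd: float, rate: Optional[CurrencyRate] = None) -> float:
    """Convert a USD amount to BRL; exact inverse of :func:`usd`."""
    rate = rate or CurrencyRate()
    return amount_usd * rate.brl_per_usd
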