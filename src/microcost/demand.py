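"""Eligible-population projection and sequencing-hub capacity.

Demand is projected from static epidemiological rates: the first model
year captures the prevalent pool of cases (prevalence per 10,000
children), and each subsequent year adds incident cases from an annual
incidence derived from a cumulative incidence over an age interval.
Probands are scaled by the public-system share, rounded up to whole
persons, and multiplied by (1 + family members) because trio analysis
sequences the proband plus two relatives.

Capacity is the closed-form throughput of a high-output sequencer:
samples per flowcell x flowcells per run x workdays per month / run
duration in days.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, Field


def _ceil(x: float) -> int:
    # guard against float noise pushing an exact integer over the ceiling
    return math.ceil(round(x, 9))


class DemandParams(BaseModel):
    """Epidemiological inputs for the eligible-population projection."""

    base_population: int = Field(ge=0, description="children <= 18 y in catchment")
    prevalence_per_10k: float = Field(default=4.0, ge=0)
    cumulative_incidence_per_10k: float = Field(default=3.46, ge=0)
    incidence_interval_years: float = Field(default=15.0, gt=0)
    annual_incidence_per_10k: Optional[float] = Field(
        default=None, ge=0, description="explicit annual rate; overrides the cumulative figure"
    )
    sus_share: float = Field(default=0.76, ge=0, le=1)
    family_members_per_proband: int = Field(default=2, ge=0)
    horizon_years: int = Field(default=5, ge=1)

    @property
    def derived_annual_incidence_per_10k(self) -> float:
        """Annual incidence: explicit override, else cumulative spread uniformly."""
        if self.annual_incidence_per_10k is not None:
            return self.annual_incidence_per_10k
        return self.cumulative_incidence_per_10k / self.incidence_interval_years


class SequencerSpec(BaseModel):
    """Throughput characteristics of the hub's sequencer."""

    samples_per_flowcell: int = Field(default=240, ge=1)
    flowcells_per_run: int = Field(default=2, ge=1)
    workdays_per_month: int = Field(default=22, ge=1)
    run_duration_days: float = Field(default=2.0, ge=1)


def annual_probands(params: DemandParams, year_index: int) -> int:
    """Whole-person probands eligible in one model year.

    Year 1 draws on prevalence (the standing pool of cases); years 2
    onwards draw on annual incidence. The expected count is scaled by the
    public-system share and rounded up before the family multiplier.
    """
    if not 1 <= year_index <= params.horizon_years:
        raise ValueError(
            f"year_index {year_index} outside horizon 1..{params.horizon_years}"
        )
    rate = (
        params.prevalence_per_10k
        if year_index == 1
        else params.derived_annual_incidence_per_10k
    )
    expected = params.base_population * rate / 10_000.0 * params.sus_share
    if expected == 0:
        return 0
    return _ceil(expected)


def annual_samples(params: DemandParams, year_index: int) -> int:
    """Samples to sequence in one year: probands x (1 + family members)."""
    return annual_probands(params, year_index) * (1 + params.family_members_per_proband)


def total_horizon_samples(params: DemandParams) -> int:
    """Samples summed over every year of the horizon."""
    return sum(annual_samples(params, y) for y in range(1, params.horizon_years + 1))


def monthly_capacity(spec: SequencerSpec) -> float:
    """Samples the sequencer can process per month at full utilisation."""
    return (
        spec.samples_per_flowcell
        * spec.flowcells_per_run
        * spec.workdays_per_month
        / spec.run_duration_days
    )


def annual_capacity(spec: SequencerSpec) -> float:
    """Samples per year: twelve months of full-utilisation throughput."""
    return 12.0 * monthly_capacity(spec)
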