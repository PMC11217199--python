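"""Sample-transport costing between referral hospitals and the hubs.

Each route connects a tertiary hospital to a hub; its annual trip count
depends on the site's activity tier (low: quarterly, moderate: monthly,
high: twice a month). A trip costs fuel (round-trip km over the vehicle's
km-per-litre performance, times the fuel price) plus the hired driver's
time (round-trip km over an assumed average urban speed, times the
driver's hourly rate). Vehicle acquisition is excluded: an existing
hospital vehicle is assumed available.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, Field, field_validator

from .resources import StaffRole, hourly_rate

#: Annual trip frequency per activity tier.
DEFAULT_TRIPS_PER_YEAR: Dict[str, int] = {"low": 4, "moderate": 12, "high": 24}


class TransportRoute(BaseModel):
    """One hospital-to-hub connection."""

    origin: str
    destination: str
    round_trip_km: float = Field(ge=0)
    activity_tier: str

    @field_validator("activity_tier")
    @classmethod
    def _tier(cls, v: str) -> str:
        if v not in DEFAULT_TRIPS_PER_YEAR:
            raise ValueError(
                f"unknown activity tier {v!r}; expected one of {sorted(DEFAULT_TRIPS_PER_YEAR)}"
            )
        return v


class TransportParams(BaseModel):
    """Vehicle, fuel and driver parameters shared by all routes."""

    km_per_liter: float = Field(default=8.0, gt=0)
    fuel_price_per_liter: float = Field(ge=0)
    avg_speed_kmh: float = Field(default=30.0, gt=0)
    driver: Optional[StaffRole] = None
    trips_per_year_by_tier: Dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_TRIPS_PER_YEAR)
    )


def _trips(route: TransportRoute, params: TransportParams) -> int:
    try:
        return params.trips_per_year_by_tier[route.activity_tier]
    except KeyError:  # tier missing from a customised mapping
        raise ValueError(f"no trip frequency configured for tier {route.activity_tier!r}")


def annual_km(routes: List[TransportRoute], params: TransportParams) -> float:
    """Total km driven per year over all routes."""
    return sum(_trips(r, params) * r.round_trip_km for r in routes)


def annual_cost_components(
    routes: List[TransportRoute], params: TransportParams
) -> Tuple[float, float]:
    """(fuel, driver-time) annual cost totals over all routes."""
    driver_rate = hourly_rate(params.driver) if params.driver is not None else 0.0
    fuel = 0.0
    driver = 0.0
    for route in routes:
        trips = _trips(route, params)
        fuel += trips * route.round_trip_km / params.km_per_liter * params.fuel_price_per_liter
        driver += trips * route.round_trip_km / params.avg_speed_kmh * driver_rate
    return fuel, driver


def annual_transport_cost(routes: List[TransportRoute], params: TransportParams) -> float:
    """Total yearly transport cost: fuel plus driver time."""
    fuel, driver = annual_cost_components(routes, params)
    return fuel + driver


def transport_cost_per_km(annual_cost: float, annual_km_driven: float) -> float:
    """Operational cost per km driven."""
    if annual_cost == 0:
        return 0.0
    if annual_km_driven <= 0:
        raise ValueError("annual km must be > 0")
    return annual_cost / annual_km_driven
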