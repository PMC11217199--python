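"""Read and write resource catalogs as a directory of tabular files.

Layout::

    catalog/
      consumables.csv    name, step, units_per_exam, batch_size, batch_price
      equipment.csv      name, acquisition_cost, maintenance_rate,
                         annual_throughput, share_2 .. share_7, share_operation
      staff.csv          name, monthly_wage, [employment fields],
                         minutes_2 .. minutes_7, minutes_operation
      reimbursement.csv  name, step, unit_price
      constants.yaml     overhead_rate, sanger_fraction, horizon_years, brl_per_usd
      routes.csv         origin, destination, round_trip_km, tier   (optional)
      transport.yaml     km_per_liter, fuel_price_per_liter, ...    (optional)
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple, Union

import pandas as pd
import yaml

from .logistics import TransportParams, TransportRoute
from .resources import (
    MICROCOSTED_STEPS,
    ConsumableItem,
    CurrencyRate,
    EquipmentItem,
    ModelConstants,
    ReimbursementItem,
    ResourceCatalog,
    StaffRole,
)

_STEP_COLS = [s if s != "operation" else "operation" for s in MICROCOSTED_STEPS]

_STAFF_SCALAR_FIELDS = (
    "annual_multiplier",
    "weekly_hours",
    "weeks_per_year",
    "productive_hours_per_day",
    "workdays_per_month",
)


def _share_col(step: str) -> str:
    return f"share_{step}"


def _minutes_col(step: str) -> str:
    return f"minutes_{step}"


def read_catalog(path: Union[str, Path]) -> ResourceCatalog:
    """Load a catalog directory into a validated :class:`ResourceCatalog`."""
    path = Path(path)

    cons = pd.read_csv(path / "consumables.csv", dtype={"step": str})
    consumables = [
        ConsumableItem(
            name=r["name"],
            step_id=r["step"],
            units_per_exam=r["units_per_exam"],
            batch_size=int(r["batch_size"]),
            batch_price=r["batch_price"],
        )
        for _, r in cons.iterrows()
    ]

    eq = pd.read_csv(path / "equipment.csv")
    equipment = []
    for _, r in eq.iterrows():
        shares = {
            step: float(r[_share_col(step)])
            for step in MICROCOSTED_STEPS
            if _share_col(step) in eq.columns and pd.notna(r[_share_col(step)]) and r[_share_col(step)] > 0
        }
        equipment.append(
            EquipmentItem(
                name=r["name"],
                acquisition_cost=r["acquisition_cost"],
                maintenance_rate=r.get("maintenance_rate", 0.05),
                step_shares=shares,
                annual_throughput=r["annual_throughput"],
            )
        )

    st = pd.read_csv(path / "staff.csv")
    staff = []
    for _, r in st.iterrows():
        minutes = {
            step: float(r[_minutes_col(step)])
            for step in MICROCOSTED_STEPS
            if _minutes_col(step) in st.columns and pd.notna(r[_minutes_col(step)]) and r[_minutes_col(step)] > 0
        }
        kwargs = {
            f: r[f] for f in _STAFF_SCALAR_FIELDS if f in st.columns and pd.notna(r[f])
        }
        staff.append(
            StaffRole(
                name=r["name"],
                monthly_wage=r["monthly_wage"],
                hands_on_minutes_per_exam=minutes,
                **kwargs,
            )
        )

    reimb_path = path / "reimbursement.csv"
    reimbursements: List[ReimbursementItem] = []
    if reimb_path.exists():
        rb = pd.read_csv(reimb_path, dtype={"step": str})
        reimbursements = [
            ReimbursementItem(name=r["name"], step_id=r["step"], unit_price=r["unit_price"])
            for _, r in rb.iterrows()
        ]

    constants = ModelConstants()
    currency = CurrencyRate()
    const_path = path / "constants.yaml"
    if const_path.exists():
        raw = yaml.safe_load(const_path.read_text()) or {}
        if "brl_per_usd" in raw:
            currency = CurrencyRate(brl_per_usd=raw.pop("brl_per_usd"))
        constants = ModelConstants(**raw)

    return ResourceCatalog(
        consumables=consumables,
        equipment=equipment,
        staff=staff,
        reimbursements=reimbursements,
        constants=constants,
        currency=currency,
    )


def write_catalog(catalog: ResourceCatalog, path: Union[str, Path]) -> None:
    """Write a catalog as the directory layout read by :func:`read_catalog`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "name": c.name,
                "step": c.step_id,
                "units_per_exam": c.units_per_exam,
                "batch_size": c.batch_size,
                "batch_price": c.batch_price,
            }
            for c in catalog.consumables
        ]
    ).to_csv(path / "consumables.csv", index=False)

    pd.DataFrame(
        [
            {
                "name": e.name,
                "acquisition_cost": e.acquisition_cost,
                "maintenance_rate": e.maintenance_rate,
                "annual_throughput": e.annual_throughput,
                **{_share_col(s): e.step_shares.get(s, 0.0) for s in MICROCOSTED_STEPS},
            }
            for e in catalog.equipment
        ]
    ).to_csv(path / "equipment.csv", index=False)

    pd.DataFrame(
        [
            {
                "name": s.name,
                "monthly_wage": s.monthly_wage,
                **{f: getattr(s, f) for f in _STAFF_SCALAR_FIELDS},
                **{
                    _minutes_col(step): s.hands_on_minutes_per_exam.get(step, 0.0)
                    for step in MICROCOSTED_STEPS
                },
            }
            for s in catalog.staff
        ]
    ).to_csv(path / "staff.csv", index=False)

    pd.DataFrame(
        [
            {"name": r.name, "step": r.step_id, "unit_price": r.unit_price}
            for r in catalog.reimbursements
        ]
    ).to_csv(path / "reimbursement.csv", index=False)

    consts = catalog.constants.model_dump()
    consts["brl_per_usd"] = catalog.currency.brl_per_usd
    (path / "constants.yaml").write_text(yaml.safe_dump(consts, sort_keys=False))


def read_routes(path: Union[str, Path]) -> List[TransportRoute]:
    """Load a transport-route table (origin, destination, round_trip_km, tier)."""
    frame = pd.read_csv(path)
    return [
        TransportRoute(
            origin=r["origin"],
            destination=r["destination"],
            round_trip_km=r["round_trip_km"],
            activity_tier=r["tier"],
        )
        for _, r in frame.iterrows()
    ]


def write_routes(routes: List[TransportRoute], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "origin": r.origin,
                "destination": r.destination,
                "round_trip_km": r.round_trip_km,
                "tier": r.activity_tier,
            }
            for r in routes
        ]
    ).to_csv(path, index=False)


def read_transport_params(path: Union[str, Path]) -> TransportParams:
    """Load transport parameters from YAML; ``driver`` may be a nested role."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    driver = raw.pop("driver", None)
    params = TransportParams(**raw)
    if driver is not None:
        params = params.model_copy(update={"driver": StaffRole(**driver)})
    return params


def write_transport_params(params: TransportParams, path: Union[str, Path]) -> None:
    raw = params.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
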