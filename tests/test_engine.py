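import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import microcost as mc
from conftest import brute_force_consumable_cost


def _item(units, batch_size, price, step="4", name="it"):
    return mc.ConsumableItem(
        name=name, step_id=step, units_per_exam=units,
        batch_size=batch_size, batch_price=price,
    )


class TestConsumables:
    def test_batch_ceiling(self):
        # 100 exams x 1 unit over batches of 30 -> 4 batches of 300 = 12.00/exam
        assert mc.consumable_cost_per_exam([_item(1.0, 30, 300.0)], 100) == pytest.approx(12.0)

    @pytest.mark.parametrize("demand", [1, 7, 100, 1234])
    def test_unit_batches_have_no_granularity(self, demand):
        assert mc.consumable_cost_per_exam([_item(1.0, 1, 25.5)], demand) == pytest.approx(25.5)

    def test_zero_usage_costs_nothing(self):
        assert mc.consumable_cost_per_exam([_item(0.0, 10, 99.0)], 50) == 0.0

    def test_zero_demand_rejected(self):
        with pytest.raises(ValueError):
            mc.consumable_cost_per_exam([_item(1.0, 1, 1.0)], 0)

    @given(
        demand=st.integers(1, 50),
        items=st.lists(
            st.tuples(
                st.integers(0, 3),       # units per exam
                st.integers(1, 10),      # batch size
                st.floats(0, 500),       # batch price
            ),
            min_size=1,
            max_size=5,
        ),
    )
    def test_matches_brute_force_purchase_simulator(self, demand, items):
        catalog_items = [
            _item(float(u), b, p, name=f"i{k}") for k, (u, b, p) in enumerate(items)
        ]
        expected = brute_force_consumable_cost(catalog_items, demand)
        assert mc.consumable_cost_per_exam(catalog_items, demand) == pytest.approx(
            expected, rel=1e-12, abs=1e-9
        )

    @given(demand=st.integers(1, 2000))
    def test_ceiling_bounds_fractional_cost(self, demand):
        item = _item(1.0, 30, 300.0)
        cost = mc.consumable_cost_per_exam([item], demand)
        fractional = item.units_per_exam * item.batch_price / item.batch_size
        assert cost >= fractional - 1e-12
        if (demand * item.units_per_exam) % item.batch_size == 0:
            assert cost == pytest.approx(fractional)


class TestEquipment:
    def _equip(self, acq=100.0, rate=0.05, shares=None, throughput=25.0):
        return mc.EquipmentItem(
            name="e", acquisition_cost=acq, maintenance_rate=rate,
            step_shares=shares or {"5": 1.0}, annual_throughput=throughput,
        )

    @pytest.mark.parametrize(
        "acq,rate,years,expected",
        [(100.0, 0.05, 5, 125.0), (100.0, 0.0, 7, 100.0), (0.0, 0.05, 5, 0.0)],
    )
    def test_horizon_cost(self, acq, rate, years, expected):
        item = self._equip(acq=acq, rate=rate)
        assert mc.equipment_horizon_cost(item, years) == pytest.approx(expected)

    def test_per_exam_full_share(self):
        item = self._equip()
        assert mc.equipment_cost_per_exam(item, "5", 125, 5) == pytest.approx(1.0)

    def test_unused_step_costs_nothing(self):
        item = self._equip()
        assert mc.equipment_cost_per_exam(item, "3", 125, 5) == 0.0

    def test_pro_rata_shares_partition_the_horizon_cost(self):
        # fluorometer-style split across four steps
        shares = {"3": 0.2, "4": 0.2, "5": 0.4, "7": 0.2}
        item = self._equip(shares=shares)
        total = sum(
            mc.equipment_cost_per_exam(item, s, 1000, 5) for s in shares
        )
        assert total == pytest.approx(mc.equipment_horizon_cost(item, 5) / 1000)

    @given(n_small=st.integers(1, 10_000), extra=st.integers(1, 10_000))
    def test_per_exam_cost_strictly_decreases_with_utilisation(self, n_small, extra):
        item = self._equip(acq=5000.0)
        low = mc.equipment_cost_per_exam(item, "5", n_small, 5)
        high = mc.equipment_cost_per_exam(item, "5", n_small + extra, 5)
        assert high < low


class TestStaffAndWeights:
    @pytest.mark.parametrize(
        "monthly,minutes,expected",
        [
            (1000.0, 60.0, 14300.0 / 2080.0),   # one hour at the hourly rate
            (1000.0, 0.0, 0.0),
            (2080.0 * 10 / 14.3, 36.0, 6.0),    # hourly 10, 36 min
        ],
    )
    def test_staff_cost(self, monthly, minutes, expected):
        role = mc.StaffRole(
            name="r", monthly_wage=monthly,
            hands_on_minutes_per_exam={"2": minutes} if minutes else {},
        )
        assert mc.staff_cost_per_exam(role, "2") == pytest.approx(expected)

    def test_missing_step_contributes_nothing(self):
        role = mc.StaffRole(name="r", monthly_wage=5000.0,
                            hands_on_minutes_per_exam={"2": 60.0})
        assert mc.staff_cost_per_exam(role, "6") == 0.0

    @pytest.mark.parametrize("cost,frac,expected", [(100.0, 0.5, 50.0), (7.0, 1.0, 7.0), (7.0, 0.0, 0.0)])
    def test_probability_weight(self, cost, frac, expected):
        assert mc.apply_probability_weight(cost, frac) == expected

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            mc.apply_probability_weight(1.0, 1.2)


class TestOverhead:
    @pytest.mark.parametrize(
        "direct,expected",
        [
            (118.30 + 0.11 + 3.93, 12.234),  # sequencing step, reference
            (42.96 + 8.49 + 26.12, 7.757),   # confirmatory step, reference
            (0.0, 0.0),
        ],
    )
    def test_ten_percent_markup(self, direct, expected):
        assert mc.overhead_for_step(direct, 0.10) == pytest.approx(expected, abs=1e-9)

    def test_negative_direct_rejected(self):
        with pytest.raises(ValueError):
            mc.overhead_for_step(-1.0, 0.10)


class TestStepCostAndAggregate:
    def test_reimbursed_step_is_bundled_tariff_only(self, small_catalog):
        scn = mc.Scenario(name="t", fixed_horizon_samples=100)
        sc = mc.step_cost(small_catalog, scn, "1")
        assert sc.total == pytest.approx(104.53)
        assert sc.direct == 0.0 and sc.overhead == 0.0

    def test_step_without_resources_is_all_zero(self, small_catalog):
        scn = mc.Scenario(name="t", fixed_horizon_samples=100)
        sc = mc.step_cost(small_catalog, scn, "6")
        assert sc.total == 0.0

    def test_unknown_step_rejected(self, small_catalog):
        scn = mc.Scenario(name="t", fixed_horizon_samples=100)
        with pytest.raises(ValueError):
            mc.step_cost(small_catalog, scn, "9")

    def test_reference_blood_collection_column(self, reference_breakdown):
        sc = reference_breakdown.step("2")
        assert sc.overhead == pytest.approx(1.154, abs=1e-9)
        assert sc.total == pytest.approx(12.69, abs=0.01)

    def test_aggregate_rejects_duplicate_steps(self):
        steps = [mc.StepCost(step_id="2"), mc.StepCost(step_id="2")]
        with pytest.raises(ValueError):
            mc.aggregate(steps)

    def test_empty_pathway_aggregates_to_zero(self):
        b = mc.aggregate([])
        assert b.grand_total == 0.0 and b.genetic_testing_total == 0.0

    def test_grand_total_is_sum_of_step_totals(self, reference_breakdown):
        assert reference_breakdown.grand_total == pytest.approx(
            sum(sc.total for sc in reference_breakdown.per_step)
        )

    def test_component_shares_sum_to_one(self, reference_breakdown, alternative_breakdown):
        for b in (reference_breakdown, alternative_breakdown):
            assert sum(b.component_shares.values()) == pytest.approx(1.0, abs=1e-9)

    @given(seed=st.integers(0, 99))
    def test_additivity_and_overhead_proportionality(self, seed):
        """Scaling every direct cost by k scales genetic-testing totals by k,
        and the grand total always equals the sum of step totals."""
        import numpy as np

        rng = np.random.default_rng(seed)
        table = {
            step: {
                "consumables": float(rng.uniform(0, 100)),
                "staff": float(rng.uniform(0, 50)),
                "equipment": float(rng.uniform(0, 30)),
            }
            for step in mc.MICROCOSTED_STEPS
        }
        k = float(rng.uniform(0.5, 3.0))
        base = mc.aggregate(mc.component_mode_ingest(table))
        scaled_table = {
            s: {c: v * k for c, v in row.items()} for s, row in table.items()
        }
        scaled = mc.aggregate(mc.component_mode_ingest(scaled_table))
        assert base.grand_total == pytest.approx(sum(sc.total for sc in base.per_step))
        assert scaled.genetic_testing_total == pytest.approx(
            k * base.genetic_testing_total, rel=1e-9
        )


class TestComponentIngest:
    def test_reference_overhead_cells(self, reference_breakdown):
        expected = {
            "2": 1.15, "3": 2.34, "4": 14.22, "5": 12.23,
            "6": 7.63, "7": 7.76, "operation": 2.65,
        }
        for step, value in expected.items():
            assert reference_breakdown.step(step).overhead == pytest.approx(value, abs=0.01)

    def test_alternative_overhead_total(self, alternative_breakdown):
        assert alternative_breakdown.component_totals["overhead"] == pytest.approx(
            35.18, abs=0.02
        )

    def test_all_zero_table(self):
        table = {s: {"consumables": 0.0, "staff": 0.0, "equipment": 0.0}
                 for s in mc.MICROCOSTED_STEPS}
        b = mc.aggregate(mc.component_mode_ingest(table))
        assert b.grand_total == 0.0

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            mc.component_mode_ingest({"2": {"consumables": 1.0, "staff": 1.0}})

    def test_overhead_never_read_from_table(self):
        table = {"2": {"consumables": 10.0, "staff": 0.0, "equipment": 0.0,
                       "overhead": 999.0}}
        steps = mc.component_mode_ingest(table, overhead_rate=0.10)
        assert steps[0].overhead == pytest.approx(1.0)
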