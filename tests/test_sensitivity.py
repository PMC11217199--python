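import pytest
from hypothesis import given
from hypothesis import strategies as st

import microcost as mc


class TestTornado:
    def test_equipment_doubling_reference(self, reference_breakdown):
        results = mc.tornado(
            reference_breakdown, [mc.SensitivityRange("equipment", 0.8, 2.0)]
        )
        r = results[0]
        assert int(mc.round_half_away(r.high_impact_pct)) == 7
        assert r.low_total <= r.baseline_total <= r.high_total

    def test_equipment_doubling_alternative(self, alternative_breakdown):
        results = mc.tornado(
            alternative_breakdown, [mc.SensitivityRange("equipment", 0.8, 2.0)]
        )
        assert int(mc.round_half_away(results[0].high_impact_pct)) == 2

    def test_unit_factor_has_no_impact(self, reference_breakdown):
        results = mc.tornado(
            reference_breakdown, [mc.SensitivityRange("staff", 1.0, 1.0)]
        )
        assert results[0].low_impact_pct == pytest.approx(0.0)
        assert results[0].high_impact_pct == pytest.approx(0.0)

    def test_sorted_by_impact_magnitude(self, reference_breakdown):
        results = mc.tornado(reference_breakdown)
        magnitudes = [abs(r.high_impact_pct) for r in results]
        assert magnitudes == sorted(magnitudes, reverse=True)
        # consumables dominate the reference scenario
        assert results[0].parameter == "consumables"

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            mc.SensitivityRange("logistics", 0.5, 1.5)

    @given(
        factor=st.floats(0.1, 3.0),
        component=st.sampled_from(["consumables", "staff", "equipment"]),
    )
    def test_impact_is_linear_in_component_share(self, reference_breakdown, factor, component):
        """With overhead held fixed, impact% = share x (factor - 1) x 100."""
        results = mc.tornado(
            reference_breakdown, [mc.SensitivityRange(component, factor, factor)]
        )
        expected = reference_breakdown.component_shares[component] * (factor - 1) * 100
        assert results[0].high_impact_pct == pytest.approx(expected, abs=1e-9)


class TestOverheadRange:
    def test_reference_band(self, reference_breakdown):
        low, high = mc.overhead_range(reference_breakdown, 0.20, 0.30)
        assert low == pytest.approx(575.83, abs=0.03)
        assert high == pytest.approx(623.82, abs=0.03)

    def test_alternative_band(self, alternative_breakdown):
        low, high = mc.overhead_range(alternative_breakdown, 0.20, 0.30)
        assert low == pytest.approx(422.16, abs=0.03)
        assert high == pytest.approx(457.34, abs=0.03)

    def test_baseline_rate_recovers_baseline_total(self, reference_breakdown):
        low, _ = mc.overhead_range(reference_breakdown, 0.10, 0.30)
        assert low == pytest.approx(reference_breakdown.genetic_testing_total)

    def test_band_above_baseline_when_baseline_rate_below_band(self, reference_breakdown):
        # base-case rate 0.10 sits below the conventional 20-30% band, so the
        # band does not bracket the baseline: total(0.10) < total(0.20) < total(0.30)
        base = reference_breakdown.genetic_testing_total
        low, high = mc.overhead_range(reference_breakdown, 0.20, 0.30)
        assert base < low < high

    def test_rates_validated(self, reference_breakdown):
        with pytest.raises(ValueError):
            mc.overhead_range(reference_breakdown, -0.1, 0.3)


class TestCostPerDiagnosis:
    @pytest.mark.parametrize(
        "cost,yield_,expected",
        [(527.85, 0.62, 851.37), (527.85, 0.80, 659.81), (42.0, 1.0, 42.0)],
    )
    def test_examples(self, cost, yield_, expected):
        assert mc.cost_per_positive_diagnosis(cost, yield_) == pytest.approx(
            expected, abs=0.02
        )

    def test_zero_yield_rejected(self):
        with pytest.raises(ValueError):
            mc.cost_per_positive_diagnosis(100.0, 0.0)

    @given(
        lo=st.floats(0.05, 0.95),
        delta=st.floats(0.01, 0.5),
    )
    def test_strictly_decreasing_in_yield(self, lo, delta):
        hi = min(lo + delta, 1.0)
        assert mc.cost_per_positive_diagnosis(100.0, hi) < mc.cost_per_positive_diagnosis(100.0, lo)


class TestItemSubsetScan:
    def test_top_k_scan_bounded_by_full_component_scan(self):
        """Scaling only the costliest reagents moves the total less than
        scaling the whole consumable component."""
        config = mc.GeneratorConfig(seed=3)
        catalog = mc.generate_catalog(config)
        scn = mc.Scenario(name="s", fixed_horizon_samples=500, utilization="shared")
        subset = mc.tornado_top_consumables(catalog, scn, top_k=2, high_factor=1.3)
        full = mc.tornado_top_consumables(
            catalog, scn, top_k=len(catalog.consumables), high_factor=1.3
        )
        assert 0.0 < subset.high_impact_pct <= full.high_impact_pct + 1e-9
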