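"""Scenario orchestration, baseline evaluation and comparison reports."""

import numpy as np
import pytest

from cropalloc import (
    ScenarioConfig,
    apply_eta_rule,
    categorize_income_change,
    evaluate_baseline,
    income_change,
    msp_sensitivity,
    nutrition_adequacy,
    nutrition_targets,
    run_scenario,
)
from cropalloc.report import econ_params


@pytest.fixture(scope="module")
def zero_result(small_instance, small_water_yield):
    return run_scenario(small_instance, ScenarioConfig(scenario="zero"),
                        water_yield=small_water_yield)


@pytest.fixture(scope="module")
def capped_result(small_instance, small_water_yield):
    return run_scenario(small_instance, ScenarioConfig(scenario="capped"),
                        water_yield=small_water_yield)


class TestBaselineEvaluation:
    def test_zero_allocation_gives_zero_metrics(self, small_instance, small_water_yield):
        econ = econ_params(small_instance)
        base = evaluate_baseline(
            np.zeros_like(small_instance.baseline_area), small_water_yield, econ,
            small_instance.suitability, small_instance.districts.eta,
            nutrients=small_instance.crops.nutrients,
        )
        assert base.revenue_inr == 0
        assert np.all(base.production_kg == 0)
        assert np.all(base.nutrition == 0)
        assert base.total_water_m3 == 0

    def test_matches_hand_loop(self, small_instance, small_water_yield):
        inst = small_instance
        econ = econ_params(inst)
        base = evaluate_baseline(
            inst.baseline_area, small_water_yield, econ, inst.suitability,
            inst.districts.eta, nutrients=inst.crops.nutrients,
        )
        n_c, n_d, n_y = small_water_yield.sd.shape
        revenue = 0.0
        for i in range(n_c):
            for j in range(n_d):
                if not inst.suitability[i, j]:
                    continue
                a = inst.baseline_area[i, j]
                eta = inst.districts.eta[i, j]
                margins, energies = [], []
                for t in range(n_y):
                    sd, cwr = small_water_yield.sd[i, j, t], small_water_yield.cwr[i, j, t]
                    y = (1 - (1 - eta) * sd / cwr) * inst.crops.potential_yield[i]
                    margins.append((inst.msp[i, j] - inst.cp[i, j]) * y)
                    v = (1 / inst.crops.beta[i]) * eta * sd * 10.0
                    energies.append(v * 1000 * 9.81 *
                                    inst.districts.table.depth_m[j] / 0.3 / 3.6e6)
                revenue += (np.mean(margins) - 3.0 * np.mean(energies)) * a
        assert base.revenue_inr == pytest.approx(revenue, rel=1e-9)

    def test_optimum_evaluates_to_its_own_objective(self, small_instance,
                                                    small_water_yield, zero_result):
        """Re-evaluating the optimal allocation with the baseline arithmetic
        (under the scenario's eta) reproduces the LP objective, so comparing
        the optimum against itself gives zero income change."""
        inst = small_instance
        eta0 = apply_eta_rule(inst.districts.eta, "zero")
        again = evaluate_baseline(
            zero_result.solution.area, small_water_yield, econ_params(inst),
            inst.suitability, eta0, nutrients=inst.crops.nutrients,
        )
        assert again.revenue_inr == pytest.approx(zero_result.solution.objective, rel=1e-9)
        assert income_change(zero_result.solution.objective, again.revenue_inr) == (
            pytest.approx(0.0, abs=1e-3)
        )

    def test_rejects_overallocated_baseline(self, small_instance, small_water_yield):
        tca = small_instance.districts.table["tca_ha"].to_numpy()
        with pytest.raises(ValueError):
            evaluate_baseline(
                np.full_like(small_instance.baseline_area, tca.max()),
                small_water_yield, econ_params(small_instance),
                small_instance.suitability, small_instance.districts.eta, tca=tca,
            )


class TestScenarioRuns:
    def test_zero_scenario_uses_no_water_or_energy(self, zero_result):
        assert np.all(zero_result.solution.district_water_m3 == 0)
        assert np.all(zero_result.solution.district_energy_kwh == 0)
        assert zero_result.national["water_optimal_m3"] == 0
        assert zero_result.national["energy_optimal_kwh"] == 0

    def test_constraint_counts(self, small_instance, zero_result, capped_result):
        n_d = small_instance.districts.n_districts
        assert zero_result.national["n_constraints"] == n_d + 12 + 6
        assert capped_result.national["n_constraints"] == 2 * n_d + 12 + 6

    def test_production_meets_targets(self, zero_result, capped_result):
        for res in (zero_result, capped_result):
            q = res.baseline.production_kg
            scale = np.maximum(q, 1.0)
            assert np.all(res.solution.production_kg >= q - 1e-6 * scale)

    def test_state_totals_equal_district_sums(self, capped_result):
        district, state = capped_result.district_report, capped_result.state_report
        for col in ("income_change_inr", "water_scenario_m3", "energy_scenario_kwh",
                    "opportunity_cost_inr"):
            by_state = district.groupby("state")[col].sum().sort_index()
            np.testing.assert_allclose(
                by_state.to_numpy(),
                state.sort_values("state")[col].to_numpy(),
                rtol=1e-12,
            )

    def test_objective_self_consistency(self, capped_result):
        """Reported objective equals gross margin minus tariff x energy,
        recomputed from the reported allocation."""
        res = capped_result
        inst = res.solution.instance
        x = res.solution.area[inst.var_crop, inst.var_district]
        margin = (res.coefficients.gross_margin[inst.var_crop, inst.var_district] * x).sum()
        energy_cost = 3.0 * (inst.var_energy_kwh * x).sum()
        assert res.solution.objective == pytest.approx(margin - energy_cost, rel=1e-9)

    def test_capped_water_respects_bounds(self, small_instance, capped_result):
        d = small_instance.districts.table
        cap = 0.15 * d["mean_annual_rain_mm"].to_numpy() * d["net_cropped_ha"].to_numpy() * 10
        used = capped_result.solution.district_water_m3
        assert np.all(used <= cap * (1 + 1e-9))

    def test_binding_water_bound_is_attained(self):
        """One-district toy where water limits the profitable crop: the
        reported district water use equals the irrigation bound."""
        from _toys import toy_problem
        from cropalloc import build_lp, solve_lp

        w = np.array([[4.0]])             # m3 per ha
        cap = np.array([100.0])           # binding: TCA * w = 800 >> 100
        coeffs, districts, crops = toy_problem([[9.0]], [200.0], water=w)
        sol = solve_lp(build_lp(coeffs, districts, crops, [0.0], [0.0],
                                "capped", irrigation_cap_override=cap))
        assert sol.district_water_m3[0] == pytest.approx(cap[0])
        assert sol.area[0, 0] == pytest.approx(25.0)

    def test_nutrition_report(self, zero_result, small_instance):
        targets = nutrition_targets(small_instance.config)
        table = zero_result.nutrition
        assert table["adequate"].all()
        np.testing.assert_allclose(table["target"], targets)


class TestIncomeCategories:
    def test_interval_rules(self):
        assert categorize_income_change(0.0) == "neutral"
        assert categorize_income_change(0.02e12) == "positive"
        assert categorize_income_change(-0.02e12) == "negative"
        # half-open boundaries: the left edge belongs to the interval
        assert categorize_income_change(0.01e12) == "positive"
        assert categorize_income_change(-0.01e12) == "neutral"
        # clamping beyond the outermost bounds
        assert categorize_income_change(5e12) == "positive"
        assert categorize_income_change(-5e12) == "negative"

    def test_vector_input(self):
        labels = categorize_income_change(np.array([0.0, 0.02e12, -0.02e12]))
        assert list(labels) == ["neutral", "positive", "negative"]


class TestNutritionAdequacy:
    def test_zero_production_fails_all(self):
        table = nutrition_adequacy(np.zeros(3), np.ones((2, 3)), np.ones(2))
        assert not table["adequate"].any()

    def test_exact_boundary_passes(self):
        nutrients = np.array([[2.0, 1.0]])
        production = np.array([1.0, 3.0])
        table = nutrition_adequacy(production, nutrients, np.array([5.0]))
        assert table["adequate"].all()
        assert table["total"].iloc[0] == pytest.approx(5.0)

    def test_matches_hand_summation(self):
        rng = np.random.default_rng(0)
        nutrients = rng.uniform(0, 10, (4, 5))
        production = rng.uniform(0, 1e6, 5)
        table = nutrition_adequacy(production, nutrients, rng.uniform(0, 1e7, 4))
        for n in range(4):
            assert table["total"].iloc[n] == pytest.approx(
                sum(nutrients[n, i] * production[i] for i in range(5))
            )


class TestSensitivity:
    def test_zero_reduction_is_noop_and_flags_consistent(self, small_instance,
                                                         small_water_yield):
        out = msp_sensitivity(
            small_instance, ScenarioConfig(scenario="zero"),
            reductions=(0.0, 0.3), crops=[0, 7], water_yield=small_water_yield,
        )
        noop = out[out["reduction"] == 0.0]
        assert not noop["support_changed"].any()
        grouped = out.groupby("crop")["support_changed"].any()
        for crop, changed in grouped.items():
            assert (out.loc[out.crop == crop, "stable"] == (not changed)).all()

    def test_break_even_flip_in_two_crop_duel(self):
        """One district, two crops, margins 100 vs 60 per ha: the support
        flips exactly when the stronger crop is cut past 40%."""
        from cropalloc import build_lp, solve_lp
        from _toys import toy_problem

        for r, flipped in [(0.3, False), (0.5, True)]:
            c = np.array([[100.0 * (1 - r)], [60.0]])
            coeffs, districts, crops = toy_problem(c, [50.0])
            sol = solve_lp(build_lp(coeffs, districts, crops, np.zeros(2),
                                    np.zeros(1), "zero"))
            winner = int(np.argmax(sol.area[:, 0]))
            assert (winner == 1) == flipped
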