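"""Assembly and solution of the allocation linear program."""

import numpy as np
import pytest

from cropalloc import (
    InfeasibleLPError,
    build_lp,
    constraint_count,
    shadow_price_report,
    solve_lp,
    to_mps,
    verify_optimality,
)
from _toys import toy_problem


class TestConstraintCounts:
    @pytest.mark.parametrize(
        "n_d,n_c,n", [(586, 12, 6), (2, 2, 1), (100, 7, 3), (1, 1, 1)]
    )
    def test_count_formula(self, n_d, n_c, n):
        assert constraint_count(n_d, n_c, n, "capped") == 2 * n_d + n_c + n
        assert constraint_count(n_d, n_c, n, "zero") == n_d + n_c + n

    def test_built_rows_match_formula(self):
        coeffs, districts, crops = toy_problem(
            np.ones((2, 2)), [100.0, 100.0], nutrients=np.ones((1, 2))
        )
        capped = build_lp(coeffs, districts, crops, np.zeros(2), np.zeros(1), "capped")
        zero = build_lp(coeffs, districts, crops, np.zeros(2), np.zeros(1), "zero")
        assert capped.n_constraints == 7  # 2*2 + 2 + 1
        assert zero.n_constraints == 5
        assert list(np.unique(capped.row_family)) == sorted(
            ["area", "irrigation", "production", "nutrition"]
        )


class TestSolve:
    def test_single_variable_closed_form(self):
        coeffs, districts, crops = toy_problem([[5.0]], [200.0])
        inst = build_lp(coeffs, districts, crops, [0.0], [0.0], "zero")
        sol = solve_lp(inst)
        assert sol.area[0, 0] == pytest.approx(200.0)
        assert sol.objective == pytest.approx(1000.0)
        # area shadow price equals the objective coefficient
        area_dual = sol.duals[sol.instance.row_family == "area"][0]
        assert area_dual == pytest.approx(5.0)

    def test_nothing_forced_when_unprofitable(self):
        coeffs, districts, crops = toy_problem(
            -np.ones((2, 3)), [50.0, 60.0, 70.0]
        )
        sol = solve_lp(build_lp(coeffs, districts, crops, np.zeros(2), np.zeros(1), "zero"))
        assert sol.objective == pytest.approx(0.0)
        np.testing.assert_allclose(sol.area, 0.0)

    def test_matches_grid_enumeration_2x2(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(1, 10, (2, 2))
        w = rng.uniform(1, 5, (2, 2))
        tca = np.array([80.0, 120.0])
        cap = np.array([150.0, 260.0])
        coeffs, districts, crops = toy_problem(c, tca, water=w)
        inst = build_lp(coeffs, districts, crops, np.zeros(2), np.zeros(1),
                        "capped", irrigation_cap_override=cap)
        sol = solve_lp(inst)

        # Exhaustive enumeration: with production/nutrition slack, districts
        # decouple; scan the 2-crop simplex at step TCA/200 per district.
        best = 0.0
        for j in range(2):
            best_j = 0.0
            step = tca[j] / 200
            for a0 in np.arange(0, tca[j] + step / 2, step):
                for a1 in np.arange(0, tca[j] - a0 + step / 2, step):
                    if w[0, j] * a0 + w[1, j] * a1 <= cap[j]:
                        best_j = max(best_j, c[0, j] * a0 + c[1, j] * a1)
            best += best_j
        assert sol.objective == pytest.approx(best, rel=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_duality_certificate_and_second_algorithm(self, seed):
        """Optimality is certified solver-independently by LP duality, and
        the dual-simplex and interior-point optima agree to 1e-6."""
        rng = np.random.default_rng(seed)
        n_c, n_d = 4, 6
        c = rng.uniform(-5, 20, (n_c, n_d))
        y = rng.uniform(500, 4000, (n_c, n_d))
        w = rng.uniform(0, 8, (n_c, n_d))
        tca = rng.uniform(100, 400, n_d)
        nutrients = rng.uniform(0, 5, (2, n_c))
        coeffs, districts, crops = toy_problem(c, tca, water=w, mean_yield=y,
                                               nutrients=nutrients)
        # feasible targets: half of what a uniform allocation achieves
        a_uniform = np.full((n_c, n_d), (tca / n_c))
        q = 0.5 * (y * a_uniform).sum(axis=1)
        n_t = 0.5 * nutrients @ (y * a_uniform).sum(axis=1)
        inst = build_lp(coeffs, districts, crops, q, n_t, "capped",
                        irrigation_cap_override=rng.uniform(500, 3000, n_d))
        sol = solve_lp(inst)
        assert verify_optimality(inst, sol)
        sol_ipm = solve_lp(inst, method="highs-ipm")
        assert sol_ipm.objective == pytest.approx(sol.objective, rel=1e-6)

    def test_relaxing_bounds_never_hurts(self):
        rng = np.random.default_rng(11)
        c = rng.uniform(0, 10, (3, 4))
        w = rng.uniform(1, 4, (3, 4))
        tca = rng.uniform(50, 150, 4)
        cap = rng.uniform(50, 200, 4)
        coeffs, districts, crops = toy_problem(c, tca, water=w)
        base = solve_lp(build_lp(coeffs, districts, crops, np.zeros(3), np.zeros(1),
                                 "capped", irrigation_cap_override=cap)).objective
        bigger_tca = solve_lp(build_lp(
            toy_problem(c, tca * 2, water=w)[0], toy_problem(c, tca * 2, water=w)[1],
            crops, np.zeros(3), np.zeros(1), "capped",
            irrigation_cap_override=cap)).objective
        bigger_cap = solve_lp(build_lp(coeffs, districts, crops, np.zeros(3), np.zeros(1),
                                       "capped", irrigation_cap_override=cap * 2)).objective
        assert bigger_tca >= base - 1e-6
        assert bigger_cap >= base - 1e-6

    def test_price_scaling_scales_objective(self):
        rng = np.random.default_rng(13)
        c = rng.uniform(-2, 10, (3, 3))
        tca = rng.uniform(50, 150, 3)
        coeffs, districts, crops = toy_problem(c, tca)
        sol1 = solve_lp(build_lp(coeffs, districts, crops, np.zeros(3), np.zeros(1), "zero"))
        coeffs5, _, _ = toy_problem(5 * c, tca)
        sol5 = solve_lp(build_lp(coeffs5, districts, crops, np.zeros(3), np.zeros(1), "zero"))
        assert sol5.objective == pytest.approx(5 * sol1.objective)
        np.testing.assert_allclose(sol5.area, sol1.area, atol=1e-6)

    def test_infeasible_names_production_family(self):
        coeffs, districts, crops = toy_problem(
            np.ones((1, 1)), [10.0], mean_yield=np.array([[100.0]])
        )
        with pytest.raises(InfeasibleLPError) as err:
            solve_lp(build_lp(coeffs, districts, crops, [1e6], [0.0], "zero"))
        assert "production" in str(err.value) or err.value.diagnosis["production"] > 0
        assert err.value.diagnosis["production"] > 0

    def test_empty_variable_set_rejected(self):
        coeffs, districts, crops = toy_problem(np.ones((1, 1)), [10.0])
        coeffs.delta = np.zeros((1, 1), dtype=int)
        with pytest.raises(ValueError):
            build_lp(coeffs, districts, crops, [0.0], [0.0], "zero")


class TestShadowPrices:
    def _solved(self, seed=3):
        rng = np.random.default_rng(seed)
        c = rng.uniform(-1, 10, (3, 5))
        tca = rng.uniform(50, 150, 5)
        coeffs, districts, crops = toy_problem(
            c, tca, mean_yield=rng.uniform(500, 3000, (3, 5)))
        inst = build_lp(coeffs, districts, crops, np.zeros(3), np.zeros(1), "zero")
        return inst, solve_lp(inst)

    def test_complementary_slackness(self):
        _, sol = self._solved()
        table = shadow_price_report(sol)
        nonbinding = table[~table["binding"]]
        assert np.allclose(nonbinding["dual"], 0.0, atol=1e-7)
        assert set(table["unit"]) <= {"INR/ha", "INR/m3", "INR/kg", "INR/unit"}

    def test_dual_predicts_bound_tightening(self):
        inst, sol = self._solved()
        table = shadow_price_report(sol)
        area = table[table["family"] == "area"].reset_index()
        j = int(area["dual"].idxmax())
        dual = area.loc[j, "dual"]
        assert dual > 0
        delta = 1.0
        b2 = inst.b_ub.copy()
        b2[j] -= delta
        inst2 = type(inst)(**{**inst.__dict__, "b_ub": b2})
        sol2 = solve_lp(inst2)
        assert sol.objective - sol2.objective == pytest.approx(dual * delta, rel=1e-4)


class TestMPSExport:
    def test_serialization_structure(self):
        coeffs, districts, crops = toy_problem(np.ones((2, 2)), [10.0, 20.0])
        inst = build_lp(coeffs, districts, crops, np.zeros(2), np.zeros(1), "zero")
        mps = to_mps(inst)
        assert mps.startswith("NAME")
        assert "OBJSENSE" in mps and "MAX" in mps
        assert mps.count(" L  R") == inst.n_constraints
        assert mps.rstrip().endswith("ENDATA")
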