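"""Scenario orchestration and district/state comparison reporting.

Runs the end-to-end pipeline for one irrigation scenario — eta rule,
water balance, coefficients, LP — and compares the optimum with the
baseline ("current") allocation: income change per district and state,
water and energy saved or used, the opportunity-cost value of energy
savings, nutrition adequacy, and the support-price sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_INCOME_CATEGORIES, ScenarioConfig
from .economics import EconParams, net_revenue_coefficients, opportunity_cost
from .lp import AllocationSolution, build_lp, solve_lp
from .synthetic import SyntheticInstance, nutrition_targets
from .water import WaterYieldTable, compute_water_yield

TRILLION = 1e12


def apply_eta_rule(eta: np.ndarray, scenario: str) -> np.ndarray:
    """Scenario irrigation potential: 'zero' sets eta = 0 everywhere;
    'capped' raises every crop to the district maximum max_i(eta_ij)."""
    if scenario == "zero":
        return np.zeros_like(eta)
    if scenario == "capped":
        return np.broadcast_to(eta.max(axis=0, keepdims=True), eta.shape).copy()
    raise ValueError("scenario must be 'zero' or 'capped'")


def econ_params(instance: SyntheticInstance,
                valuation_price: float = 7.0) -> EconParams:
    """EconParams assembled from a synthetic instance's tables."""
    return EconParams(
        msp=instance.msp,
        cp=instance.cp,
        tariff=instance.districts.table["tariff_inr_kwh"].to_numpy(),
        beta=instance.crops.beta,
        depth_m=instance.districts.table["depth_m"].to_numpy(),
        valuation_price=valuation_price,
    )


@dataclass
class BaselineMetrics:
    """The current allocation evaluated with the objective arithmetic."""

    revenue_inr: float
    production_kg: np.ndarray        # per crop, expected
    nutrition: np.ndarray            # per nutrient
    district_income: np.ndarray      # INR
    district_water_m3: np.ndarray
    district_energy_kwh: np.ndarray

    @property
    def total_water_m3(self) -> float:
        return float(self.district_water_m3.sum())

    @property
    def total_energy_kwh(self) -> float:
        return float(self.district_energy_kwh.sum())


def evaluate_baseline(baseline_area: np.ndarray, water_yield: WaterYieldTable,
                      econ: EconParams, delta: np.ndarray,
                      eta: np.ndarray, tca: np.ndarray | None = None,
                      nutrients: np.ndarray | None = None) -> BaselineMetrics:
    """Evaluate a fixed allocation with the same arithmetic as the objective.

    Uses the current (generated) irrigation potential eta. The resulting
    expected production per crop is the default food-security target Q_i.
    """
    baseline_area = np.asarray(baseline_area, dtype=float)
    if np.any(baseline_area < 0):
        raise ValueError("baseline areas must be non-negative")
    if tca is not None and np.any(
        baseline_area.sum(axis=0) > np.asarray(tca) * (1 + 1e-9)
    ):
        raise ValueError("baseline allocation exceeds a district's cropped area")
    coeffs = net_revenue_coefficients(water_yield, econ, delta, eta)
    district_income = (coeffs.objective * baseline_area).sum(axis=0)
    production = (coeffs.mean_yield * baseline_area).sum(axis=1)
    nutrition = (
        nutrition_totals(production, nutrients)
        if nutrients is not None
        else np.zeros(0)
    )
    return BaselineMetrics(
        revenue_inr=float(district_income.sum()),
        production_kg=production,
        nutrition=nutrition,
        district_income=district_income,
        district_water_m3=(coeffs.water_m3 * baseline_area).sum(axis=0),
        district_energy_kwh=(coeffs.energy_kwh * baseline_area).sum(axis=0),
    )


def nutrition_totals(production_kg: np.ndarray, nutrients: np.ndarray) -> np.ndarray:
    """Per-nutrient totals sum_i c_ni * production_i."""
    return np.asarray(nutrients, dtype=float) @ np.asarray(production_kg, dtype=float)


def nutrition_adequacy(production_kg: np.ndarray, nutrients: np.ndarray,
                       targets: np.ndarray,
                       names: tuple | None = None) -> pd.DataFrame:
    """Compare per-nutrient totals with the recommended targets."""
    totals = nutrition_totals(production_kg, nutrients)
    targets = np.asarray(targets, dtype=float)
    return pd.DataFrame(
        {
            "nutrient": list(names) if names is not None else list(range(len(totals))),
            "total": totals,
            "target": targets,
            "adequate": totals >= targets - 1e-9 * np.maximum(targets, 1.0),
        }
    )


def income_change(scenario_revenue_inr: float, baseline_revenue_inr: float) -> float:
    """Net income gain of a scenario over the baseline (INR)."""
    return float(scenario_revenue_inr) - float(baseline_revenue_inr)


def categorize_income_change(delta_inr, categories=DEFAULT_INCOME_CATEGORIES):
    """Label district income changes by the trillion-INR map categories.

    Intervals are closed on the left, open on the right; values outside
    the outermost bounds clamp to the extreme categories.
    """
    delta_tr = np.atleast_1d(np.asarray(delta_inr, dtype=float)) / TRILLION
    names = [c[0] for c in categories]
    lows = np.array([c[1] for c in categories])
    idx = np.searchsorted(lows, delta_tr, side="right") - 1
    idx = np.clip(idx, 0, len(names) - 1)
    labels = np.array(names, dtype=object)[idx]
    return labels if np.ndim(delta_inr) else labels[0]


@dataclass
class ScenarioResult:
    """Everything one scenario run produces."""

    config: ScenarioConfig
    solution: AllocationSolution
    baseline: BaselineMetrics
    district_report: pd.DataFrame
    state_report: pd.DataFrame
    national: dict
    nutrition: pd.DataFrame
    coefficients: object


def _comparison_tables(instance, solution, baseline, cfg):
    dist = instance.districts.table
    scen_income = np.zeros(instance.districts.n_districts)
    x = solution.area[solution.instance.var_crop, solution.instance.var_district]
    np.add.at(
        scen_income, solution.instance.var_district, solution.instance.c * x
    )
    d_income = scen_income - baseline.district_income
    water_saved = baseline.district_water_m3 - solution.district_water_m3
    energy_saved = baseline.district_energy_kwh - solution.district_energy_kwh
    district = pd.DataFrame(
        {
            "district": dist["district"],
            "state": dist["state"],
            "income_current_inr": baseline.district_income,
            "income_scenario_inr": scen_income,
            "income_change_inr": d_income,
            "income_category": categorize_income_change(
                d_income, cfg.income_categories
            ),
            "water_current_m3": baseline.district_water_m3,
            "water_scenario_m3": solution.district_water_m3,
            "water_saved_m3": water_saved,
            "energy_current_kwh": baseline.district_energy_kwh,
            "energy_scenario_kwh": solution.district_energy_kwh,
            "energy_saved_kwh": energy_saved,
            "opportunity_cost_inr": opportunity_cost(
                energy_saved, cfg.valuation_price
            ),
        }
    )
    numeric = [c for c in district.columns if c.endswith(("_inr", "_m3", "_kwh"))]
    state = district.groupby("state", as_index=False)[numeric].sum()
    return district, state


def run_scenario(instance: SyntheticInstance, cfg: ScenarioConfig,
                 water_yield: WaterYieldTable | None = None,
                 baseline: BaselineMetrics | None = None) -> ScenarioResult:
    """Full pipeline for one scenario: eta rule -> water/yield ->
    coefficients -> LP -> comparison report against the baseline."""
    cfg.validate()
    econ = econ_params(instance, cfg.valuation_price)
    if water_yield is None:
        water_yield = compute_water_yield(instance.climate, instance.crops, cfg.alpha)
    if baseline is None:
        baseline = evaluate_baseline(
            instance.baseline_area, water_yield, econ, instance.suitability,
            instance.districts.eta, instance.districts.table["tca_ha"].to_numpy(),
            instance.crops.nutrients,
        )

    eta_s = apply_eta_rule(instance.districts.eta, cfg.scenario)
    coeffs = net_revenue_coefficients(water_yield, econ, instance.suitability, eta_s)
    q = (
        np.asarray(cfg.production_targets_override, dtype=float)
        if cfg.production_targets_override is not None
        else baseline.production_kg
    )
    n_targets = nutrition_targets(instance.config) * cfg.nutrition_scale
    inst = build_lp(
        coeffs, instance.districts, instance.crops, q, n_targets,
        cfg.scenario, cfg.lam, cfg.irrigation_cap_override,
    )
    solution = solve_lp(inst)

    district, state = _comparison_tables(instance, solution, baseline, cfg)
    nutrition = nutrition_adequacy(
        solution.production_kg, instance.crops.nutrients, n_targets,
        instance.crops.nutrient_names,
    )
    national = {
        "scenario": cfg.scenario,
        "revenue_current_inr": baseline.revenue_inr,
        "revenue_optimal_inr": solution.objective,
        "income_gain_inr": income_change(solution.objective, baseline.revenue_inr),
        "water_current_m3": baseline.total_water_m3,
        "water_optimal_m3": float(solution.district_water_m3.sum()),
        "energy_current_kwh": baseline.total_energy_kwh,
        "energy_optimal_kwh": float(solution.district_energy_kwh.sum()),
        "energy_saved_value_inr": float(
            opportunity_cost(
                baseline.total_energy_kwh - solution.district_energy_kwh.sum(),
                cfg.valuation_price,
            )
        ),
        "n_constraints": inst.n_constraints,
        "n_variables": inst.n_vars,
    }
    return ScenarioResult(
        config=cfg,
        solution=solution,
        baseline=baseline,
        district_report=district,
        state_report=state,
        national=national,
        nutrition=nutrition,
        coefficients=coeffs,
    )


def support(area: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Boolean support of an allocation (areas above tol hectares)."""
    return np.asarray(area) > tol


def msp_sensitivity(instance: SyntheticInstance, cfg: ScenarioConfig,
                    reductions=(0.1, 0.2, 0.3, 0.4, 0.5),
                    crops: list | None = None,
                    water_yield: WaterYieldTable | None = None) -> pd.DataFrame:
    """Net-unit-revenue sensitivity sweep.

    For each crop, the gross margin (MSP - CP) is reduced one crop at a
    time by each reduction level, the model is re-solved, and the support
    (set of positive areas) is compared with the unperturbed optimum.
    Returns one row per (crop, reduction) with a `support_changed` flag;
    a crop whose support never changes is allocation-stable.
    """
    cfg.validate()
    econ = econ_params(instance, cfg.valuation_price)
    if water_yield is None:
        water_yield = compute_water_yield(instance.climate, instance.crops, cfg.alpha)
    baseline = evaluate_baseline(
        instance.baseline_area, water_yield, econ, instance.suitability,
        instance.districts.eta, nutrients=instance.crops.nutrients,
    )
    eta_s = apply_eta_rule(instance.districts.eta, cfg.scenario)
    coeffs = net_revenue_coefficients(water_yield, econ, instance.suitability, eta_s)
    n_targets = nutrition_targets(instance.config) * cfg.nutrition_scale

    def _solve(margin_scale: np.ndarray) -> AllocationSolution:
        c = type(coeffs)(
            objective=coeffs.gross_margin * margin_scale[:, None]
            - (coeffs.gross_margin - coeffs.objective),
            gross_margin=coeffs.gross_margin * margin_scale[:, None],
            water_m3=coeffs.water_m3,
            energy_kwh=coeffs.energy_kwh,
            mean_yield=coeffs.mean_yield,
            delta=coeffs.delta,
        )
        inst = build_lp(
            c, instance.districts, instance.crops, baseline.production_kg,
            n_targets, cfg.scenario, cfg.lam, cfg.irrigation_cap_override,
        )
        return solve_lp(inst)

    n_c = instance.crops.n_crops
    ref = _solve(np.ones(n_c))
    ref_support = support(ref.area)
    rows = []
    crop_idx = crops if crops is not None else range(n_c)
    for i in crop_idx:
        for r in reductions:
            if not 0.0 <= r < 1.0:
                raise ValueError("reductions must lie in [0, 1)")
            scale = np.ones(n_c)
            scale[i] = 1.0 - r
            sol = _solve(scale)
            rows.append(
                {
                    "crop": instance.crops.names[i],
                    "reduction": r,
                    "objective_inr": sol.objective,
                    "support_changed": bool(
                        np.any(support(sol.area) != ref_support)
                    ),
                }
            )
    out = pd.DataFrame(rows)
    stable = (~out.groupby("crop")["support_changed"].any()).rename("stable")
    return out.merge(stable.reset_index(), on="crop")
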