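"""The national crop-allocation linear program.

Decision variables are the areas a_ij (ha) of crop i in district j, one
variable per suitable (delta_ij = 1) pair. The model maximizes the
expected net national agricultural revenue sum_ij c_ij a_ij subject to

* area:        sum_i a_ij <= TCA_j                     per district
* irrigation:  sum_i w_ij a_ij <= lam * Pbar_j * A_j   per district
               (capped scenario only; w_ij is expected water use, m3/ha,
               and the bound is the renewable-recharge share of mean
               annual rainfall over the net cropped area)
* production:  sum_j ybar_ij a_ij >= Q_i               per crop
* nutrition:   sum_ij c_ni ybar_ij a_ij >= N_n         per nutrient

giving 2 n_d + n_c + n rows under the capped scenario and n_d + n_c + n
under the zero scenario (the irrigation rows are vacuous without
irrigation and are omitted). Solved with HiGHS via scipy.optimize.linprog;
duals and slacks are reported per constraint family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .economics import M3_PER_MM_HA

FEASIBILITY_TOL = 1e-7

FAMILY_UNITS = {
    "area": "INR/ha",
    "irrigation": "INR/m3",
    "production": "INR/kg",
    "nutrition": "INR/unit",
}


class InfeasibleLPError(RuntimeError):
    """Raised when the allocation LP has no feasible point.

    Carries a per-family violation diagnosis (from an elastic relaxation
    that minimizes the total constraint violation).
    """

    def __init__(self, message: str, diagnosis: dict[str, float]):
        super().__init__(message)
        self.diagnosis = diagnosis


@dataclass
class LPInstance:
    """Assembled matrices plus labels for every row and variable.

    All rows are <= rows (>= targets are negated at build time); units are
    ha (area), m3 (water), kg (production), INR (money), so the matrix is
    unit-consistent.
    """

    c: np.ndarray                 # (n_vars,) objective, INR/ha, maximized
    a_ub: sparse.csr_matrix       # (n_rows, n_vars)
    b_ub: np.ndarray              # (n_rows,)
    row_family: np.ndarray        # area | irrigation | production | nutrition
    row_key: np.ndarray           # district / crop / nutrient label
    var_crop: np.ndarray          # crop index per variable
    var_district: np.ndarray      # district index per variable
    var_water_m3: np.ndarray      # expected water use per ha, per variable
    var_energy_kwh: np.ndarray    # expected pumping energy per ha, per variable
    var_yield: np.ndarray         # expected yield per ha, per variable
    shape: tuple                  # (n_crops, n_districts)
    scenario: str = "zero"

    @property
    def n_constraints(self) -> int:
        return self.a_ub.shape[0]

    @property
    def n_vars(self) -> int:
        return self.a_ub.shape[1]


@dataclass
class AllocationSolution:
    """Optimal allocation with duals, slacks and realized use per district."""

    status: str
    area: np.ndarray              # (n_crops, n_districts), ha
    objective: float              # INR
    duals: np.ndarray             # per row, for the maximization problem
    slacks: np.ndarray            # per row, b - A a*
    instance: LPInstance
    district_water_m3: np.ndarray
    district_energy_kwh: np.ndarray
    production_kg: np.ndarray     # expected production per crop
    diagnosis: dict | None = None


def build_lp(coeffs, districts, crops, production_targets, nutrition_targets,
             scenario: str, lam: float = 0.15,
             irrigation_cap_override: np.ndarray | None = None) -> LPInstance:
    """Assemble the LP for one scenario.

    coeffs is a RevenueCoefficients; districts a DistrictAttrs; crops a
    CropParams. production_targets (kg) has one entry per crop and
    nutrition_targets one per nutrient. Under 'zero' the irrigation rows
    are omitted; under 'capped' the bound is lam * Pbar_j * A_j (in m3)
    unless a per-district override (m3) is given.
    """
    if scenario not in ("zero", "capped"):
        raise ValueError("scenario must be 'zero' or 'capped'")
    delta = np.asarray(coeffs.delta)
    n_c, n_d = delta.shape
    var_crop, var_district = np.nonzero(delta)
    n_vars = var_crop.size
    if n_vars == 0:
        raise ValueError("no suitable (crop, district) pairs: empty variable set")

    production_targets = np.asarray(production_targets, dtype=float)
    nutrition_targets = np.asarray(nutrition_targets, dtype=float)
    n_nut = nutrition_targets.size
    tca = districts.table["tca_ha"].to_numpy()
    if np.any(tca < 0) or np.any(production_targets < 0) or np.any(nutrition_targets < 0):
        raise ValueError("constraint bounds must be non-negative")

    c = coeffs.objective[var_crop, var_district]
    w = coeffs.water_m3[var_crop, var_district]
    e = coeffs.energy_kwh[var_crop, var_district]
    y = coeffs.mean_yield[var_crop, var_district]
    nutrients = np.asarray(crops.nutrients, dtype=float)  # (n_nut, n_crops)

    rows, cols, vals = [], [], []
    b, family, key = [], [], []
    row = 0

    # Area rows: one per district, coefficient 1 on its variables.
    rows.extend(var_district.tolist())
    cols.extend(range(n_vars))
    vals.extend(np.ones(n_vars).tolist())
    b.extend(tca.tolist())
    family.extend(["area"] * n_d)
    key.extend(districts.district_id.tolist())
    row = n_d

    if scenario == "capped":
        if irrigation_cap_override is not None:
            cap = np.asarray(irrigation_cap_override, dtype=float)
            if cap.shape != (n_d,):
                raise ValueError("irrigation cap override must have one entry per district")
        else:
            cap = (
                lam
                * districts.table["mean_annual_rain_mm"].to_numpy()
                * districts.table["net_cropped_ha"].to_numpy()
                * M3_PER_MM_HA
            )
        if np.any(cap < 0):
            raise ValueError("irrigation bounds must be non-negative")
        rows.extend((row + var_district).tolist())
        cols.extend(range(n_vars))
        vals.extend(w.tolist())
        b.extend(cap.tolist())
        family.extend(["irrigation"] * n_d)
        key.extend(districts.district_id.tolist())
        row += n_d

    # Production rows: sum_j ybar a >= Q_i, negated to <=.
    rows.extend((row + var_crop).tolist())
    cols.extend(range(n_vars))
    vals.extend((-y).tolist())
    b.extend((-production_targets).tolist())
    family.extend(["production"] * n_c)
    key.extend(list(crops.names))
    row += n_c

    # Nutrition rows: sum_ij c_ni ybar a >= N_n, negated to <=.
    for n in range(n_nut):
        rows.extend([row + n] * n_vars)
        cols.extend(range(n_vars))
        vals.extend((-nutrients[n, var_crop] * y).tolist())
        b.append(-nutrition_targets[n])
        family.append("nutrition")
        key.append(crops.nutrient_names[n] if n < len(crops.nutrient_names) else f"nutrient_{n}")
    row += n_nut

    a_ub = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(row, n_vars)
    )
    return LPInstance(
        c=c,
        a_ub=a_ub,
        b_ub=np.asarray(b, dtype=float),
        row_family=np.asarray(family),
        row_key=np.asarray(key),
        var_crop=var_crop,
        var_district=var_district,
        var_water_m3=w,
        var_energy_kwh=e,
        var_yield=y,
        shape=(n_c, n_d),
        scenario=scenario,
    )


def diagnose_infeasibility(instance: LPInstance) -> dict[str, float]:
    """Minimum total violation per constraint family (elastic relaxation).

    Adds a non-negative violation variable to every row and minimizes the
    total violation measured relative to each row's bound (families carry
    different units, so raw row units are not comparable); the families
    with positive violation name what cannot be met.
    """
    m, n = instance.a_ub.shape
    scale = np.maximum(1.0, np.abs(instance.b_ub))
    a_el = sparse.hstack([instance.a_ub, -sparse.identity(m, format="csr")])
    c_el = np.concatenate([np.zeros(n), 1.0 / scale])
    res = optimize.linprog(c_el, A_ub=a_el, b_ub=instance.b_ub, method="highs")
    if not res.success:  # pragma: no cover - elastic LP is always feasible
        raise RuntimeError("elastic relaxation failed: " + res.message)
    viol = res.x[n:] / scale
    out: dict[str, float] = {}
    for fam in np.unique(instance.row_family):
        out[str(fam)] = float(viol[instance.row_family == fam].sum())
    return out


def solve_lp(instance: LPInstance, tolerance: float = FEASIBILITY_TOL,
             method: str = "highs") -> AllocationSolution:
    """Maximize the instance; return allocation, duals and slacks.

    Raises InfeasibleLPError with a per-family diagnosis when no feasible
    allocation exists. Duals are reported for the maximization problem:
    the marginal increase of the optimum per unit increase of a row's
    right-hand side (>= 0 for all <= rows).
    """
    res = optimize.linprog(
        -instance.c,
        A_ub=instance.a_ub,
        b_ub=instance.b_ub,
        bounds=(0, None),
        method=method,
    )
    if res.status == 2:
        diag = diagnose_infeasibility(instance)
        worst = max(diag, key=diag.get)
        raise InfeasibleLPError(
            "allocation LP infeasible; largest violation in the "
            f"'{worst}' constraint family ({diag[worst]:.3g} relative); "
            f"full diagnosis: {diag}",
            diag,
        )
    if res.status != 0:
        raise RuntimeError(f"LP solve failed (status {res.status}): {res.message}")

    x = res.x
    n_c, n_d = instance.shape
    area = np.zeros((n_c, n_d))
    area[instance.var_crop, instance.var_district] = x
    slacks = instance.b_ub - instance.a_ub @ x
    if slacks.min() < -tolerance * max(1.0, np.abs(instance.b_ub).max()):
        raise RuntimeError("solver returned an infeasible point")
    duals = -res.ineqlin.marginals  # max problem: dO/db >= 0 for <= rows

    water = np.bincount(
        instance.var_district, weights=instance.var_water_m3 * x, minlength=n_d
    )
    energy = np.bincount(
        instance.var_district, weights=instance.var_energy_kwh * x, minlength=n_d
    )
    production = np.bincount(
        instance.var_crop, weights=instance.var_yield * x, minlength=n_c
    )
    return AllocationSolution(
        status="optimal",
        area=area,
        objective=float(instance.c @ x),
        duals=duals,
        slacks=slacks,
        instance=instance,
        district_water_m3=water,
        district_energy_kwh=energy,
        production_kg=production,
    )


def shadow_price_report(solution: AllocationSolution,
                        slack_tol: float = 1e-6) -> pd.DataFrame:
    """Duals per constraint with units, verified for complementary slackness.

    For production/nutrition rows (built as negated >= rows) the reported
    shadow price is the marginal cost of raising the target by one unit.
    """
    if solution.status != "optimal":
        raise ValueError("shadow prices are defined only for optimal solutions")
    inst = solution.instance
    scale = np.maximum(1.0, np.abs(inst.b_ub))
    comp = np.abs(solution.duals) * np.abs(solution.slacks) / scale
    if np.any(comp > 1e-4 * np.maximum(1.0, np.abs(solution.duals))):
        raise RuntimeError("complementary slackness violated in reported duals")
    return pd.DataFrame(
        {
            "family": inst.row_family,
            "key": inst.row_key,
            "unit": [FAMILY_UNITS[f] for f in inst.row_family],
            "dual": solution.duals,
            "slack": solution.slacks,
            "binding": np.abs(solution.slacks) <= slack_tol * scale,
        }
    )


def verify_optimality(instance: LPInstance, solution: AllocationSolution,
                      rtol: float = 1e-6) -> bool:
    """Solver-independent optimality certificate via LP duality.

    Checks (i) primal feasibility, (ii) dual feasibility
    A^T y >= c with y >= 0 (reduced costs non-positive wherever x could
    increase), and (iii) strong duality b^T y == c^T x. Any vertex failing
    one of these is not optimal, whatever solver produced it.
    """
    x = solution.area[instance.var_crop, instance.var_district]
    y = solution.duals
    b_scale = max(1.0, float(np.abs(instance.b_ub).max()))
    primal_ok = (instance.a_ub @ x <= instance.b_ub + rtol * b_scale).all() and (
        x >= -rtol
    ).all()
    reduced = instance.c - instance.a_ub.T @ y
    dual_ok = (y >= -rtol).all() and (
        reduced <= rtol * max(1.0, float(np.abs(instance.c).max()))
    ).all()
    gap = abs(float(instance.b_ub @ y) - float(instance.c @ x))
    duality_ok = gap <= rtol * max(1.0, abs(float(instance.c @ x)))
    return bool(primal_ok and dual_ok and duality_ok)


def to_mps(instance: LPInstance, name: str = "CROPALLOC") -> str:
    """Serialize the instance as a free-format MPS string (OBJSENSE MAX)."""
    lines = [f"NAME          {name}", "OBJSENSE", "    MAX", "ROWS", " N  OBJ"]
    row_names = [f"R{k:06d}" for k in range(instance.n_constraints)]
    for rn in row_names:
        lines.append(f" L  {rn}")
    lines.append("COLUMNS")
    a_csc = instance.a_ub.tocsc()
    for v in range(instance.n_vars):
        col = f"A{v:06d}"
        lines.append(f"    {col}  OBJ  {instance.c[v]:.12g}")
        start, end = a_csc.indptr[v], a_csc.indptr[v + 1]
        for r, val in zip(a_csc.indices[start:end], a_csc.data[start:end]):
            lines.append(f"    {col}  {row_names[r]}  {val:.12g}")
    lines.append("RHS")
    for rn, bv in zip(row_names, instance.b_ub):
        lines.append(f"    RHS  {rn}  {bv:.12g}")
    lines.append("BOUNDS")  # default: x >= 0, no upper bound
    lines.append("ENDATA")
    return "\n".join(lines) + "\n"


def constraint_count(n_districts: int, n_crops: int, n_nutrients: int,
                     scenario: str) -> int:
    """Row count of the assembled model: 2 n_d + n_c + n under 'capped',
    n_d + n_c + n under 'zero'."""
    if scenario == "capped":
        return 2 * n_districts + n_crops + n_nutrients
    if scenario == "zero":
        return n_districts + n_crops + n_nutrients
    raise ValueError("scenario must be 'zero' or 'capped'")
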