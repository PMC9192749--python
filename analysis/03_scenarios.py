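"""Optimize the national allocation under both irrigation scenarios.

Solves the "Irrigation Zero" (rainfed) and "Irrigation Capped" linear
programs against the baseline cropping pattern, and writes per scenario:
the optimal allocation, district and state comparison reports (income
change, water and energy saved/used, opportunity cost), the nutrition
adequacy table, the shadow-price table and a national summary. Output goes
to results/scenario_zero/ and results/scenario_capped/.
"""

import argparse
from pathlib import Path

from cropalloc import (
    GeneratorConfig,
    ScenarioConfig,
    compute_water_yield,
    generate_instance,
    run_scenario,
    shadow_price_report,
)
from cropalloc.io import write_scenario_result


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--districts", type=int, default=60)
    p.add_argument("--years", type=int, default=40)
    p.add_argument("--states", type=int, default=12)
    p.add_argument("--seed", type=int, default=42)
    p.add_argument("--out", type=Path, default=Path("results"))
    args = p.parse_args()

    config = GeneratorConfig(
        n_districts=args.districts, n_years=args.years,
        n_states=args.states, random_seed=args.seed,
    )
    instance = generate_instance(config)
    water_yield = compute_water_yield(instance.climate, instance.crops)

    for scenario in ("zero", "capped"):
        res = run_scenario(instance, ScenarioConfig(scenario=scenario),
                           water_yield=water_yield)
        outdir = args.out / f"scenario_{scenario}"
        write_scenario_result(res, outdir)
        shadow_price_report(res.solution).to_csv(
            outdir / "shadow_prices.tsv", sep="\t", index=False
        )
        n = res.national
        gain_pct = 100 * n["income_gain_inr"] / n["revenue_current_inr"]
        print(f"[{scenario}] {n['n_constraints']} constraints, "
              f"{n['n_variables']} variables")
        print(f"  revenue: {n['revenue_current_inr'] / 1e12:.3f} -> "
              f"{n['revenue_optimal_inr'] / 1e12:.3f} trillion INR "
              f"({gain_pct:+.1f}%)")
        print(f"  irrigation water: {n['water_current_m3'] / 1e9:.1f} -> "
              f"{n['water_optimal_m3'] / 1e9:.1f} billion m3")
        print(f"  pumping energy: {n['energy_current_kwh'] / 1e6:.0f} -> "
              f"{n['energy_optimal_kwh'] / 1e6:.0f} GWh")
        cats = res.district_report["income_category"].value_counts().to_dict()
        print(f"  district income categories: {cats}")
        print(f"  outputs in {outdir}/")


if __name__ == "__main__":
    main()
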