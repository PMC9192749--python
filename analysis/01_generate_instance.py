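"""Generate a synthetic national instance and write its tables.

A desk-scale instance (default 60 districts, 40 monsoon seasons) stands in
for the national data: district land/groundwater attributes, the 12-crop
Kharif roster, crop suitability from cultivation history, the baseline
("current") allocation, and per-district daily climate. The tables land in
results/instance/.
"""

import argparse
from pathlib import Path

from cropalloc import GeneratorConfig, generate_instance
from cropalloc.io import write_instance


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--districts", type=int, default=60)
    p.add_argument("--years", type=int, default=40)
    p.add_argument("--states", type=int, default=12)
    p.add_argument("--seed", type=int, default=42)
    p.add_argument("--out", type=Path, default=Path("results/instance"))
    p.add_argument("--climate", action="store_true",
                   help="also write the (large) long-format climate table")
    args = p.parse_args()

    config = GeneratorConfig(
        n_districts=args.districts, n_years=args.years,
        n_states=args.states, random_seed=args.seed,
    )
    instance = generate_instance(config)
    write_instance(instance, args.out, climate=args.climate)

    clim = instance.climate
    inside = clim.season_rain().sum() / clim.rain.sum()
    print(f"instance: {config.n_districts} districts x {config.n_crops} crops "
          f"x {config.n_years} years (seed {config.random_seed})")
    print(f"mean annual rainfall {clim.annual_totals().mean():.0f} mm, "
          f"{inside:.0%} of it inside the {config.n_season_days}-day Kharif window")
    print(f"suitable (crop, district) pairs: {instance.suitability.sum()} "
          f"of {instance.suitability.size}")
    print(f"baseline cropped area: {instance.baseline_area.sum() / 1e6:.2f} Mha "
          f"of {instance.districts.table.tca_ha.sum() / 1e6:.2f} Mha available")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
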