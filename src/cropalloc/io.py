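"""Delimited-text writers for instances and scenario results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_instance(instance, outdir: str | Path, climate: bool = False) -> None:
    """Write an instance's tables as TSV under `outdir`.

    districts.tsv, crops.tsv, kc.tsv, nutrients.tsv, suitability.tsv,
    baseline_allocation.tsv, prices.tsv and generator.yaml; the (large)
    long-format climate table only when `climate=True`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sep = "\t"
    instance.districts.table.to_csv(out / "districts.tsv", sep=sep, index=False)
    instance.crops.table.to_csv(out / "crops.tsv", sep=sep, index=False)

    crops = instance.crops.names
    districts = instance.districts.district_id
    pd.DataFrame(instance.crops.kc, index=pd.Index(crops, name="crop")).to_csv(
        out / "kc.tsv", sep=sep
    )
    pd.DataFrame(
        instance.crops.nutrients,
        index=pd.Index(instance.crops.nutrient_names, name="nutrient"),
        columns=crops,
    ).to_csv(out / "nutrients.tsv", sep=sep)

    def _cd(matrix, name):
        pd.DataFrame(matrix, index=pd.Index(crops, name="crop"), columns=districts).to_csv(
            out / name, sep=sep
        )

    _cd(instance.suitability, "suitability.tsv")
    _cd(instance.baseline_area, "baseline_allocation.tsv")
    _cd(instance.districts.eta, "irrigation_potential.tsv")
    _cd(instance.msp, "msp.tsv")
    _cd(instance.cp, "cost_of_production.tsv")
    instance.config.to_yaml(out / "generator.yaml")
    if climate:
        instance.climate.to_frame().to_csv(out / "climate.tsv", sep=sep, index=False)


def write_scenario_result(result, outdir: str | Path) -> None:
    """Write one scenario's allocation, reports and national summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    inst = result.solution.instance
    alloc = pd.DataFrame(
        {
            "crop_index": inst.var_crop,
            "district_index": inst.var_district,
            "area_ha": result.solution.area[inst.var_crop, inst.var_district],
        }
    )
    alloc.to_csv(out / "allocation.tsv", sep="\t", index=False)
    result.district_report.to_csv(out / "district_report.tsv", sep="\t", index=False)
    result.state_report.to_csv(out / "state_report.tsv", sep="\t", index=False)
    result.nutrition.to_csv(out / "nutrition.tsv", sep="\t", index=False)
    national = {
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in result.national.items()
    }
    (out / "national_summary.yaml").write_text(yaml.safe_dump(national, sort_keys=False))
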