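"""Hand-assembled toy LP inputs shared across test modules."""

import numpy as np
import pandas as pd

from cropalloc.economics import RevenueCoefficients
from cropalloc.synthetic import CropParams, DistrictAttrs


def toy_problem(objective, tca, water=None, mean_yield=None, energy=None,
                nutrients=None, rain=None, net_cropped=None):
    """Assemble DistrictAttrs / CropParams / RevenueCoefficients stand-ins
    from plain arrays for direct LP tests."""
    objective = np.asarray(objective, dtype=float)
    n_c, n_d = objective.shape
    if mean_yield is None:
        mean_yield = np.ones_like(objective)
    if water is None:
        water = np.zeros_like(objective)
    if energy is None:
        energy = np.zeros_like(objective)
    if nutrients is None:
        nutrients = np.ones((1, n_c))
    districts = DistrictAttrs(
        table=pd.DataFrame(
            {
                "district": [f"D{j}" for j in range(n_d)],
                "state": ["S0"] * n_d,
                "latitude": 20.0,
                "mean_annual_rain_mm": rain if rain is not None else np.full(n_d, 1000.0),
                "tca_ha": np.asarray(tca, dtype=float),
                "net_cropped_ha": net_cropped if net_cropped is not None else np.asarray(tca, dtype=float),
                "depth_m": 10.0,
                "tariff_inr_kwh": 3.0,
            }
        ),
        eta=np.zeros((n_c, n_d)),
    )
    crops = CropParams(
        table=pd.DataFrame(
            {
                "crop": [f"C{i}" for i in range(n_c)],
                "group": "g",
                "potential_yield_kg_ha": 1000.0,
                "msp_inr_kg": 20.0,
                "cp_inr_kg": 10.0,
                "beta": 0.75,
            }
        ),
        kc=np.ones((n_c, 10)),
        nutrients=np.asarray(nutrients, dtype=float),
        nutrient_names=tuple(f"n{k}" for k in range(np.asarray(nutrients).shape[0])),
    )
    coeffs = RevenueCoefficients(
        objective=objective,
        gross_margin=objective.copy(),
        water_m3=np.asarray(water, dtype=float),
        energy_kwh=np.asarray(energy, dtype=float),
        mean_yield=np.asarray(mean_yield, dtype=float),
        delta=np.ones((n_c, n_d), dtype=int),
    )
    return coeffs, districts, crops
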