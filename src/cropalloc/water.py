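"""Daily crop water accounting and deficit-driven yield.

The season-scale quantities per (crop, district, year) are:

* effective supply        S_d   = alpha * P_d
* crop demand             D_d   = kc_d * ET0_d
* crop water requirement  CWR   = sum_d D_d
* accumulated deficit     def_d = max(0, def_{d-1} + D_d - S_d), def_0 = 0
* seasonal deficit        SD    = max_d def_d
* yield                   Y     = (1 - (1 - eta) * SD / CWR) * PY

The deficit recursion keys on the within-season timing of rainfall: two
years with identical totals but different daily distributions generally
produce different SD. Surplus supply on a wet day draws the accumulated
deficit down but never banks a credit (the max(0, .) clamp); there is no
soil-moisture carryover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import climate as _climate

DEFAULT_ALPHA = 0.7  # usable fraction of daily rainfall


def effective_supply(rain, alpha: float = DEFAULT_ALPHA):
    """Water supply available to the crop from daily rainfall: S = alpha * P."""
    rain = np.asarray(rain, dtype=float)
    if np.any(rain < 0):
        raise ValueError("rainfall must be non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * rain


def daily_demand(kc, et0):
    """Daily crop water demand D = kc * ET0 (mm/day)."""
    return np.asarray(kc, dtype=float) * np.asarray(et0, dtype=float)


def seasonal_cwr(demand, n_season_days: int | None = None):
    """Seasonal crop water requirement: sum of daily demand along the last axis."""
    demand = np.asarray(demand, dtype=float)
    if n_season_days is not None and demand.shape[-1] != n_season_days:
        raise ValueError(
            f"demand series has length {demand.shape[-1]}, expected {n_season_days}"
        )
    return demand.sum(axis=-1)


def seasonal_deficit(demand, supply):
    """Accumulated-deficit path and seasonal crop water deficit.

    Applies the clamped recursion day by day along the last axis and takes
    the running maximum. Returns (path, SD); 0 <= SD <= CWR always holds.
    """
    demand = np.asarray(demand, dtype=float)
    supply = np.asarray(supply, dtype=float)
    if demand.shape != supply.shape:
        raise ValueError("demand and supply must have identical shapes")
    path = np.empty_like(demand)
    deficit = np.zeros(demand.shape[:-1])
    sd = np.zeros(demand.shape[:-1])
    for d in range(demand.shape[-1]):
        deficit = np.maximum(0.0, deficit + demand[..., d] - supply[..., d])
        path[..., d] = deficit
        sd = np.maximum(sd, deficit)
    return path, sd


def estimate_yield(sd, cwr, eta, potential_yield):
    """Yield under unmet water deficit: Y = (1 - (1-eta) * SD/CWR) * PY.

    With full irrigation potential (eta = 1) yield reaches PY regardless
    of the deficit. CWR = 0 (no demand at all) is treated as unstressed,
    Y = PY. Output is bounded: eta * PY <= Y <= PY.
    """
    sd = np.asarray(sd, dtype=float)
    cwr = np.asarray(cwr, dtype=float)
    eta = np.asarray(eta, dtype=float)
    py = np.asarray(potential_yield, dtype=float)
    if np.any(sd < -1e-9) or np.any(sd > cwr + 1e-6 * np.maximum(cwr, 1.0)):
        raise ValueError("SD must lie in [0, CWR]")
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("eta must lie in [0, 1]")
    if np.any(py <= 0):
        raise ValueError("potential yield must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        stress = np.where(cwr > 0, sd / np.where(cwr > 0, cwr, 1.0), 0.0)
    return (1.0 - (1.0 - eta) * stress) * py


@dataclass
class WaterYieldTable:
    """Season-scale water and yield quantities per (crop, district, year).

    cwr and sd have shape (n_crops, n_districts, n_years); they do not
    depend on the irrigation scenario, so yields for any eta are derived
    from them via :meth:`yields`.
    """

    crop: np.ndarray
    district: np.ndarray
    cwr: np.ndarray
    sd: np.ndarray
    potential_yield: np.ndarray   # (n_crops,)

    def yields(self, eta: np.ndarray) -> np.ndarray:
        """Yields (kg/ha) for irrigation potential eta of shape (n_crops, n_districts)."""
        return estimate_yield(
            self.sd, self.cwr, np.asarray(eta)[:, :, None],
            self.potential_yield[:, None, None],
        )

    def mean_sd(self) -> np.ndarray:
        """E_t[SD] per (crop, district), mm."""
        return self.sd.mean(axis=2)

    def mean_yield(self, eta: np.ndarray) -> np.ndarray:
        """E_t[Y] per (crop, district), kg/ha."""
        return self.yields(eta).mean(axis=2)


def compute_water_yield(climate_series, crops, alpha: float = DEFAULT_ALPHA,
                        et0: np.ndarray | None = None) -> WaterYieldTable:
    """Run the daily water balance for every crop, district and year.

    The day loop carries only (n_crops, n_districts, n_years) state, so a
    national-scale instance (12 x 586 x 109) stays well within memory.
    """
    if et0 is None:
        et0 = _climate.season_et0(climate_series)
    supply = effective_supply(climate_series.season_rain(), alpha)
    kc = crops.kc
    n_c = kc.shape[0]
    n_d, n_y, n_s = et0.shape
    if kc.shape[1] != n_s:
        raise ValueError(
            f"kc curves have length {kc.shape[1]}, season has {n_s} days"
        )

    cwr = np.zeros((n_c, n_d, n_y))
    deficit = np.zeros((n_c, n_d, n_y))
    sd = np.zeros((n_c, n_d, n_y))
    for d in range(n_s):
        demand_d = kc[:, d][:, None, None] * et0[None, :, :, d]
        cwr += demand_d
        deficit = np.maximum(0.0, deficit + demand_d - supply[None, :, :, d])
        sd = np.maximum(sd, deficit)

    return WaterYieldTable(
        crop=np.arange(n_c),
        district=climate_series.district_id,
        cwr=cwr,
        sd=sd,
        potential_yield=crops.potential_yield,
    )
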