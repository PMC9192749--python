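"""Revenue, irrigation-water, pumping-energy and cost coefficients.

The objective of the national allocation model is, per hectare of crop i
in district j,

    c_ij = E_t[(MSP_ij - CP_ij) * Y_ijt]  -  CI_j * E_t[energy per ha],

where the pumping energy lifts the irrigation water (the supplied fraction
eta of the seasonal deficit, inflated by the application-efficiency factor
1/beta) from the district's depth-to-groundwater h_j:

    energy (J) = mass (kg) * g * h_j / mu_p,   mass = psi1 * SD * area,

with psi1 = 1e4 kg per mm.ha (1 mm over 1 ha is 10 m3 = 10,000 kg) and
psi2 = 1/3,600,000 kWh per J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAVITY = 9.81                    # m s-2
PSI1_KG_PER_MM_HA = 1.0e4         # mm.ha -> kg of water
PSI2_KWH_PER_J = 1.0 / 3_600_000  # J -> kWh
M3_PER_MM_HA = 10.0               # 1 mm over 1 ha = 10 m3
DEFAULT_PUMP_EFFICIENCY = 0.3
DEFAULT_VALUATION_PRICE = 7.0     # INR/kWh, residential tariff


@dataclass
class EconParams:
    """Economic constants and district/crop price-cost tables.

    msp and cp have shape (n_crops, n_districts), INR/kg. tariff and
    depth_m have shape (n_districts,). beta (n_crops,) is the irrigation
    application efficiency (0.30 for flood-irrigated rice, 0.75 otherwise).
    """

    msp: np.ndarray
    cp: np.ndarray
    tariff: np.ndarray
    beta: np.ndarray
    depth_m: np.ndarray
    mu_p: float = DEFAULT_PUMP_EFFICIENCY
    g: float = GRAVITY
    psi1: float = PSI1_KG_PER_MM_HA
    psi2: float = PSI2_KWH_PER_J
    valuation_price: float = DEFAULT_VALUATION_PRICE

    def validate(self) -> None:
        if np.any(self.beta <= 0) or np.any(self.beta > 1):
            raise ValueError("beta must lie in (0, 1]")
        if not (0.0 < self.mu_p <= 1.0):
            raise ValueError("pump efficiency must lie in (0, 1]")
        if np.any(self.depth_m < 0):
            raise ValueError("depth to groundwater must be >= 0")


def irrigation_volume(sd_mm, eta, beta, area_ha):
    """Irrigation water pumped (m3) for a seasonal deficit SD over an area.

    V = (1/beta) * eta * SD * area * 10; the supplied share eta of the
    deficit, inflated by application losses.
    """
    sd_mm = np.asarray(sd_mm, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    if np.any(sd_mm < 0) or np.any(np.asarray(area_ha) < 0):
        raise ValueError("SD and area must be non-negative")
    return (1.0 / beta) * np.asarray(eta, dtype=float) * sd_mm * np.asarray(
        area_ha, dtype=float
    ) * M3_PER_MM_HA


def pumping_energy(volume_m3, depth_m, mu_p: float = DEFAULT_PUMP_EFFICIENCY,
                   g: float = GRAVITY):
    """Electricity (kWh) to lift a water volume from depth_m.

    E = V * 1000 kg/m3 * g * h / mu_p, converted J -> kWh.
    """
    if np.any(np.asarray(mu_p) <= 0):
        raise ValueError("pump efficiency must be positive")
    volume_m3 = np.asarray(volume_m3, dtype=float)
    if np.any(volume_m3 < 0):
        raise ValueError("volume must be non-negative")
    joules = volume_m3 * 1000.0 * g * np.asarray(depth_m, dtype=float) / mu_p
    return joules * PSI2_KWH_PER_J


def opportunity_cost(energy_kwh, price: float = DEFAULT_VALUATION_PRICE):
    """Monetary value (INR) of electricity at the valuation price (INR/kWh)."""
    if price <= 0:
        raise ValueError("price must be positive")
    return np.asarray(energy_kwh, dtype=float) * price


@dataclass
class RevenueCoefficients:
    """Per-hectare coefficients of the allocation model, per (crop, district).

    objective     INR/ha  : expected gross margin minus irrigation cost
    gross_margin  INR/ha  : E_t[(MSP - CP) * Y]
    water_m3      m3/ha   : E_t[(1/beta) * eta * SD] * 10
    energy_kwh    kWh/ha  : pumping energy for water_m3 from district depth
    mean_yield    kg/ha   : E_t[Y]
    All are zero where the crop is unsuitable (delta = 0).
    """

    objective: np.ndarray
    gross_margin: np.ndarray
    water_m3: np.ndarray
    energy_kwh: np.ndarray
    mean_yield: np.ndarray
    delta: np.ndarray


def net_revenue_coefficients(water_yield, econ: EconParams, delta: np.ndarray,
                             eta: np.ndarray) -> RevenueCoefficients:
    """Expected per-hectare objective, water, energy and yield coefficients.

    The expectation is the unweighted mean over the simulated years. The
    coefficients are linear in area, so the national objective for an
    allocation a is sum_ij c_ij * a_ij.
    """
    econ.validate()
    eta = np.asarray(eta, dtype=float)
    delta = np.asarray(delta)
    mean_yield = water_yield.mean_yield(eta)                       # kg/ha
    gross_margin = (econ.msp - econ.cp) * mean_yield               # INR/ha
    water = irrigation_volume(
        water_yield.mean_sd(), eta, econ.beta[:, None], 1.0
    )                                                              # m3/ha
    energy = pumping_energy(water, econ.depth_m[None, :], econ.mu_p, econ.g)
    objective = gross_margin - econ.tariff[None, :] * energy
    mask = delta.astype(float)
    return RevenueCoefficients(
        objective=objective * mask,
        gross_margin=gross_margin * mask,
        water_m3=water * mask,
        energy_kwh=energy * mask,
        mean_yield=mean_yield * mask,
        delta=delta,
    )
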