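"""Run configuration for the synthetic-instance generator and the scenario pipeline.

Defaults correspond to the national Kharif-season study conditions: 586
districts, 12 procured crops, 109 monsoon seasons of daily weather, a
120-day growing season starting June 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

DAYS_PER_YEAR = 365


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-instance generator.

    Attributes
    ----------
    n_districts, n_crops, n_years : int
        Problem dimensions. Crops are drawn from the built-in 12-crop
        Kharif roster (rice, other cereals, pulses, oilseeds).
    n_season_days : int
        Length of the Kharif growing season (days); default 120.
    season_start_doy : int
        Day-of-year the season starts (June 1 -> 152 in non-leap years).
    history_years : int
        Length of the cultivation history used for crop suitability.
    suitability_threshold : int
        A crop is suitable in a district if it was cultivated at least
        this many times in the history (default 5).
    latitude_range : (float, float)
        District latitudes are drawn uniformly in this range (degrees N).
    annual_rain_range : (float, float)
        Per-district mean annual rainfall drawn uniformly in this range (mm).
    rain_cv : float
        Target interannual coefficient of variation of annual rainfall.
    wet_prob_monsoon, wet_prob_dry : float
        Marginal wet-day probability inside / outside the monsoon window.
    markov_persistence : float
        Excess probability of a wet day following a wet day (first-order
        occurrence chain): p11 = pi + persistence, clipped to <= 0.98.
    gamma_shape : float
        Shape of the gamma distribution of wet-day rainfall amounts.
    temp_mean_start, temp_mean_end : float
        Climatological mean daily temperature at season start / end (degC);
        the in-season climatology interpolates linearly.
    temp_sd : float
        Day-to-day standard deviation around the climatology (degC),
        applied to min, mean and max temperature alike.
    diurnal_half_range : float
        Climatological (tmax - tmean) = (tmean - tmin) half range (degC).
    n_states : int
        Districts are grouped into this many states for state-level
        parameters (cost of cultivation, irrigation development).
    baseline_area_fraction : float
        Fraction of each district's total cropped area occupied by the
        baseline ("current") allocation.
    tariff_inr_per_kwh : float
        Flat agricultural electricity tariff CI_j (INR/kWh).
    population_per_district : float
        Population served per district; the national total for the
        nutrition targets is this times n_districts (about 1.3 billion at
        the full 586-district scale).
    kharif_coverage : float
        Fraction of annual national nutrient needs expected from these
        Kharif crops (the remainder comes from the Rabi season and
        non-PDS foods).
    random_seed : int
        Seed for all generator randomness; fixed seed gives identical output.
    """

    n_districts: int = 586
    n_crops: int = 12
    n_years: int = 109
    n_season_days: int = 120
    season_start_doy: int = 152
    history_years: int = 20
    suitability_threshold: int = 5
    latitude_range: tuple[float, float] = (8.0, 34.0)
    annual_rain_range: tuple[float, float] = (450.0, 1600.0)
    rain_cv: float = 0.18
    wet_prob_monsoon: float = 0.55
    wet_prob_dry: float = 0.03
    markov_persistence: float = 0.25
    gamma_shape: float = 0.8
    temp_mean_start: float = 31.0
    temp_mean_end: float = 27.0
    temp_sd: float = 1.5
    diurnal_half_range: float = 6.0
    n_states: int = 32
    baseline_area_fraction: float = 0.85
    tariff_inr_per_kwh: float = 3.0
    population_per_district: float = 2.22e6
    kharif_coverage: float = 0.25
    random_seed: int = 0

    @property
    def season_window(self) -> tuple[int, int]:
        """(first, last) day-of-year of the growing season, inclusive."""
        start = self.season_start_doy
        return (start, start + self.n_season_days - 1)

    def validate(self) -> None:
        if self.n_districts < 1 or self.n_crops < 1 or self.n_years < 1:
            raise ValueError("n_districts, n_crops and n_years must be >= 1")
        if self.n_season_days < 1:
            raise ValueError("n_season_days must be >= 1")
        start, end = self.season_window
        if not (1 <= start <= DAYS_PER_YEAR) or end > DAYS_PER_YEAR:
            raise ValueError(
                f"season window ({start}, {end}) must lie within 1..{DAYS_PER_YEAR}"
            )
        if not (0.0 <= self.wet_prob_dry <= 1.0 and 0.0 <= self.wet_prob_monsoon <= 1.0):
            raise ValueError("wet-day probabilities must lie in [0, 1]")
        if self.temp_sd < 0:
            raise ValueError("temperature standard deviation must be >= 0")
        if self.rain_cv < 0:
            raise ValueError("rainfall CV must be >= 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if not (0.0 < self.baseline_area_fraction <= 1.0):
            raise ValueError("baseline_area_fraction must lie in (0, 1]")
        if self.suitability_threshold < 1:
            raise ValueError("suitability threshold must be >= 1")
        lo, hi = self.latitude_range
        if not (-90 <= lo <= hi <= 90):
            raise ValueError("latitude range must be ordered and within [-90, 90]")

    def wet_prob_by_doy(self) -> np.ndarray:
        """Marginal wet-day probability for each day of year (length 365)."""
        p = np.full(DAYS_PER_YEAR, self.wet_prob_dry)
        start, end = self.season_window
        p[start - 1 : end] = self.wet_prob_monsoon
        return p

    def temperature_climatology(self) -> dict[str, np.ndarray]:
        """Per season-day climatological mean and sd of tmin/tmean/tmax."""
        frac = np.linspace(0.0, 1.0, self.n_season_days)
        tmean = self.temp_mean_start + (self.temp_mean_end - self.temp_mean_start) * frac
        sd = np.full(self.n_season_days, self.temp_sd)
        return {
            "tmin_mean": tmean - self.diurnal_half_range,
            "tmean_mean": tmean,
            "tmax_mean": tmean + self.diurnal_half_range,
            "tmin_sd": sd,
            "tmean_sd": sd.copy(),
            "tmax_sd": sd.copy(),
        }

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["latitude_range"] = list(self.latitude_range)
        d["annual_rain_range"] = list(self.annual_rain_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("latitude_range", "annual_rain_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Income-change map categories, in trillion INR, half-open [lo, hi).
DEFAULT_INCOME_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("negative", -0.03, -0.01),
    ("neutral", -0.01, 0.01),
    ("positive", 0.01, 0.03),
)


@dataclass
class ScenarioConfig:
    """Settings of one optimization scenario.

    scenario 'zero' removes irrigation everywhere (eta = 0); 'capped'
    raises every crop's irrigation potential in a district to the
    district maximum and enforces the renewable-groundwater cap.
    """

    scenario: str = "zero"
    lam: float = 0.15                 # renewable fraction of mean annual rainfall
    alpha: float = 0.7                # usable fraction of daily rainfall
    valuation_price: float = 7.0      # INR/kWh for the energy opportunity cost
    income_categories: tuple = DEFAULT_INCOME_CATEGORIES
    nutrition_scale: float = 1.0      # multiplier on the nutrition targets
    irrigation_cap_override: np.ndarray | None = None  # per-district m3 cap
    production_targets_override: np.ndarray | None = None  # per-crop kg

    def validate(self) -> None:
        if self.scenario not in ("zero", "capped"):
            raise ValueError("scenario must be 'zero' or 'capped'")
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.alpha <= 1.0):
            raise ValueError("lam and alpha must lie in [0, 1]")
        bounds = [b for _, lo, hi in self.income_categories for b in (lo, hi)]
        if bounds != sorted(bounds):
            raise ValueError("income category bounds must be ordered")
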