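"""Synthetic national Kharif instances: climate, districts, crops, baseline.

Generates self-contained problem instances with the statistical structure
the analysis assumes: monsoonal daily rainfall (first-order two-state
occurrence chain + gamma amounts, concentrated June-September), daily
temperature sampled around a day-of-year climatology, district land/water
attributes, a 12-crop Kharif roster with stage-wise crop coefficients,
cultivation histories that define crop suitability, and a baseline
("current") allocation from which current production and revenue are
evaluated.

Everything is driven by a single integer seed; a fixed seed reproduces the
instance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DAYS_PER_YEAR, GeneratorConfig

# ---------------------------------------------------------------------------
# Crop roster
# ---------------------------------------------------------------------------

NUTRIENTS = ("energy_kcal", "protein_g", "fat_g", "iron_mg", "niacin_mg", "folate_ug")

#: Recommended per-capita daily intake for each nutrient
#: (kcal, g, g, mg, mg, ug per person per day).
RECOMMENDED_DAILY_INTAKE = {
    "energy_kcal": 2100.0,
    "protein_g": 50.0,
    "fat_g": 40.0,
    "iron_mg": 17.0,
    "niacin_mg": 14.0,
    "folate_ug": 320.0,
}

# name, group, potential yield (kg/ha), MSP (INR/kg), national mean cost of
# production (INR/kg), irrigation application efficiency beta,
# kc stage values (ini, mid, end), kc stage lengths as fractions of season
# (ini, dev, mid, late), nutrient content per kg of produce
# (kcal, g protein, g fat, mg iron, mg niacin, ug folate).
_CROP_TABLE = [
    ("rice",         "rice",     4500.0, 17.5, 6.0, 0.30, (1.05, 1.20, 0.90), (0.17, 0.25, 0.41, 0.17), (3600.0,  71.0,   7.0,   8.0,  16.0,   80.0)),
    ("bajra",        "cereals",  2500.0, 19.5, 8.0, 0.75, (0.35, 1.00, 0.65), (0.13, 0.21, 0.37, 0.29), (3780.0, 110.0,  42.0,  30.0,  47.0,  850.0)),
    ("maize",        "cereals",  4000.0, 17.0, 7.0, 0.75, (0.40, 1.15, 0.70), (0.17, 0.29, 0.33, 0.21), (3650.0,  94.0,  47.0,  27.0,  36.0,  190.0)),
    ("jowar",        "cereals",  2800.0, 24.3, 10.0, 0.75, (0.35, 1.05, 0.65), (0.17, 0.25, 0.33, 0.25), (3290.0, 109.0,  33.0,  34.0,  37.0,  200.0)),
    ("ragi",         "cereals",  2500.0, 29.0, 12.0, 0.75, (0.35, 1.00, 0.65), (0.13, 0.21, 0.37, 0.29), (3280.0,  73.0,  13.0,  39.0,  11.0,  180.0)),
    ("tur",          "pulses",   1800.0, 56.8, 25.0, 0.75, (0.40, 1.10, 0.60), (0.17, 0.25, 0.33, 0.25), (3430.0, 217.0,  15.0,  52.0,  30.0, 4560.0)),
    ("other_pulses", "pulses",   1500.0, 55.8, 24.0, 0.75, (0.40, 1.05, 0.60), (0.13, 0.21, 0.37, 0.29), (3470.0, 240.0,  12.0,  67.0,  23.0, 6250.0)),
    ("groundnut",    "oilseeds", 2200.0, 48.9, 22.0, 0.75, (0.40, 1.15, 0.60), (0.21, 0.29, 0.29, 0.21), (5670.0, 258.0, 492.0,  46.0, 121.0, 2400.0)),
    ("sesamum",      "oilseeds",  800.0, 62.5, 30.0, 0.75, (0.35, 1.10, 0.55), (0.17, 0.25, 0.33, 0.25), (5730.0, 177.0, 497.0, 146.0,  45.0,  970.0)),
    ("soybean",      "oilseeds", 2500.0, 34.0, 15.0, 0.75, (0.40, 1.15, 0.50), (0.17, 0.25, 0.37, 0.21), (4460.0, 365.0, 199.0, 157.0,  16.0, 3750.0)),
    ("nigerseed",    "oilseeds",  700.0, 58.5, 28.0, 0.75, (0.35, 1.05, 0.55), (0.17, 0.25, 0.33, 0.25), (5000.0, 195.0, 390.0, 100.0,  30.0, 1000.0)),
    ("sunflower",    "oilseeds", 1800.0, 53.9, 24.0, 0.75, (0.35, 1.10, 0.45), (0.21, 0.29, 0.29, 0.21), (5840.0, 208.0, 515.0,  53.0,  83.0, 2270.0)),
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ClimateSeries:
    """Daily weather for every district and year.

    rain covers the full calendar year (365 days, mm); temperatures cover
    the growing-season window only, which is where they are needed.
    Shapes: rain (n_districts, n_years, 365); tmin/tmean/tmax
    (n_districts, n_years, n_season_days).
    """

    district_id: np.ndarray
    latitude: np.ndarray
    rain: np.ndarray
    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    season_start_doy: int

    @property
    def n_districts(self) -> int:
        return self.rain.shape[0]

    @property
    def n_years(self) -> int:
        return self.rain.shape[1]

    @property
    def n_season_days(self) -> int:
        return self.tmean.shape[2]

    def season_rain(self) -> np.ndarray:
        """Rainfall inside the growing-season window (mm)."""
        s = self.season_start_doy - 1
        return self.rain[:, :, s : s + self.n_season_days]

    def annual_totals(self) -> np.ndarray:
        """Annual rainfall totals, shape (n_districts, n_years) (mm)."""
        return self.rain.sum(axis=2)

    def validate(self) -> None:
        if np.any(self.rain < 0):
            raise ValueError("rainfall must be non-negative")
        if np.any(self.tmin > self.tmean + 1e-9) or np.any(self.tmean > self.tmax + 1e-9):
            raise ValueError("temperature ordering tmin <= tmean <= tmax violated")

    def to_frame(self) -> pd.DataFrame:
        """Long-format season table (district, year, day, rain, tmin, tmean, tmax)."""
        n_d, n_y, n_s = self.tmean.shape
        idx = pd.MultiIndex.from_product(
            [self.district_id, np.arange(1, n_y + 1), np.arange(1, n_s + 1)],
            names=["district", "year", "season_day"],
        )
        return pd.DataFrame(
            {
                "rain_mm": self.season_rain().ravel(),
                "tmin": self.tmin.ravel(),
                "tmean": self.tmean.ravel(),
                "tmax": self.tmax.ravel(),
            },
            index=idx,
        ).reset_index()


@dataclass
class DistrictAttrs:
    """Land, water-table, irrigation and tariff attributes per district.

    table columns: district, state, latitude, tca_ha (total Kharif cropped
    area), net_cropped_ha, mean_annual_rain_mm (configured generator mean),
    depth_m (depth to groundwater), tariff_inr_kwh.
    eta is the irrigation potential per (crop, district), in [0, 1].
    """

    table: pd.DataFrame
    eta: np.ndarray

    @property
    def n_districts(self) -> int:
        return len(self.table)

    @property
    def district_id(self) -> np.ndarray:
        return self.table["district"].to_numpy()

    @property
    def state(self) -> np.ndarray:
        return self.table["state"].to_numpy()


@dataclass
class CropParams:
    """Agronomic, economic and nutritional parameters of the crop roster.

    table columns: crop, group, potential_yield_kg_ha, msp_inr_kg,
    cp_inr_kg (national mean cost of production), beta (irrigation
    application efficiency). kc has shape (n_crops, n_season_days);
    nutrients has shape (n_nutrients, n_crops), per kg of produce.
    """

    table: pd.DataFrame
    kc: np.ndarray
    nutrients: np.ndarray
    nutrient_names: tuple = NUTRIENTS

    @property
    def n_crops(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["crop"].to_numpy()

    @property
    def potential_yield(self) -> np.ndarray:
        return self.table["potential_yield_kg_ha"].to_numpy()

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()


@dataclass
class SyntheticInstance:
    """A complete self-contained problem instance."""

    config: GeneratorConfig
    climate: ClimateSeries
    districts: DistrictAttrs
    crops: CropParams
    history: np.ndarray            # (n_crops, n_districts) cultivation counts
    suitability: np.ndarray        # (n_crops, n_districts) 0/1
    baseline_area: np.ndarray      # (n_crops, n_districts) ha
    msp: np.ndarray                # (n_crops, n_districts) INR/kg
    cp: np.ndarray                 # (n_crops, n_districts) INR/kg


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _streams(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from the single seed."""
    names = ("core", "econ", "rain", "temp", "history", "baseline")
    children = np.random.SeedSequence(config.random_seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _district_core(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic base attributes shared by the climate and district tables."""
    rng = _streams(config)["core"]
    n = config.n_districts
    ids = np.array([f"D{k:04d}" for k in range(1, n + 1)])
    states = np.array(
        [f"S{(k * config.n_states) // n + 1:02d}" for k in range(n)]
    )
    lat = rng.uniform(*config.latitude_range, size=n)
    rain_mean = rng.uniform(*config.annual_rain_range, size=n)
    return pd.DataFrame(
        {
            "district": ids,
            "state": states,
            "latitude": lat,
            "mean_annual_rain_mm": rain_mean,
        }
    )


def generate_climate(config: GeneratorConfig) -> ClimateSeries:
    """Simulate daily rainfall and temperature for every district and year.

    Rainfall occurrence follows a first-order two-state chain whose
    stationary wet-day probability matches the configured day-of-year
    profile; wet-day amounts are gamma distributed with a per-district
    scale chosen so the expected annual total equals the configured mean.
    A lognormal year factor (mean 1) adds interannual variability at the
    configured CV. Temperatures are drawn around the day-of-year
    climatology; per-day sorting enforces tmin <= tmean <= tmax.
    """
    config.validate()
    streams = _streams(config)
    core = _district_core(config)
    n_d, n_y = config.n_districts, config.n_years
    rng = streams["rain"]

    pi = config.wet_prob_by_doy()                       # (365,)
    p11 = np.clip(pi + config.markov_persistence, 0.0, 0.98)
    with np.errstate(divide="ignore", invalid="ignore"):
        p01 = np.where(pi < 1.0, pi * (1.0 - p11) / (1.0 - pi), 1.0)
    p01 = np.clip(p01, 0.0, 1.0)

    expected_wet_days = pi.sum()
    mean_amount = config.gamma_shape  # gamma(shape, scale=1) mean
    # Per-district gamma scale so E[annual total] = configured mean; no wet
    # days at all means no rain, whatever the configured mean.
    if expected_wet_days > 0:
        scale = core["mean_annual_rain_mm"].to_numpy() / (expected_wet_days * mean_amount)
    else:
        scale = np.zeros(n_d)

    wet = np.empty((n_d, n_y, DAYS_PER_YEAR), dtype=bool)
    state = rng.random((n_d, n_y)) < pi[0]
    wet[:, :, 0] = state
    u = rng.random((n_d, n_y, DAYS_PER_YEAR - 1))
    for d in range(1, DAYS_PER_YEAR):
        p = np.where(state, p11[d], p01[d])
        state = u[:, :, d - 1] < p
        wet[:, :, d] = state

    amounts = rng.gamma(config.gamma_shape, 1.0, size=wet.shape)
    rain = np.where(wet, amounts, 0.0) * scale[:, None, None]

    if config.rain_cv > 0:
        sigma = np.sqrt(np.log1p(config.rain_cv**2))
        year_factor = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_d, n_y))
        rain *= year_factor[:, :, None]

    # Temperature: normal draws around the climatology, sorted per day so
    # that min <= mean <= max always holds.
    trng = streams["temp"]
    clim = config.temperature_climatology()
    n_s = config.n_season_days
    draws = np.empty((3, n_d, n_y, n_s))
    for k, name in enumerate(("tmin", "tmean", "tmax")):
        draws[k] = clim[f"{name}_mean"] + clim[f"{name}_sd"] * trng.standard_normal(
            (n_d, n_y, n_s)
        )
    draws.sort(axis=0)
    series = ClimateSeries(
        district_id=core["district"].to_numpy(),
        latitude=core["latitude"].to_numpy(),
        rain=rain,
        tmin=draws[0],
        tmean=draws[1],
        tmax=draws[2],
        season_start_doy=config.season_start_doy,
    )
    series.validate()
    return series


def generate_districts(config: GeneratorConfig) -> DistrictAttrs:
    """District land, groundwater and irrigation attributes.

    Depth to groundwater is anticorrelated with mean annual rainfall (arid
    districts pump from deeper). Irrigation potential eta is state-level:
    each state has a development level, rice gets the full level (it is
    the most irrigated crop), other crops a state-by-crop fraction of it.
    """
    config.validate()
    core = _district_core(config)
    rng = _streams(config)["econ"]
    n = config.n_districts

    tca = rng.uniform(5.0e4, 3.0e5, size=n)  # ha
    net_cropped = tca / rng.uniform(0.6, 0.9, size=n)
    rain_mean = core["mean_annual_rain_mm"].to_numpy()
    depth = np.clip(
        45.0 - 0.025 * rain_mean + rng.normal(0.0, 4.0, size=n), 2.0, 60.0
    )

    states = core["state"].to_numpy()
    unique_states = np.unique(states)
    dev_level = dict(
        zip(unique_states, rng.uniform(0.05, 0.70, size=len(unique_states)))
    )
    crop_factor = {
        s: np.concatenate(([1.0], rng.uniform(0.4, 1.0, size=max(config.n_crops - 1, 0))))
        for s in unique_states
    }
    eta = np.empty((config.n_crops, n))
    for j, s in enumerate(states):
        eta[:, j] = np.clip(dev_level[s] * crop_factor[s][: config.n_crops], 0.0, 1.0)

    table = core.copy()
    table["tca_ha"] = tca
    table["net_cropped_ha"] = net_cropped
    table["depth_m"] = depth
    table["tariff_inr_kwh"] = config.tariff_inr_per_kwh
    return DistrictAttrs(table=table, eta=eta)


def _kc_curve(kc_ini: float, kc_mid: float, kc_end: float,
              fractions: tuple, n_days: int) -> np.ndarray:
    """FAO-style four-stage crop-coefficient curve over the season.

    Constant at kc_ini during establishment, linear ramp through
    development, constant at kc_mid, linear decline to kc_end.
    """
    lengths = np.floor(np.asarray(fractions) * n_days).astype(int)
    lengths[-1] = n_days - lengths[:-1].sum()
    if np.any(lengths < 0):
        raise ValueError("crop-coefficient stage lengths inconsistent with season length")
    l_ini, l_dev, l_mid, l_late = lengths
    parts = [
        np.full(l_ini, kc_ini),
        np.linspace(kc_ini, kc_mid, l_dev + 2)[1:-1] if l_dev else np.empty(0),
        np.full(l_mid, kc_mid),
        np.linspace(kc_mid, kc_end, l_late + 1)[1:] if l_late else np.empty(0),
    ]
    curve = np.concatenate(parts)
    assert curve.size == n_days
    return curve


def generate_crops(config: GeneratorConfig) -> CropParams:
    """The Kharif crop roster with kc curves, prices and nutrient contents.

    The default 12 crops are grouped rice / other cereals / pulses /
    oilseeds; a smaller n_crops takes the first n_crops of the roster.
    Rice irrigates at 30% application efficiency (flood irrigation), all
    other crops at 75%.
    """
    config.validate()
    if config.n_crops > len(_CROP_TABLE):
        raise ValueError(f"at most {len(_CROP_TABLE)} crops are defined")
    rows = _CROP_TABLE[: config.n_crops]
    table = pd.DataFrame(
        [
            {
                "crop": name,
                "group": group,
                "potential_yield_kg_ha": py,
                "msp_inr_kg": msp,
                "cp_inr_kg": cp,
                "beta": beta,
            }
            for name, group, py, msp, cp, beta, _, _, _ in rows
        ]
    )
    kc = np.vstack(
        [
            _kc_curve(kc_vals[0], kc_vals[1], kc_vals[2], fracs, config.n_season_days)
            for *_x, kc_vals, fracs, _nut in rows
        ]
    )
    nutrients = np.array([nut for *_x, nut in rows]).T  # (n_nutrients, n_crops)
    return CropParams(table=table, kc=kc, nutrients=nutrients)


def generate_history(config: GeneratorConfig,
                     districts: DistrictAttrs) -> np.ndarray:
    """Counts of past seasons each crop was cultivated in each district.

    Wetter districts favour rice; drier districts favour millets and
    oilseeds. Counts are binomial over the history years with a
    crop-by-district propensity, so most (crop, district) pairs either
    clearly pass or clearly fail the suitability threshold.
    """
    rng = _streams(config)["history"]
    n_c, n_d = config.n_crops, config.n_districts
    rain = districts.table["mean_annual_rain_mm"].to_numpy()
    wetness = (rain - rain.min()) / max(np.ptp(rain), 1.0)  # 0 dry .. 1 wet

    # Per-crop affinity for wetness: rice strongly wet, oilseeds/millets dry.
    affinity = np.linspace(1.0, -1.0, n_c)  # roster is ordered wet- to dry-adapted
    logit = 2.0 * affinity[:, None] * (wetness[None, :] - 0.5) + rng.normal(
        0.0, 1.2, size=(n_c, n_d)
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    counts = rng.binomial(config.history_years, p)
    # Every district must have at least one suitable crop so the area
    # constraint row is never empty.
    thin = counts.max(axis=0) < config.suitability_threshold
    counts[rng.integers(0, n_c, size=n_d)[thin], np.where(thin)[0]] = (
        config.suitability_threshold
    )
    return counts


def derive_suitability(history: np.ndarray, threshold: int = 5) -> np.ndarray:
    """Suitability indicators: 1 where a crop was cultivated at least
    `threshold` times in the past, else 0."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    history = np.asarray(history)
    if np.any(history < 0):
        raise ValueError("history counts must be non-negative")
    return (history >= threshold).astype(int)


def generate_baseline_allocation(
    districts: DistrictAttrs,
    crops: CropParams,
    suitability: np.ndarray,
    seed: int,
    area_fraction: float = 0.85,
    history: np.ndarray | None = None,
) -> np.ndarray:
    """Baseline ("current") cropped areas a0 (ha), shape (n_crops, n_districts).

    Each district plants `area_fraction` of its total Kharif cropped area
    (a small margin stays fallow in any given season), split across its
    suitable crops with weights proportional to how often each crop was
    cultivated there — current patterns track local suitability — times a
    Dirichlet-style jitter. Unsuitable crops get exactly zero area, so the
    land constraint holds by construction.
    """
    if not (0.0 < area_fraction <= 1.0):
        raise ValueError("area_fraction must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    n_c, n_d = suitability.shape
    tca = districts.table["tca_ha"].to_numpy()
    baseline = np.zeros((n_c, n_d))
    propensity = (
        np.asarray(history, dtype=float) if history is not None else np.ones((n_c, n_d))
    )
    weights = rng.gamma(2.0, 1.0, size=(n_c, n_d)) * propensity * suitability
    totals = weights.sum(axis=0)
    nonzero = totals > 0
    baseline[:, nonzero] = (
        weights[:, nonzero] / totals[nonzero] * (area_fraction * tca[nonzero])
    )
    return baseline


def generate_instance(config: GeneratorConfig) -> SyntheticInstance:
    """Generate a full instance: climate, districts, crops, suitability,
    baseline allocation and district-level price/cost tables."""
    config.validate()
    climate = generate_climate(config)
    districts = generate_districts(config)
    crops = generate_crops(config)
    history = generate_history(config, districts)
    suitability = derive_suitability(history, config.suitability_threshold)
    baseline = generate_baseline_allocation(
        districts, crops, suitability, config.random_seed,
        config.baseline_area_fraction, history,
    )

    # MSP is announced nationally; the cost of production is state-level
    # (all districts of a state share it), varying around the national mean.
    rng = _streams(config)["econ"]
    n_c, n_d = config.n_crops, config.n_districts
    msp = np.repeat(crops.table["msp_inr_kg"].to_numpy()[:, None], n_d, axis=1)
    states = districts.state
    unique_states = np.unique(states)
    state_factor = dict(
        zip(unique_states, rng.uniform(0.8, 1.3, size=(len(unique_states), n_c)))
    )
    cp_national = crops.table["cp_inr_kg"].to_numpy()
    cp = np.empty((n_c, n_d))
    for j, s in enumerate(states):
        cp[:, j] = cp_national * state_factor[s]

    return SyntheticInstance(
        config=config,
        climate=climate,
        districts=districts,
        crops=crops,
        history=history,
        suitability=suitability,
        baseline_area=baseline,
        msp=msp,
        cp=cp,
    )


def nutrition_targets(config: GeneratorConfig) -> np.ndarray:
    """Annual national nutrition targets N_n for each nutrient.

    Per-capita recommended daily intake x population x 365, scaled by the
    Kharif coverage fraction (these crops supply only part of the annual
    national nutrient intake). The population is proportional to the
    number of districts, so sub-national instances carry proportional
    targets."""
    rdi = np.array([RECOMMENDED_DAILY_INTAKE[n] for n in NUTRIENTS])
    population = config.population_per_district * config.n_districts
    return rdi * population * 365.0 * config.kharif_coverage
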