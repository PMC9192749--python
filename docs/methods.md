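# Methods

## Scope and shape

The package implements a national hydro-economic allocation analysis as a
pipeline of five stages: (1) synthetic instance generation, (2) reference
evapotranspiration, (3) the daily crop-water balance and deficit-driven
yields, (4) per-hectare economic coefficients (gross margin, irrigation
water, pumping energy, irrigation cost), and (5) a linear program per
irrigation scenario with district/state comparison reporting. Each stage
is a library module; the `analysis/` drivers narrate a desk-scale run and
`scripts/acceptance.py` re-runs the full national scale.

## Water balance and yield

Daily usable supply is a fixed fraction α = 0.7 of rainfall; the remainder
is treated as lost to runoff and deep drainage. α is one global scalar
(overridable per run, not per district). Crop demand is kc·ET0 with
four-stage FAO-style kc curves over a 120-day season starting June 1. The
accumulated deficit follows the clamped recursion
`def_d = max(0, def_{d-1} + D_d − S_d)`; a wet day can draw the
accumulated deficit down to zero but never banks a surplus, and there is
no soil-moisture store or carryover. The seasonal deficit SD is the
running maximum, so two years with equal totals but different daily
timing give different SD. Yield declines linearly in the unmet deficit
fraction: Y = (1 − (1−η)·SD/CWR)·PY, bounded between η·PY and PY. The
degenerate case CWR = 0 (zero demand all season) is defined as unstressed,
Y = PY, with zero irrigation volume; the formula is otherwise undefined
there. All crops plant on season day 1; planting offsets exist only
through the kc staging.

ET0 uses Hargreaves–Samani, 0.0023·0.408·Ra·(Tmean+17.8)·√(Tmax−Tmin),
floored at zero, with FAO-56 extraterrestrial radiation (sunset-hour-angle
argument clamped to [−1, 1], so polar night gives Ra = 0). Day-of-year 366
maps to 365; the error is negligible at seasonal scale.

## Economics and energy

Gross margin per hectare is (MSP − CP)·E_t[Y] with MSP uniform nationally
and the cost of production state-level, per kg of output (so margins scale
with realized yield). Irrigation water per hectare is (1/β)·η·E_t[SD],
with application efficiency β = 0.30 for flood-irrigated rice and 0.75
for the other crops. Pumping energy lifts that volume from the district's
depth to groundwater at pump efficiency μ_p = 0.3, with ψ1 = 10⁴ kg per
mm·ha and ψ2 = 1/3,600,000 kWh per J; the cost enters the objective at the
flat agricultural tariff CI = 3 INR/kWh. Energy savings are valued
separately at the 7 INR/kWh residential price (an opportunity cost, not an
objective term). Expectations are unweighted means over the simulated
years. Objective coefficients may be negative; the LP then avoids the pair
unless a production or nutrition floor forces it.

## The linear program

Variables exist only for suitable (δ = 1) pairs. All rows are assembled as
≤ rows in consistent units (ha, m³, kg, INR): area per district (bound
TCA_j), irrigation per district under the capped scenario (bound
λ·P̄_j·A_j·10 m³ with λ = 0.15, the renewable-recharge share of mean
annual rainfall; an explicit per-district m³ override supports the
"current-use cap" reading), production per crop (≥ Q_i, negated) and
nutrition per nutrient (≥ N_n, negated). Under the zero scenario the
irrigation rows are vacuous and are omitted, which reproduces the
n_d + n_c + n count. Q_i defaults to the model-evaluated expected
production of the baseline allocation, keeping the comparison internally
consistent (an override accepts externally reported production). N_n is
the per-capita recommended daily intake × population × 365 × a Kharif
coverage fraction (below).

The LP is solved with HiGHS (scipy.optimize.linprog); duals are reported
for the maximization problem (marginal objective per unit of right-hand
side). Optimality is cross-checked three independent ways in the tests:
an LP-duality certificate (primal feasibility, dual feasibility, strong
duality — computed from the matrices alone), agreement between the dual
simplex and interior-point algorithms, and exhaustive grid enumeration on
2×2 instances. Complementary slackness of the reported duals is verified
inside `shadow_price_report`. Infeasibility is diagnosed by an elastic
relaxation minimizing total violation *relative to each row's bound*
(families carry different units, so raw violations are not comparable);
the report names the family that cannot be met. Feasibility tolerance is
1e-7 relative. Alternate optima are possible in degenerate instances;
comparisons therefore rest on objective values, and allocation-level tests
use instances constructed to have unique optima.

The MPS exporter writes a free-format maximization model for cross-solver
checks outside this environment.

## The synthetic generator

The generator emulates the statistical structure of the analysis's real
inputs; it does not fit any observed dataset, and districts are spatially
independent (no inter-district rainfall correlation, no downscaling).

* **Rainfall**: first-order two-state occurrence chain whose stationary
  wet-day probability is 0.55 inside the 120-day monsoon window and 0.03
  outside (≈90% of annual rain falls in the window), persistence +0.25 on
  wet days; gamma amounts (shape 0.8) scaled per district so the expected
  annual total equals the district's configured mean (drawn uniformly in
  450–1600 mm); a mean-one lognormal year factor sets the interannual CV
  (0.18). A fixed seed reproduces every array bit-for-bit; the simulated
  mean annual total recovers the configured mean within 5% over 200 years.
* **Temperature**: normal draws around a linear in-season climatology
  (31 °C falling to 27 °C, sd 1.5 °C, ±6 °C diurnal half-range), sorted
  per day so Tmin ≤ Tmean ≤ Tmax always holds. With sd = 0 the simulation
  reproduces the climatology exactly.
* **Districts**: land areas uniform 50–300 kha, depth to groundwater
  anticorrelated with mean rainfall (arid districts pump deeper),
  districts grouped into 32 states carrying the state-level parameters
  (cost-of-production factor, irrigation development level 0.05–0.70;
  rice receives the full level, other crops a state-by-crop fraction).
* **Crops**: a fixed 12-crop roster (rice; bajra, maize, jowar, ragi; tur,
  other pulses; groundnut, sesamum, soybean, nigerseed, sunflower) with
  order-of-magnitude realistic potential yields (rice 4,500 kg/ha),
  support prices, costs and USDA-style nutrient contents; all overridable
  through the tables.
* **Suitability and baseline**: cultivation histories are binomial with a
  wetness-affinity propensity (rice wet-adapted, millets/oilseeds
  dry-adapted; ~80% of pairs end up suitable at the ≥5-of-20 threshold,
  and every district keeps at least one suitable crop). The baseline
  allocation splits 85% of each district's cropped area across suitable
  crops with history-proportional jittered weights — current patterns
  track local suitability, and a ~15% margin of the cropped-area envelope
  is fallow or under other crops in any one season. The baseline satisfies
  the land constraint by construction, and under the default conditions
  both scenarios are feasible across seeds and scales.
* **Nutrition targets**: recommended daily intakes (2100 kcal, 50 g
  protein, 40 g fat, 17 mg iron, 14 mg niacin, 320 µg folate per person)
  × 365 days × population (2.22 million per district, ≈1.3 billion at the
  586-district scale) × a coverage fraction of 0.25 — these Kharif crops
  supply roughly a quarter of annual national nutrient intake, with the
  Rabi season and non-procured foods supplying the rest.

Because the instance is synthetic, passing tests demonstrate the
*machinery* — the recursion, the coefficients, the optimization, the
reporting — under realistic magnitudes; the headline revenue/water/energy
numbers of a synthetic run characterize the synthetic instance, not
India. Structural conclusions that do transfer: the zero scenario uses
exactly no water and energy, production and nutrition floors bind or stay
slack as reported, and income redistribution is mostly within the neutral
band because per-district changes are small relative to ±0.01 trillion
INR.

## Numerical and design choices

* Problem sizes: the unit-test fixture is 12×12×8; the analysis drivers
  default to 60×12×40; the acceptance script and the timed acceptance test
  run the full 586×12×109 (a few seconds for the water balance, under a
  second per LP solve).
* The deficit recursion is the only day-level loop (120 iterations over
  (crop, district, year) arrays); everything else is vectorized.
* The support-price sensitivity sweep reduces (MSP − CP) one crop at a
  time and flags any change in the exact support (set of positive areas)
  of the optimum; with near-degenerate economics this is a conservative
  (easily triggered) flag.
* Income-change categories are half-open intervals, closed on the left,
  with out-of-range values clamped to the extreme categories; they are
  reported in absolute trillion INR at district level.
* Known limitations: no Rabi season, no surface-water irrigation costs,
  no capital costs of wells/pumps, no spatial correlation in weather, no
  soil water-holding capacity, single global α, and no multi-objective
  equity treatment (state-level redistribution is reported, not
  constrained).
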