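# Methods

This note documents the models inside `wfcrop`, the parameter choices that
matter, the numerical conventions, and the limits of what the synthetic
world can show.

## Scope and design

The package reproduces, at desk scale, the production chain of gridded
crop water-footprint datasets: daily crop growth coupled to a vertical
soil water balance with green/blue water tracing, simulated on a coarse
grid, allocated to a finer grid by harvested-area distributions, scaled to
a national census, and post-processed into unit water footprints
(uWF, m³ t⁻¹ yr⁻¹), water footprints of production (pWF, m³ yr⁻¹) and crop
water use (CWU, mm yr⁻¹). Simulation runs include a two-year warm-up that
establishes realistic soil moisture and is discarded from reporting, and
fallow periods between seasons are simulated continuously so that soil
moisture (including left-over blue water) carries over between seasons.

## Soil water balance and colour tracing

The column is discretised into compartments (default 3 m in 8 layers of
0.1–0.7 m; a 2 m, 7-layer variant for shallow-rooting crops such as rice
in this archetype set). Each compartment stores water (mm) plus the mass
fractions of three colours: green (precipitation), blue-from-irrigation
and blue-from-capillary-rise. Inflows mix instantaneously and completely
with pre-stored water (perfect mixing per compartment); outflows remove
water proportionally across colours of the donor store. This fractional
representation is cross-checked in the test suite against a brute-force
parcel ledger in which every inflow remains an individually tagged parcel;
the two agree to 10⁻⁶ mm over multi-year runs.

Daily event order is fixed: capillary rise → rainfall partition into
runoff/infiltration → irrigation → drainage → evaporation and
transpiration. The order is a modelling convention; no ordering is
canonical at a daily step, and mass conservation per colour holds exactly
(residuals ~10⁻¹⁰ mm over 12 years) regardless.

Component rules:

* **Runoff**: SCS curve number, S = 254(100/CN − 1) mm, initial
  abstraction 0.2 S. Flooded rice fields are bunded (300 mm): no runoff
  until ponded water tops the bund, then only the excess spills.
* **Infiltration** fills compartments to saturation top-down; what passes
  the bottom leaves as deep percolation.
* **Drainage**: a τ-cascade — each day a fraction τ (per texture class) of
  the water above field capacity moves to the compartment below, carrying
  the donor's colour mix. This matches the compartment design; no
  Richards-type flow is attempted.
* **Capillary rise** applies to rainfed crops only (farmers are assumed
  not to irrigate where crops tap shallow groundwater), with flooded rice
  as the single irrigated exception. Daily water-table depth is linearly
  interpolated from a monthly climatology; surfacing water tables are
  treated as drained to 1 m. The flux law itself is not dictated by any
  data source, so a transparent form is used: 5 mm/day at ≤1 m depth,
  declining linearly to zero at 4 m, multiplied by the bottom
  compartment's dryness relative to field capacity and capped by its
  headroom to field capacity. Only the *where it applies* rules are
  inherited; the flux magnitudes are this package's own choice.
* **Soil evaporation** follows the standard two-stage model: demand-driven
  until the cumulative depletion of the surface layer exceeds the readily
  evaporable water (REW), then a linearly falling rate until the totally
  evaporable water (TEW = (θ_fc − 0.5 θ_wp)·Δz₁) is gone. Rain and
  irrigation reset the depletion. Ponded rice water evaporates first at
  full rate.
* **Transpiration** demand is ET₀·Kcb·CC·Ks; uptake is distributed over
  the root zone by overlap-weighted, depth-tapered weights with a second
  compensation pass, limited per compartment by water above wilting point.
  Availability gates use a 10⁻⁹ mm threshold so uptake never depends on
  float rounding at exactly-wilting-point storage.

Three texture classes (sand/loam/clay) carry θ_sat/θ_fc/θ_wp, τ, CN and
REW through a small pedotransfer table; values are standard textbook
magnitudes, chosen once.

## Evapotranspiration

FAO-56 Penman-Monteith, daily, short reference crop: albedo 0.23, soil
heat flux G = 0, psychrometric constant from elevation-adjusted pressure,
net longwave from the Stefan-Boltzmann term with humidity and relative
shortwave corrections (Rs/Rso clipped to [0.33, 1]), wind assumed measured
at 2 m. ET₀ is clamped at zero. An independent hand evaluation of the
closed form on pinned inputs is frozen in the test suite.

## Crop growth

* **Phenology** runs on growing degree days,
  GDD = max(0, (min(tmax, Tupp) + clamp(tmin, Tbase, Tupp))/2 − Tbase).
  Heat-unit requirements are calibrated per cell: the maturity requirement
  is the mean GDD accumulated between the reference planting and harvest
  dates over all forcing years, and stage boundaries (emergence, maximum
  canopy, senescence, maturity) sit at fixed fractions 5/40/80/100 % of
  it. This makes simulated harvests land on the reference date under the
  mean climate, earlier in warm years, and at most 15 % past the reference
  season length in cold years. Sown annuals wait for seedbed moisture
  (θ ≥ θ_wp + 0.3(θ_fc − θ_wp) in the top compartment), at most 30 days.
* **Canopy cover** grows exponentially from CC₀ while CC ≤ CCₓ/2, then
  approaches CCₓ by the mirrored exponential, and declines exponentially
  with CDC in senescence; water stress scales the growth coefficient.
* **Habits.** Deciduous perennials replace planting with bud break (first
  day whose trailing 10-day GDD sum exceeds a crop requirement), keep
  rooting depth constant and hold a minimum leafless canopy; evergreen
  perennials hold CC at CCₓ and are harvested every 31 December. Perennial
  CWU is accumulated over the entire calendar year.
* **Biomass and yield.** ΔB = WP\*·f(CO₂)·Tr/ET₀ with normalised water
  productivity WP\* per archetype. f(CO₂) = 1 + s(1 − e^(−0.005 Δppm)) is
  anchored at exactly 1 at 369.41 ppm; the response scale s is set so
  +200 ppm yields ≈ +10 % for C3 and ≈ +2 % for C4 archetypes — a
  magnitude chosen by this package, parameterised rather than asserted.
  Dry yield is B·HI₀·f_stress, where each flowering day above the
  pollination-failure temperature multiplies the harvest index by 0.8,
  each severe-water-stress day (stomatal Ks < 0.3) during yield formation
  by 0.95, floored at 0.05 (near-total but never exactly total failure).
  The flowering window spans maximum canopy to +10 % of maturity GDD.
* **Water stress** coefficients fall linearly from 1 at the threshold
  depletion p·TAW to 0 at full depletion; canopy expansion uses 0.7 of
  the stomatal threshold so expansion is hit first.
* **Fallow** periods carry a static cover crop (CC 0.30, Kcb 0.60,
  rooting 0.3 m) standing in for grasses and short weeds.

## Irrigation

Soil-moisture-depletion scheduling: when root-zone depletion exceeds the
crop's trigger fraction of TAW (0.50 for tolerant crops such as maize,
down to 0.25 for sensitive ones), the application refills the root zone
exactly to field capacity — supply and conveyance are never limiting, so
applications are net field-level requirements and blue consumption is a
potential value. Rice has no threshold: the paddy is topped up to a 50 mm
ponding target daily (the target depth is this package's choice; bunds
and flooding are the inherited constraints), and ponded water percolates
into the profile at 10 mm/day, a typical puddled-paddy rate. Drip systems
wet 30 % of the surface, which reduces soil-evaporation demand on
application days; the method does not change the applied depth.

## Synthetic world

The generator emulates the *structure* of the real input stack: daily
gridded weather, an annual CO₂ series, per-cell soil texture and monthly
groundwater-depth climatology (about a third of cells shallower than 2 m,
the rest deeper than 4 m), five crop archetypes (C3 annual, C4
stress-tolerant annual, two-season flooded rice, deciduous perennial,
evergreen perennial) with calendars and irrigation policies, fine-grid
rainfed/irrigated harvested-area maps nested in the coarse simulation
grid, country labels, and a national census of harvested area and
production.

Weather: a first-order two-state wet/dry chain (persistence 0.5, tuned to
the configured wet-day probability) with gamma wet-day amounts
(shape 0.75), a sinusoidal annual temperature cycle with AR(1) noise
(φ = 0.7, σ = 2 °C), shortwave radiation as a fraction of extraterrestrial
radiation that drops on wet days, and humidity/wind consistent with the
wet state. A 365-day calendar is used throughout. All randomness flows
from one root seed through named substreams, so worlds are bit-identical
under a fixed seed and adding a component never perturbs another's draws.

The census is the generator's truth perturbed by a configurable relative
noise. Census harvested areas derive from the generator's base areas and
trend indices; census production is the pipeline's own pre-scaling
national production bookkeeping times the noise factor — production truth
cannot exist before the simulation has run, so the world finalises the
census after the simulate stage. At zero noise every scaling factor is
exactly 1, which is the package's self-consistency anchor.

What the synthetic world does *not* emulate: real geography and
coastlines, bias-corrected reanalysis statistics, historical CO₂ (linear
trend only), interannually varying groundwater, the real crop catalogue
(five archetypes stand for it), and fodder-crop census gaps. Passing
tests therefore demonstrate correctness of the machinery — conservation,
scaling exactness, schema fidelity, oracle agreement — not agreement with
any real-world dataset.

## Post-processing conventions

Order of operations: area projection → area census-scaling → production
computation → yield scaling → uWF → pWF. Harvested area counts every
growing season (two-season rice contributes twice its physical area);
multi-season CWU is reported as the area-weighted *average* of season
values, never the sum, and the per-harvest yield divides total fresh
yield by the number of completed seasons, so uWF·yield/10 = CWU holds
identically. Area scaling preserves the rainfed/irrigated split per cell
(uniform national rescale with systems summed). Rainfed blue uWF is
capillary rise only; irrigated blue uWF is irrigation (plus capillary
rise only for rice) — with capillary rise disabled for irrigated non-rice
crops in the engine, the components pass through unchanged. Seasons still
in progress when the simulation ends are dropped. A season is reported
under its harvest year even when planted the year before.

Gridded decade layers weight uWF by production and CWU by harvested area;
the `*_total` layers combine rainfed and irrigated with the same weights.
Masked cells are written as the NetCDF fill value (NaN), never zero.
NetCDF I/O uses xarray's scipy backend (NETCDF3); grids carry WGS84
lat/lon coordinates and the writer works for any rectangular geometry,
including the 4320×2160 5-arcmin global grid.

## Numerical conventions and degenerate inputs

Colour fractions are renormalised only through mass-weighted mixing and
sum to 1 within 10⁻⁹ wherever storage is positive. Zero yields mask uWF
(NaN) rather than producing infinities; zero production forces pWF to 0;
zero simulated production with positive census leaves the scaling factor
undefined and flags the country-crop-year. All-zero weights leave
aggregates undefined (NaN). Cells whose climate accumulates no heat units
over a crop's window are non-viable: the calendar entry is skipped, and a
crop with no viable calendar returns an empty result with a reason.

## Default problem sizes

The default world is a 4×4 coarse grid with a 2× allocation subdivision,
3 countries, 5 crops and 12 simulated years (2 warm-up + 10 reported) —
about 750 seasons — chosen so a full pipeline runs in about a minute on
one CPU while every mechanism (both systems, shallow and deep groundwater,
all three habits, multi-season rice) is exercised. Tests use smaller
worlds (down to a single humid cell) where a property does not need the
full grid.

## Known limitations

No nutrient cycling, soil fertility or salinity stress; no crop rotation
or multi-cropping (overlapping calendar entries defer planting until the
field is free); no groundwater pumping or interannual water-table
variability; no conveyance losses or water-availability constraints; no
grey water footprints. The capillary-rise law, CO₂ response, heat/water
harvest-index dose-response, rice ponding target and paddy percolation
rate are plausible canonical forms, parameterised and documented here,
and should be recalibrated before any use beyond the synthetic world.
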