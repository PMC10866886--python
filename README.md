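# wfcrop

Green and blue crop water footprints from a daily process-based crop and
soil-water simulation, at desk scale.

`wfcrop` is aimed at agro-hydrologists and water-footprint practitioners who
want a transparent, fully testable implementation of the production chain
behind gridded crop water-footprint datasets: a daily crop growth and
vertical soil-water-balance model that traces *where the water came from*,
followed by the census-scaling and accounting steps that turn simulated
crop water use and yields into unit water footprints (uWF, m³ t⁻¹ yr⁻¹) and
water footprints of production (pWF, m³ yr⁻¹). Everything runs on a
reproducible synthetic world (grid, weather, soils, groundwater, crops,
harvested-area maps, census), so the whole pipeline is exercisable offline
in minutes.

## The model in brief

**Water colours.** The soil column (3 m in 8 compartments; 2 m in 7 for
shallow-rooting crops) stores water together with the fractions of three
colours: green (precipitation), blue-from-irrigation, and
blue-from-capillary-rise. Every inflow mixes with pre-stored water; every
outflow — curve-number runoff, drainage (τ-cascade), soil evaporation
(two-stage), transpiration (root-weighted uptake) — carries its donor
store's colour composition. Summing colour-split evapotranspiration over a
season gives green and blue crop water use:

CWU_c = Σ_days (E_c + T_c),  c ∈ {green, blue_irr, blue_cr}

**Crop growth.** Phenology runs on growing degree days with per-cell
calibrated heat-unit requirements; canopy cover grows exponentially from
CC₀ toward CCₓ and declines in senescence; biomass accumulates as
ΔB = WP\* · f(CO₂) · Tr/ET₀ and a stress-adjusted harvest index converts it
to dry yield. Annual, deciduous-perennial (bud break, leafless minimum
canopy) and evergreen-perennial (harvest 31 Dec) habits are supported.
Reference evapotranspiration is the FAO-56 Penman-Monteith daily form.

**Irrigation.** Triggered when root-zone depletion exceeds a crop-specific
fraction of total available water (0.25–0.50); applications refill the root
zone to field capacity. Rice is flooded daily to a 50 mm target behind
300 mm bunds and is the only irrigated crop with capillary-rise access.

**Accounting.** Yields are converted dry→fresh (fresh = dry/(1−wc)),
harvested areas are projected from a base year and scaled to the national
census, national yield-scaling factors k = census/simulated production are
applied uniformly to all rainfed and irrigated cells (CWU is never scaled),
then per cell: uWF = 10·CWU/yield and pWF = uWF·production. National uWFs
are production-weighted means; national CWU and yields are harvested-area
weighted.

## Worked example

```bash
wfcrop simulate --seed 4 --out run    # generate world + run the simulation
wfcrop postprocess --run-dir run      # census scaling, uWF/pWF, writers
wfcrop report --run-dir run
```

prints, for the default 4×4-cell, 3-country, 12-year world:

```
citrus: mean wf_tot 138 m3/t, mean yield 65.52 t/ha
grape: mean wf_tot 478 m3/t, mean yield 19.26 t/ha
maize: mean wf_tot 495 m3/t, mean yield 12.50 t/ha
rice: mean wf_tot 1099 m3/t, mean yield 3.95 t/ha
wheat: mean wf_tot 2652 m3/t, mean yield 3.32 t/ha
```

i.e. the production-weighted national unit water footprint averaged over
countries and years: ~1100 m³ of consumed water per tonne of paddy rice,
~500 m³/t for maize, and so on; fruit crops are cheap per fresh tonne
because of their high water content. The run directory holds the national
CSV (13 fixed columns, `wfg_m3_t`/`wfb_cr_m3_t`/`wfb_i_m3_t`/`wf_tot_m3_t`),
and per-crop NetCDF files with `wf_unit_{wf_type}` and `cwu_{cwu_type}`
layers. Two gridded datasets can be compared with

```bash
wfcrop validate --ours run/cwu_maize_average.nc --theirs other.nc --threshold 50
```

which reports the matching-cell fraction, (weighted) Pearson correlation,
and the median of grid-level relative differences.

The same pipeline is available as a library:

```python
from wfcrop import WorldConfig, run_pipeline
result = run_pipeline(WorldConfig(seed=4))
result.national.head()     # the 13-column national table
result.summary()           # global pWF, green share, conservation residual
```

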