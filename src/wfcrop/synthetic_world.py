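"""Reproducible miniature world for exercising the full pipeline offline.

The world is a coarse simulation grid (default 4 x 4 cells) subdivided into
a finer allocation grid, split into countries, with daily weather per
coarse cell, a soil texture class and monthly groundwater-depth climatology
per cell, crop archetypes with calendars and irrigation policies,
rainfed/irrigated harvested-area maps on the fine grid, and a national
census of harvested area and production.

Weather uses a first-order two-state wet/dry occurrence chain with
gamma-distributed wet-day amounts, a sinusoidal annual temperature cycle
with AR(1) noise, shortwave radiation co-varying negatively with wet days,
and humidity/wind consistent with the wet state. A 365-day calendar is
used throughout (no leap days).

All randomness flows from a single root seed through named substreams
(weather, soils, groundwater, areas, census), so adding one component
never perturbs another's draw sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from . import evapotranspiration as et
from .crop_growth import CropCalendar, CropParameters
from .irrigation import IrrigationPolicy
from .parameters import (load_crop_calendars, load_crop_parameters,
                         load_irrigation_policies)
from .soil_water import TEXTURE_CLASSES

DAYS_PER_YEAR = 365

# substream tags (stable across versions; order must never change)
_STREAM_WEATHER = 1
_STREAM_SOILS = 2
_STREAM_GROUNDWATER = 3
_STREAM_AREAS = 4
_STREAM_CENSUS = 5

__all__ = ["ClimateParams", "WorldConfig", "WeatherSeries", "World",
           "generate_weather", "generate_world"]


@dataclass(frozen=True)
class ClimateParams:
    """Climate of one latitude band (one coarse-grid row)."""

    mean_annual_precip_mm: float
    wet_day_prob: float
    temp_mean_c: float
    temp_amplitude_c: float
    mean_wind_ms: float
    mean_rh_pct: float
    latitude_deg: float


#: default bands, warm/wet at the top row to cool temperate at the bottom
DEFAULT_CLIMATES = [
    ClimateParams(1500.0, 0.40, 24.0, 4.0, 2.0, 75.0, 15.0),
    ClimateParams(1100.0, 0.32, 18.0, 8.0, 2.5, 68.0, 25.0),
    ClimateParams(650.0, 0.20, 16.0, 10.0, 3.0, 55.0, 35.0),
    ClimateParams(900.0, 0.30, 12.0, 11.0, 3.0, 65.0, 45.0),
]


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world.

    ``years`` counts simulated years including the two warm-up years, so it
    must be at least 3. ``census_noise`` is the relative perturbation of the
    census relative to the generator's truth; at 0 the census equals the
    simulated-truth bookkeeping exactly and all downstream scaling factors
    are 1.
    """

    seed: int = 0
    years: int = 12
    coarse_rows: int = 4
    coarse_cols: int = 4
    fine_factor: int = 2
    n_countries: int = 3
    start_year: int = 2000
    co2_start_ppm: float = 369.41
    co2_trend_ppm_yr: float = 2.0
    census_noise: float = 0.05
    climates: tuple = tuple(DEFAULT_CLIMATES)

    def __post_init__(self):
        if self.years < 3:
            raise ValueError("need at least 3 years (2 warm-up + 1 reported)")
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if self.n_countries > self.coarse_rows * self.coarse_cols:
            raise ValueError("more countries than coarse cells")
        if self.n_countries < 1:
            raise ValueError("need at least one country")

    @property
    def n_coarse(self) -> int:
        return self.coarse_rows * self.coarse_cols

    @property
    def warmup_years(self) -> int:
        return 2

    @property
    def reported_years(self) -> range:
        return range(self.start_year + self.warmup_years,
                     self.start_year + self.years)

    @property
    def reference_year(self) -> int:
        ys = self.reported_years
        return ys[len(ys) // 2]

    def climate_of_row(self, row: int) -> ClimateParams:
        return self.climates[row % len(self.climates)]

    def co2_ppm(self, year: int) -> float:
        return self.co2_start_ppm + self.co2_trend_ppm_yr * (year - self.start_year)

    def to_yaml(self, path):
        d = asdict(self)
        d["climates"] = [asdict(c) for c in self.climates]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "climates" in d:
            d["climates"] = tuple(ClimateParams(**c) for c in d["climates"])
        return cls(**d)


@dataclass
class WeatherSeries:
    """Daily meteorology for one coarse cell over all simulated years."""

    year: np.ndarray
    day_of_year: np.ndarray
    precip: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    srad: np.ndarray
    wind: np.ndarray
    rh: np.ndarray

    def __len__(self):
        return len(self.precip)

    def validate(self):
        if np.any(self.precip < 0) or np.any(self.srad < 0) or np.any(self.wind < 0):
            raise ValueError("precip, srad and wind must be non-negative")
        if np.any(self.tmin > self.tmax):
            raise ValueError("tmin must not exceed tmax")
        if np.any((self.rh < 0) | (self.rh > 100)):
            raise ValueError("relative humidity outside [0, 100] %")


def generate_weather(config: WorldConfig, cell: int) -> WeatherSeries:
    """Stochastic daily weather for one coarse cell, deterministic in seed.

    Occurrence: first-order two-state chain with persistence 0.5, tuned so
    the stationary wet-day probability equals the configured one. Amounts:
    gamma (shape 0.75) with mean set by the configured annual total.
    """
    row = cell // config.coarse_cols
    clim = config.climate_of_row(row)
    rng = np.random.default_rng([config.seed, _STREAM_WEATHER, cell])
    n = config.years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), config.years)
    year = np.repeat(np.arange(config.start_year, config.start_year + config.years),
                     DAYS_PER_YEAR)

    # wet/dry occurrence chain
    pi, rho = clim.wet_day_prob, 0.5
    p_wet_after_wet = pi + rho * (1.0 - pi)
    p_wet_after_dry = pi * (1.0 - rho)
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    prev = False
    for i in range(n):
        p = p_wet_after_wet if prev else p_wet_after_dry
        prev = u[i] < p
        wet[i] = prev
    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet and pi > 0:
        mean_wet = clim.mean_annual_precip_mm / (DAYS_PER_YEAR * pi)
        shape = 0.75
        precip[wet] = rng.gamma(shape, mean_wet / shape, size=n_wet)

    # temperature: annual cycle (NH peak around day 201) + AR(1) noise
    phi, sigma = 0.7, 2.0
    z = rng.normal(0.0, sigma * np.sqrt(1.0 - phi**2), size=n)
    noise = signal.lfilter([1.0], [1.0, -phi], z)
    tmean = clim.temp_mean_c + clim.temp_amplitude_c * np.cos(
        2.0 * np.pi * (doy - 201) / DAYS_PER_YEAR) + noise
    diurnal = np.where(wet, 7.0, 11.0)
    tmin = tmean - diurnal / 2.0
    tmax = tmean + diurnal / 2.0

    # shortwave: clear-sky fraction of extraterrestrial, reduced on wet days
    ra = et.extraterrestrial_radiation(clim.latitude_deg, doy)
    frac = np.where(wet, 0.45, 0.72) + 0.04 * rng.standard_normal(n)
    srad = np.clip(ra * np.clip(frac, 0.1, 0.78), 0.0, None)

    rh = np.where(wet, clim.mean_rh_pct + 12.0, clim.mean_rh_pct - 5.0)
    rh = np.clip(rh + 4.0 * rng.standard_normal(n), 5.0, 100.0)
    wind = rng.gamma(4.0, clim.mean_wind_ms / 4.0, size=n)

    ws = WeatherSeries(year=year, day_of_year=doy, precip=precip, tmin=tmin,
                       tmax=tmax, srad=srad, wind=wind, rh=rh)
    ws.validate()
    return ws


@dataclass
class World:
    """The generated world: grids, forcing, soils, crops, areas, census."""

    config: WorldConfig
    country_of_coarse: np.ndarray  # (n_coarse,) int
    texture_of_coarse: list  # texture class name per coarse cell
    elevation_m: np.ndarray  # (n_coarse,)
    groundwater_monthly_m: np.ndarray  # (n_coarse, 12) depth below surface
    crops: dict = field(default_factory=dict)  # name -> CropParameters
    calendars: dict = field(default_factory=dict)  # name -> [CropCalendar]
    policies: dict = field(default_factory=dict)  # name -> IrrigationPolicy
    base_areas_ha: dict = field(default_factory=dict)  # (crop, system) -> fine 2D
    area_trend_pct: dict = field(default_factory=dict)  # (country, crop) -> growth
    census_area_factor: dict = field(default_factory=dict)  # (country, crop, year)
    census_prod_factor: dict = field(default_factory=dict)
    _weather_cache: dict = field(default_factory=dict, repr=False)
    _et0_cache: dict = field(default_factory=dict, repr=False)

    # --- geometry -----------------------------------------------------
    @property
    def fine_shape(self):
        f = self.config.fine_factor
        return (self.config.coarse_rows * f, self.config.coarse_cols * f)

    def coarse_of_fine(self) -> np.ndarray:
        """(fine_rows, fine_cols) array of parent coarse-cell ids."""
        f = self.config.fine_factor
        rows = np.arange(self.fine_shape[0]) // f
        cols = np.arange(self.fine_shape[1]) // f
        return rows[:, None] * self.config.coarse_cols + cols[None, :]

    def country_of_fine(self) -> np.ndarray:
        return self.country_of_coarse[self.coarse_of_fine()]

    def latitude_of_coarse(self, cell: int) -> float:
        return self.config.climate_of_row(cell // self.config.coarse_cols).latitude_deg

    # --- forcing ------------------------------------------------------
    def weather(self, cell: int) -> WeatherSeries:
        if cell not in self._weather_cache:
            self._weather_cache[cell] = generate_weather(self.config, cell)
        return self._weather_cache[cell]

    def et0(self, cell: int) -> np.ndarray:
        if cell not in self._et0_cache:
            w = self.weather(cell)
            self._et0_cache[cell] = et.et0_series(
                w, self.latitude_of_coarse(cell), float(self.elevation_m[cell]))
        return self._et0_cache[cell]

    def hydraulics(self, cell: int):
        return TEXTURE_CLASSES[self.texture_of_coarse[cell]]

    # --- areas and census ---------------------------------------------
    def n_seasons(self, crop: str) -> int:
        return len(self.calendars[crop])

    def trend(self, country: int, crop: str, year: int) -> float:
        g = self.area_trend_pct[(country, crop)]
        return float((1.0 + g) ** (year - self.config.reference_year))

    def cell_area_table(self) -> pd.DataFrame:
        """Long table of fine-cell base areas with country/coarse labels."""
        rows = []
        parent = self.coarse_of_fine()
        country = self.country_of_fine()
        for (crop, system), grid in self.base_areas_ha.items():
            idx = np.nonzero(grid > 0)
            for r, c in zip(*idx):
                rows.append((crop, system, int(r), int(c),
                             int(parent[r, c]), int(country[r, c]),
                             float(grid[r, c])))
        return pd.DataFrame(rows, columns=["crop", "system", "fine_row",
                                           "fine_col", "coarse_cell",
                                           "country", "base_area_ha"])

    def true_national_areas(self) -> pd.DataFrame:
        """Generator-truth national harvested areas (ha) per crop-year.

        Harvested area counts every growing season, so a two-season crop
        contributes twice its physical area.
        """
        cells = self.cell_area_table()
        rows = []
        for year in self.config.reported_years:
            for (country, crop), sub in cells.groupby(["country", "crop"]):
                t = self.trend(country, crop, year)
                area = sub.base_area_ha.sum() * t * self.n_seasons(crop)
                rows.append((country, crop, year, area))
        return pd.DataFrame(rows, columns=["country", "crop", "year",
                                           "harvarea_ha"])

    def census_areas(self) -> pd.DataFrame:
        """Census harvested areas: truth perturbed by the census noise."""
        df = self.true_national_areas().copy()
        df["harvarea_ha"] *= [
            self.census_area_factor[(r.country, r.crop, r.year)]
            for r in df.itertuples()]
        return df

    def finalize_census(self, true_production: pd.DataFrame) -> pd.DataFrame:
        """Build the full census table once simulated production is known.

        ``true_production`` must have columns country, crop, year,
        production_t (the pipeline's pre-scaling national bookkeeping).
        With census_noise = 0 the returned census equals the truth exactly,
        making every downstream scaling factor 1.
        """
        census = self.census_areas().merge(
            true_production, on=["country", "crop", "year"], how="left")
        census["production_t"] = census["production_t"].fillna(0.0) * [
            self.census_prod_factor[(r.country, r.crop, r.year)]
            for r in census.itertuples()]
        return census[["country", "crop", "year", "harvarea_ha", "production_t"]]

    def groundwater_daily(self, cell: int, day_of_year: int) -> float:
        from .soil_water import interpolate_monthly_to_daily
        return interpolate_monthly_to_daily(
            self.groundwater_monthly_m[cell], day_of_year)

    # --- serialization -------------------------------------------------
    def save(self, directory):
        """Write weather NetCDF, area NetCDF, census-area CSV, config YAML."""
        import os

        import xarray as xr
        os.makedirs(directory, exist_ok=True)
        cfg = self.config
        self.config.to_yaml(os.path.join(directory, "world.yaml"))

        lats = np.array([self.latitude_of_coarse(c)
                         for c in range(0, cfg.n_coarse, cfg.coarse_cols)])
        lons = np.arange(cfg.coarse_cols) * 0.5
        w0 = self.weather(0)
        time = np.arange(len(w0))
        shape = (len(time), cfg.coarse_rows, cfg.coarse_cols)
        data = {v: np.zeros(shape) for v in
                ("pr", "tasmin", "tasmax", "rsds", "sfcWind", "hurs")}
        for cell in range(cfg.n_coarse):
            r, c = divmod(cell, cfg.coarse_cols)
            w = self.weather(cell)
            data["pr"][:, r, c] = w.precip
            data["tasmin"][:, r, c] = w.tmin
            data["tasmax"][:, r, c] = w.tmax
            data["rsds"][:, r, c] = w.srad
            data["sfcWind"][:, r, c] = w.wind
            data["hurs"][:, r, c] = w.rh
        ds = xr.Dataset(
            {k: (("time", "lat", "lon"), v) for k, v in data.items()},
            coords={"time": time, "lat": lats, "lon": lons})
        ds.to_netcdf(os.path.join(directory, "weather.nc"), engine="scipy")

        fine = {f"{crop}_{system}": (("lat_fine", "lon_fine"), grid)
                for (crop, system), grid in self.base_areas_ha.items()}
        nr, nc = self.fine_shape
        ds_a = xr.Dataset(fine, coords={"lat_fine": np.arange(nr, dtype=float),
                                        "lon_fine": np.arange(nc, dtype=float)})
        ds_a.to_netcdf(os.path.join(directory, "areas.nc"), engine="scipy")
        self.census_areas().rename(columns={"harvarea_ha": "harvarea_ha"}).to_csv(
            os.path.join(directory, "census_areas.csv"), index=False)


def generate_world(config: WorldConfig) -> World:
    """Build the full world from a configuration (deterministic in seed)."""
    n = config.n_coarse
    rng_soil = np.random.default_rng([config.seed, _STREAM_SOILS])
    rng_gw = np.random.default_rng([config.seed, _STREAM_GROUNDWATER])
    rng_area = np.random.default_rng([config.seed, _STREAM_AREAS])
    rng_census = np.random.default_rng([config.seed, _STREAM_CENSUS])

    # countries: contiguous bands in flattened order
    country = (np.arange(n) * config.n_countries) // n

    texture = [("loam", "clay", "sand")[i] for i in rng_soil.integers(0, 3, n)]
    elevation = rng_soil.uniform(0.0, 400.0, n)

    # groundwater: about a third of cells shallow (< 2 m), the rest deep
    base = np.where(rng_gw.random(n) < 0.35,
                    rng_gw.uniform(1.2, 1.9, n),
                    rng_gw.uniform(4.5, 9.0, n))
    months = np.arange(12)
    seasonal = 0.35 * np.sin(2.0 * np.pi * (months - 3) / 12.0)
    gw_monthly = np.clip(base[:, None] + seasonal[None, :], 0.0, None)

    crops = load_crop_parameters()
    calendars = load_crop_calendars()
    policies = load_irrigation_policies()

    fine_f = config.fine_factor
    fine_shape = (config.coarse_rows * fine_f, config.coarse_cols * fine_f)
    base_areas: dict = {}
    for crop in crops:
        for system in ("rainfed", "irrigated"):
            grid = np.zeros(fine_shape)
            grown = rng_area.random(n) < 0.45
            coarse_area = np.exp(rng_area.normal(7.0, 0.8, n))  # ~1 kha
            for cell in range(n):
                if not grown[cell]:
                    continue
                r, c = divmod(cell, config.coarse_cols)
                w = rng_area.gamma(1.0, 1.0, (fine_f, fine_f))
                w[rng_area.random((fine_f, fine_f)) < 0.3] = 0.0
                if w.sum() == 0.0:
                    w[rng_area.integers(0, fine_f), rng_area.integers(0, fine_f)] = 1.0
                w /= w.sum()
                grid[r * fine_f:(r + 1) * fine_f,
                     c * fine_f:(c + 1) * fine_f] = coarse_area[cell] * w
            base_areas[(crop, system)] = grid

    # guarantee every country at least one rainfed and one irrigated combo
    crop_names = list(crops)
    for ctry in range(config.n_countries):
        cells = np.flatnonzero(country == ctry)
        for system in ("rainfed", "irrigated"):
            present = False
            for crop in crop_names:
                grid = base_areas[(crop, system)]
                for cell in cells:
                    r, c = divmod(int(cell), config.coarse_cols)
                    if grid[r * fine_f:(r + 1) * fine_f,
                            c * fine_f:(c + 1) * fine_f].sum() > 0:
                        present = True
                        break
                if present:
                    break
            if not present:
                crop = crop_names[int(rng_area.integers(0, len(crop_names)))]
                cell = int(cells[int(rng_area.integers(0, len(cells)))])
                r, c = divmod(cell, config.coarse_cols)
                area = float(np.exp(rng_area.normal(7.0, 0.8)))
                base_areas[(crop, system)][r * fine_f, c * fine_f] = area

    trends = {(ctry, crop): float(np.clip(rng_area.normal(0.008, 0.006),
                                          -0.02, 0.03))
              for ctry in range(config.n_countries) for crop in crops}

    area_factor = {}
    prod_factor = {}
    for ctry in range(config.n_countries):
        for crop in crops:
            for year in config.reported_years:
                eps_a, eps_p = rng_census.uniform(-1.0, 1.0, 2) * config.census_noise
                area_factor[(ctry, crop, year)] = 1.0 + eps_a
                prod_factor[(ctry, crop, year)] = 1.0 + eps_p

    return World(config=config, country_of_coarse=country,
                 texture_of_coarse=texture, elevation_m=elevation,
                 groundwater_monthly_m=gw_monthly, crops=crops,
                 calendars=calendars, policies=policies,
                 base_areas_ha=base_areas, area_trend_pct=trends,
                 census_area_factor=area_factor, census_prod_factor=prod_factor)
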