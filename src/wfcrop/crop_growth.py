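"""Heat-unit phenology, canopy cover, biomass and yield formation.

Crop development is driven by growing degree days (GDD). Canopy cover (CC)
grows exponentially from CC0, approaches its maximum CCx with a mirrored
exponential, and declines exponentially during senescence. Transpiration
relative to reference evapotranspiration, multiplied by a CO2-adjusted
normalised water productivity, accumulates above-ground biomass, which a
stress-adjusted harvest index converts to dry yield at harvest.

Three habits are supported: annual, deciduous perennial (bud break instead
of planting, constant rooting depth, a minimum canopy during the leafless
period), and evergreen perennial (near-static canopy, harvested 31 Dec).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CO2_REFERENCE_PPM = 369.41  # year-2000 reference concentration
CO2_RATE_PER_PPM = 0.005  # e-folding rate of the saturating WP response

# harvest-index stress dose-response (per day, multiplicative)
HEAT_FAILURE_PER_DAY = 0.20
WATER_STRESS_PER_DAY = 0.05
HI_STRESS_FLOOR = 0.05
SEVERE_WATER_STRESS_KS = 0.30  # stomatal Ks below this counts as severe

#: stage boundaries as fractions of the maturity GDD requirement
STAGE_FRACTIONS = (0.05, 0.40, 0.80, 1.00)

#: fallow-period cover crop (grasses/short weeds between seasons)
COVER_CROP_CC = 0.30
COVER_CROP_KCB = 0.60
COVER_CROP_ROOT_M = 0.30

MAX_EMERGENCE_DELAY_DAYS = 30
SEASON_EXTENSION_FACTOR = 1.15  # cold-year cap on annual season length
GERMINATION_DEPLETION = 0.7  # seedbed moist if theta above wp + 30% of (fc-wp)

__all__ = [
    "CropParameters",
    "CropCalendar",
    "StageRequirements",
    "StressCoefficients",
    "daily_gdd",
    "canopy_step",
    "rooting_depth",
    "water_stress_coefficients",
    "co2_factor",
    "biomass_increment",
    "yield_at_harvest",
    "adjust_calendar",
    "calibrate_heat_units",
    "NonViableCellError",
]


class NonViableCellError(RuntimeError):
    """The cell's climate accumulates no heat units over the crop window."""


@dataclass(frozen=True)
class CropParameters:
    """Parameter set of one crop archetype.

    GDD requirements here are *reference* values; per-cell values come from
    :func:`calibrate_heat_units`. ``wc`` is the water content of fresh
    harvested mass, used for the dry-to-fresh yield conversion downstream.
    ``irrigation_threshold`` is the root-zone depletion fraction that
    triggers irrigation (0.25 for stress-sensitive crops up to 0.50 for
    tolerant ones); rice ignores it and is flooded instead.
    """

    name: str
    habit: str  # annual | deciduous_perennial | evergreen_perennial
    tbase: float
    tupp: float
    gdd_maturity: float
    cc0: float
    ccx: float
    cgc: float  # canopy growth coefficient, per GDD
    cdc: float  # canopy decline coefficient, per GDD
    zmin: float
    zmax: float
    kcb: float
    wp_star: float  # t/ha per unit of seasonal sum(Tr/ET0)
    hi0: float
    p_up: float
    irrigation_threshold: float
    tcrit_heat: float
    wc: float
    co2_response: float
    cc_min_leafless: float = 0.0
    budbreak_gdd: float = 0.0
    is_rice: bool = False
    shallow_soil: bool = False

    def __post_init__(self):
        if not (0.0 < self.cc0 < self.ccx <= 1.0):
            raise ValueError("require 0 < CC0 < CCx <= 1")
        if self.zmin > self.zmax:
            raise ValueError("Zmin must not exceed Zmax")
        if not (0.0 < self.hi0 < 1.0):
            raise ValueError("HI0 must lie in (0, 1)")
        if not self.is_rice and not (0.25 <= self.irrigation_threshold <= 0.50):
            raise ValueError("irrigation threshold must lie in [0.25, 0.50]")
        if self.habit not in ("annual", "deciduous_perennial", "evergreen_perennial"):
            raise ValueError(f"unknown habit {self.habit!r}")

    def stage_requirements(self, maturity_gdd=None) -> "StageRequirements":
        m = self.gdd_maturity if maturity_gdd is None else maturity_gdd
        f = STAGE_FRACTIONS
        return StageRequirements(f[0] * m, f[1] * m, f[2] * m, f[3] * m)


@dataclass(frozen=True)
class CropCalendar:
    """Reference planting (or bud-break) and harvest days of year."""

    planting_doy: int
    harvest_doy: int

    @property
    def season_length_days(self) -> int:
        length = self.harvest_doy - self.planting_doy
        if length <= 0:
            length += 365
        return length


@dataclass(frozen=True)
class StageRequirements:
    """Cumulative GDD needed to reach each development stage."""

    emergence: float
    max_canopy: float
    senescence: float
    maturity: float


@dataclass(frozen=True)
class StressCoefficients:
    """Water-stress multipliers in [0, 1]; 1 means unstressed."""

    expansion: float
    stomatal: float


def daily_gdd(tmax, tmin, tbase: float, tupp: float):
    """Growing degree days for one day.

    Daily extremes are first limited to the crop's operating range (tmax
    capped at Tupp; tmin raised to at least Tbase, capped at Tupp), then
    GDD = max(0, mean - Tbase). Vectorises over arrays.
    """
    tmax = np.minimum(np.asarray(tmax, dtype=float), tupp)
    tmin = np.clip(np.asarray(tmin, dtype=float), tbase, tupp)
    gdd = (tmax + tmin) / 2.0 - tbase
    return np.maximum(gdd, 0.0)


def canopy_step(cc: float, cum_gdd: float, gdd_today: float,
                params: CropParameters, requirements: StageRequirements,
                ks_expansion: float = 1.0) -> float:
    """Advance canopy cover by one day of thermal time.

    Growth phase: exponential growth from CC0 while CC <= CCx/2, then a
    mirrored exponential approach to CCx; water stress scales the growth
    coefficient through ``ks_expansion``. Senescence: exponential decline
    with CDC. Evergreen perennials hold CC at CCx throughout.
    """
    if params.habit == "evergreen_perennial":
        return params.ccx
    if cum_gdd < requirements.emergence:
        # deciduous perennials keep a minimum canopy (branches, trunk)
        return params.cc_min_leafless if params.habit == "deciduous_perennial" else 0.0
    if cc < params.cc0:
        cc = params.cc0
    if cum_gdd < requirements.senescence:
        rate = params.cgc * ks_expansion * gdd_today
        if cc <= params.ccx / 2.0:
            cc = cc * np.exp(rate)
        else:
            cc = params.ccx - (params.ccx - cc) * np.exp(-rate)
        return min(cc, params.ccx)
    return max(cc * np.exp(-params.cdc * gdd_today), 0.0)


def rooting_depth(cum_gdd: float, params: CropParameters,
                  requirements: StageRequirements) -> float:
    """Effective rooting depth (m): linear in GDD up to maximum canopy.

    Perennials keep a constant (maximum) rooting depth.
    """
    if params.habit != "annual":
        return params.zmax
    if cum_gdd <= 0.0:
        return params.zmin
    f = min(cum_gdd / max(requirements.max_canopy, 1e-9), 1.0)
    return params.zmin + (params.zmax - params.zmin) * f


def water_stress_coefficients(depletion_mm: float, taw_mm: float,
                              p_up: float) -> StressCoefficients:
    """Stress multipliers from root-zone depletion.

    Each coefficient is 1 while depletion stays below its threshold
    fraction of TAW and falls linearly to 0 at full depletion. Canopy
    expansion is the more sensitive process and engages at 0.7 of the
    stomatal threshold.
    """
    if taw_mm <= 0:
        raise ValueError("TAW must be positive")
    dr = min(max(depletion_mm, 0.0), taw_mm)

    def ks(p: float) -> float:
        if dr <= p * taw_mm:
            return 1.0
        return max((taw_mm - dr) / (taw_mm * (1.0 - p)), 0.0)

    return StressCoefficients(expansion=ks(0.7 * p_up), stomatal=ks(p_up))


def co2_factor(co2_ppm: float, co2_response: float,
               co2_ref_ppm: float = CO2_REFERENCE_PPM) -> float:
    """Saturating water-productivity adjustment, exactly 1 at the reference.

    ``co2_response`` is the asymptotic fractional gain at very high CO2;
    C3 archetypes respond several times more strongly than C4 ones.
    """
    return 1.0 + co2_response * (1.0 - np.exp(-CO2_RATE_PER_PPM * (co2_ppm - co2_ref_ppm)))


def biomass_increment(transpiration_mm: float, et0_mm: float, wp_star: float,
                      co2_ppm: float = CO2_REFERENCE_PPM,
                      co2_response: float = 0.0) -> float:
    """Daily above-ground biomass gain (t/ha): WP* x f_CO2 x Tr/ET0."""
    if et0_mm <= 0.0:
        return 0.0
    return wp_star * co2_factor(co2_ppm, co2_response) * (transpiration_mm / et0_mm)


def yield_at_harvest(biomass_t_ha: float, params: CropParameters,
                     heat_failure_days: int = 0,
                     severe_water_stress_days: int = 0) -> float:
    """Dry yield (t/ha) = B x HI0 x f_stress.

    Each flowering day with tmax above the pollination-failure threshold
    multiplies the harvest index by (1 - 0.20); each day of severe water
    stress during yield formation by (1 - 0.05); the combined factor is
    floored at 0.05 (near-total but never exactly total failure).
    """
    f_heat = (1.0 - HEAT_FAILURE_PER_DAY) ** max(heat_failure_days, 0)
    f_water = (1.0 - WATER_STRESS_PER_DAY) ** max(severe_water_stress_days, 0)
    f = max(f_heat * f_water, HI_STRESS_FLOOR)
    return biomass_t_ha * params.hi0 * f


def adjust_calendar(planting_index: int, gdd: np.ndarray,
                    seedbed_moist: np.ndarray,
                    requirements: StageRequirements,
                    calendar: CropCalendar):
    """Realised (emergence, harvest) day indices for one annual season.

    Emergence waits for sufficient seedbed moisture, at most 30 days after
    planting. Heat units then accumulate from emergence; harvest falls on
    the day the maturity requirement is met, capped at 1.15x the reference
    season length after planting (cold years), and can come earlier than
    the reference date in warm years. Returns ``(emergence, harvest,
    matured)`` as day indices into the simulation axis plus a flag; returns
    ``None`` if the cap exceeds the series.
    """
    n = len(gdd)
    emergence = planting_index
    for d in range(planting_index,
                   min(planting_index + MAX_EMERGENCE_DELAY_DAYS, n)):
        emergence = d
        if seedbed_moist[d]:
            break
    cap = planting_index + int(np.ceil(
        SEASON_EXTENSION_FACTOR * calendar.season_length_days))
    if cap >= n:
        return None
    cum = 0.0
    for d in range(emergence, cap + 1):
        cum += gdd[d]
        if cum >= requirements.maturity:
            return emergence, d, True
    return emergence, cap, False


def calibrate_heat_units(weather, calendar: CropCalendar,
                         params: CropParameters,
                         stage_fractions=STAGE_FRACTIONS) -> StageRequirements:
    """Per-cell GDD requirements from the local mean climate.

    The maturity requirement is the mean cumulative GDD between the
    reference planting and harvest dates over all calibration years; stage
    requirements are fixed fractions of it. Cells that accumulate no heat
    over the window are non-viable.
    """
    gdd = daily_gdd(weather.tmax, weather.tmin, params.tbase, params.tupp)
    years = np.unique(weather.year)
    sums = []
    for y in years:
        start_idx = np.flatnonzero((weather.year == y)
                                   & (weather.day_of_year == calendar.planting_doy))
        if start_idx.size == 0:
            continue
        start = int(start_idx[0])
        length = calendar.season_length_days
        if start + length >= len(gdd):
            continue
        sums.append(gdd[start:start + length + 1].sum())
    if not sums:
        raise NonViableCellError("no complete reference season in the forcing")
    maturity = float(np.mean(sums))
    if maturity <= 0.0:
        raise NonViableCellError("no heat units accumulate over the crop window")
    f = stage_fractions
    return StageRequirements(f[0] * maturity, f[1] * maturity,
                             f[2] * maturity, f[3] * maturity)
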