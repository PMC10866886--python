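"""Multi-year simulation of one (cell, crop, system) combination.

Couples weather -> ET0 -> irrigation -> soil water balance -> crop growth
day by day over all simulated years, including a two-year warm-up whose
seasons are discarded, cover-crop fallow periods in between seasons, and
emission of one :class:`SeasonResult` per completed growing season (one
per calendar year for perennials, whose crop water use is accumulated over
the entire calendar year). Crop water use (CWU) and yields are attributed
to the year of harvest, so a season may span two calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crop_growth as cg
from . import soil_water as sw
from .irrigation import RICE_BUND_HEIGHT_MM, irrigation_decision
from .soil_water import BLUE_CR, BLUE_I, GREEN, N_COLOURS

FALLOW, AWAIT_EMERGENCE, SEASON = 0, 1, 2
DAYS_PER_YEAR = 365

__all__ = ["SeasonResult", "RunLedger", "RunResult", "run_cell",
           "attribute_to_harvest_year"]


@dataclass
class SeasonResult:
    """Green/blue crop water use and dry yield of one completed season."""

    crop: str
    season: int  # calendar entry index (rice has two per year)
    system: str
    planting_year: int
    harvest_year: int
    emergence_doy: int
    harvest_doy: int
    cwu_green: float
    cwu_blue_cr: float
    cwu_blue_i: float
    dry_yield_t_ha: float
    irrigation_applied_mm: float
    matured: bool

    @property
    def cwu_total(self) -> float:
        return self.cwu_green + self.cwu_blue_cr + self.cwu_blue_i


def attribute_to_harvest_year(season: SeasonResult) -> int:
    """All CWU and yield of a season are reported under its harvest year,
    even when planting happened the previous calendar year (winter crops)."""
    return season.harvest_year


@dataclass
class RunLedger:
    """Cumulative colour-split mass bookkeeping over the whole run (mm)."""

    inflow: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    outflow: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    initial_storage: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    final_storage: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))

    def residual(self) -> np.ndarray:
        """inflow - outflow - (final - initial); ~0 when mass is conserved."""
        return self.inflow - self.outflow - (self.final_storage - self.initial_storage)


@dataclass
class RunResult:
    seasons: list
    ledger: RunLedger
    non_viable_reason: str | None = None
    warmup_end_total_mm: float | None = None  # soil water when warm-up ends
    final_state: "sw.SoilState | None" = None


def _budbreak_day(gdd_year: np.ndarray, requirement: float) -> int | None:
    """First day-index whose trailing 10-day GDD sum meets the requirement."""
    rolling = np.convolve(gdd_year, np.ones(10), mode="full")[: len(gdd_year)]
    hits = np.flatnonzero(rolling >= requirement)
    return int(hits[0]) if hits.size else None


def run_cell(world, cell: int, crop_name: str, system: str,
             initial_state: sw.SoilState | None = None,
             warmup_years: int | None = None) -> RunResult:
    """Simulate all years of one crop on one coarse cell and system.

    Returns the per-season results (warm-up seasons discarded, in-progress
    seasons at the simulation end dropped) together with a colour mass
    ledger kept independently of the soil-state update, for conservation
    checks. Deterministic: identical inputs give identical results.
    """
    config = world.config
    params: cg.CropParameters = world.crops[crop_name]
    calendars = world.calendars[crop_name]
    policy = world.policies[crop_name]
    profile = sw.SoilProfile.shallow() if params.shallow_soil else sw.SoilProfile.deep()
    hyd = world.hydraulics(cell)
    weather = world.weather(cell)
    et0 = world.et0(cell)
    n_days = len(weather)
    warmup = config.warmup_years if warmup_years is None else warmup_years
    first_reported = config.start_year + warmup

    gdd = cg.daily_gdd(weather.tmax, weather.tmin, params.tbase, params.tupp)
    gw_doy = np.array([world.groundwater_daily(cell, d)
                       for d in range(1, DAYS_PER_YEAR + 1)])

    # per-calendar heat-unit calibration; a non-viable calendar entry is
    # simply never planted
    requirements: list[cg.StageRequirements | None] = []
    for cal in calendars:
        try:
            requirements.append(cg.calibrate_heat_units(weather, cal, params))
        except cg.NonViableCellError:
            requirements.append(None)
    if all(r is None for r in requirements):
        return RunResult([], RunLedger(),
                         non_viable_reason="no heat units over any crop window")

    if initial_state is None:
        theta0 = hyd.theta_wp + 0.5 * (hyd.theta_fc - hyd.theta_wp)
        state = sw.SoilState.at_content(profile, hyd, theta=theta0)
    else:
        state = initial_state.copy()

    ledger = RunLedger(initial_storage=state.colour_storage())
    seasons: list[SeasonResult] = []

    is_perennial = params.habit != "annual"
    is_deciduous = params.habit == "deciduous_perennial"
    is_evergreen = params.habit == "evergreen_perennial"

    # deciduous bud-break day-of-year per calendar year, from thermal time
    budbreak: dict[int, int | None] = {}
    if is_deciduous:
        for iy, y in enumerate(range(config.start_year,
                                     config.start_year + config.years)):
            sl = slice(iy * DAYS_PER_YEAR, (iy + 1) * DAYS_PER_YEAR)
            bb = _budbreak_day(np.asarray(gdd[sl]), params.budbreak_gdd)
            budbreak[y] = None if bb is None else bb + 1  # to day-of-year

    germ_theta = hyd.theta_wp + 0.3 * (hyd.theta_fc - hyd.theta_wp)
    dz0_mm = profile.thicknesses[0] * 1000.0
    wetted = policy.wetted_fraction if system == "irrigated" else 1.0

    phase = SEASON if is_evergreen else FALLOW
    season_idx = 0
    pending: dict[int, int] = {}  # calendar index -> day planting became due
    cum_gdd = 0.0
    cc = params.ccx if is_evergreen else 0.0
    biomass = 0.0
    heat_days = 0
    water_days = 0
    irrigation_total = 0.0
    cwu_season = np.zeros(N_COLOURS)
    cwu_year = np.zeros(N_COLOURS)
    plant_day = 0
    emergence_day = 0
    planting_year = config.start_year
    pending_yield: list[SeasonResult] = []  # deciduous: awaiting 31 Dec
    warmup_end_total: float | None = None

    for d in range(n_days):
        doy = int(weather.day_of_year[d])
        year = int(weather.year[d])

        # --- planting triggers
        if not is_evergreen:
            for si, cal in enumerate(calendars):
                if requirements[si] is None:
                    continue
                if is_deciduous:
                    due = budbreak.get(year) is not None and doy == budbreak[year]
                else:
                    due = doy == cal.planting_doy
                if due:
                    pending[si] = d
            if phase == FALLOW and pending:
                si = min(pending, key=pending.get)
                season_idx = si
                plant_day = d
                planting_year = year
                emergence_day = d
                cum_gdd = 0.0
                biomass = 0.0
                heat_days = water_days = 0
                irrigation_total = 0.0
                cwu_season[:] = 0.0
                # rice is transplanted into flooded paddies, deciduous buds
                # break on their own; only sown annuals wait for moisture
                if is_deciduous or params.is_rice:
                    phase = SEASON
                    cc = params.cc_min_leafless if is_deciduous else 0.0
                else:
                    phase = AWAIT_EMERGENCE
                    cc = 0.0
                pending.pop(si, None)
            # stale planting windows expire after 30 days
            pending = {k: v for k, v in pending.items() if d - v <= 30}

        # --- emergence wait (sown annuals): seedbed must be moist
        if phase == AWAIT_EMERGENCE:
            moist = state.w[0] / dz0_mm >= germ_theta
            if moist or d - plant_day >= cg.MAX_EMERGENCE_DELAY_DAYS:
                phase = SEASON
                emergence_day = d
                cum_gdd = 0.0
                cc = 0.0

        reqs = requirements[season_idx] or requirements[0]
        rice_flooded = params.is_rice and phase == SEASON
        bund = RICE_BUND_HEIGHT_MM if rice_flooded else 0.0

        # --- crop surface for today
        if phase == SEASON:
            cum_gdd += float(gdd[d])
            z = cg.rooting_depth(cum_gdd, params, reqs)
            kcb = params.kcb
        elif phase == AWAIT_EMERGENCE:
            z = params.zmin
            cc = 0.0
            kcb = params.kcb
        elif is_deciduous:  # leafless period
            cc = params.cc_min_leafless
            z = params.zmax
            kcb = params.kcb
        else:  # fallow cover crop
            cc = cg.COVER_CROP_CC
            z = cg.COVER_CROP_ROOT_M
            kcb = cg.COVER_CROP_KCB

        dr, taw = sw.root_zone_depletion(state, hyd, profile, z)
        p_up = params.p_up if phase == SEASON else 0.5
        ks = cg.water_stress_coefficients(dr, taw, p_up)
        if phase == SEASON:
            cc = cg.canopy_step(cc, cum_gdd, float(gdd[d]), params, reqs,
                                ks.expansion)

        # --- irrigation decision (irrigated systems, in-season only)
        irr = 0.0
        if system == "irrigated" and phase == SEASON:
            irr = irrigation_decision(dr, taw, policy, system,
                                      ponding_mm=state.ponding)
            irrigation_total += irr

        state, fx = sw.step_water_balance(
            state, float(weather.precip[d]), float(et0[d]), cc, z, irr,
            float(gw_doy[doy - 1]), hyd, profile, system=system,
            crop_is_rice=params.is_rice, bund_height_mm=bund,
            kcb=kcb, ks_stomatal=ks.stomatal, wetted_fraction=wetted)

        ledger.inflow += fx.inflow()
        ledger.outflow += fx.outflow()
        if d == warmup * DAYS_PER_YEAR - 1:
            warmup_end_total = state.total()

        et_colour = fx.evaporation_out + fx.transpiration_out
        if phase == SEASON:
            cwu_season += et_colour
        if is_perennial:
            cwu_year += et_colour

        # --- growth and stress bookkeeping
        if phase == SEASON:
            if float(et0[d]) > 0.0:
                biomass += cg.biomass_increment(
                    float(fx.transpiration_out.sum()), float(et0[d]),
                    params.wp_star, config.co2_ppm(year), params.co2_response)
            if not is_evergreen:
                flowering = (reqs.max_canopy <= cum_gdd
                             <= reqs.max_canopy + 0.1 * reqs.maturity)
                if flowering and float(weather.tmax[d]) > params.tcrit_heat:
                    heat_days += 1
                if (cum_gdd >= reqs.max_canopy
                        and ks.stomatal < cg.SEVERE_WATER_STRESS_KS):
                    water_days += 1

        # --- harvest checks (annual + deciduous)
        if phase == SEASON and not is_evergreen:
            cap_days = int(np.ceil(cg.SEASON_EXTENSION_FACTOR
                                   * calendars[season_idx].season_length_days))
            matured = cum_gdd >= reqs.maturity
            if matured or d - plant_day >= cap_days:
                dry = cg.yield_at_harvest(biomass, params, heat_days, water_days)
                if state.ponding > 0.0:  # paddy drained at harvest
                    ledger.outflow += state.ponding * state.ponding_frac
                    state.ponding = 0.0
                result = SeasonResult(
                    crop=crop_name, season=season_idx, system=system,
                    planting_year=planting_year, harvest_year=year,
                    emergence_doy=int(weather.day_of_year[emergence_day]),
                    harvest_doy=doy,
                    cwu_green=float(cwu_season[GREEN]),
                    cwu_blue_cr=float(cwu_season[BLUE_CR]),
                    cwu_blue_i=float(cwu_season[BLUE_I]),
                    dry_yield_t_ha=dry,
                    irrigation_applied_mm=irrigation_total, matured=matured)
                if is_deciduous:
                    pending_yield.append(result)
                elif year >= first_reported:
                    seasons.append(result)
                phase = FALLOW
                cc = params.cc_min_leafless if is_deciduous else 0.0
                biomass = 0.0

        # --- perennial calendar-year emission on 31 Dec
        if is_perennial and doy == DAYS_PER_YEAR:
            if is_evergreen:
                dry = cg.yield_at_harvest(biomass, params, 0, water_days)
                if year >= first_reported:
                    seasons.append(SeasonResult(
                        crop=crop_name, season=0, system=system,
                        planting_year=year, harvest_year=year,
                        emergence_doy=1, harvest_doy=DAYS_PER_YEAR,
                        cwu_green=float(cwu_year[GREEN]),
                        cwu_blue_cr=float(cwu_year[BLUE_CR]),
                        cwu_blue_i=float(cwu_year[BLUE_I]),
                        dry_yield_t_ha=dry,
                        irrigation_applied_mm=irrigation_total, matured=True))
                biomass = 0.0
                water_days = 0
                irrigation_total = 0.0
            else:
                harvested = [r for r in pending_yield if r.harvest_year == year]
                if year >= first_reported:
                    seasons.append(SeasonResult(
                        crop=crop_name, season=0, system=system,
                        planting_year=year, harvest_year=year,
                        emergence_doy=(harvested[0].emergence_doy
                                       if harvested else 1),
                        harvest_doy=(harvested[0].harvest_doy
                                     if harvested else DAYS_PER_YEAR),
                        cwu_green=float(cwu_year[GREEN]),
                        cwu_blue_cr=float(cwu_year[BLUE_CR]),
                        cwu_blue_i=float(cwu_year[BLUE_I]),
                        dry_yield_t_ha=sum(r.dry_yield_t_ha for r in harvested),
                        irrigation_applied_mm=sum(r.irrigation_applied_mm
                                                  for r in harvested),
                        matured=any(r.matured for r in harvested)))
                pending_yield = [r for r in pending_yield
                                 if r.harvest_year != year]
            cwu_year[:] = 0.0

    ledger.final_storage = state.colour_storage()
    return RunResult(seasons, ledger, warmup_end_total_mm=warmup_end_total,
                     final_state=state)
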