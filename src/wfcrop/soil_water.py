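"""Daily vertical soil water balance with green/blue water-colour tracing.

The soil profile is a stack of compartments. Each compartment stores water
(mm) together with the fractions of that water belonging to three "colours":

* ``green``   — from precipitation,
* ``blue_i``  — blue water applied as irrigation,
* ``blue_cr`` — blue water entering by capillary rise from a shallow water
  table.

Every inflow mixes with the pre-stored water of the receiving compartment
(perfect mixing), and every outflow — runoff, soil evaporation,
transpiration, drainage, deep percolation — carries the colour composition
of its donor store. Summing the colour-split evapotranspiration over a
growing season yields green and blue crop water use (CWU).

Daily event order within :func:`step_water_balance` is fixed as:
capillary rise -> rainfall partition (runoff/infiltration) -> irrigation
-> drainage cascade -> evaporation and transpiration extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# colour channel indices
GREEN, BLUE_I, BLUE_CR = 0, 1, 2
COLOURS = ("green", "blue_i", "blue_cr")
N_COLOURS = 3

# capillary rise: linear decrease from full strength at <=1 m water-table
# depth to zero at 4 m, gated by sub-field-capacity dryness of the bottom
# compartment
CR_MAX_MM_DAY = 5.0
CR_CUTOFF_M = 4.0
CR_DRAINED_M = 1.0  # surfacing water tables treated as drained to 1 m

# rice paddies: percolation out of the ponded layer into the profile
PONDING_PERC_MM_DAY = 10.0

__all__ = [
    "GREEN",
    "BLUE_I",
    "BLUE_CR",
    "COLOURS",
    "SoilHydraulics",
    "SoilProfile",
    "SoilState",
    "DailyFluxes",
    "OverfillError",
    "curve_number_runoff",
    "mix_inflow",
    "infiltrate",
    "drain",
    "capillary_rise",
    "interpolate_monthly_to_daily",
    "root_weights",
    "root_zone_depletion",
    "extract_evapotranspiration",
    "step_water_balance",
]


class OverfillError(ValueError):
    """Inflow exceeds compartment capacity; excess must be routed onward."""

    def __init__(self, excess_mm: float):
        super().__init__(f"inflow exceeds capacity by {excess_mm:.6f} mm")
        self.excess_mm = excess_mm


@dataclass(frozen=True)
class SoilHydraulics:
    """Hydraulic parameters of one texture class.

    theta_sat/theta_fc/theta_wp are volumetric water contents (m3/m3) at
    saturation, field capacity and wilting point; tau is the fraction of the
    above-field-capacity excess that drains per day; curve_number controls
    storm runoff; rew is the readily evaporable water of the surface layer.
    """

    theta_sat: float
    theta_fc: float
    theta_wp: float
    tau: float
    curve_number: float
    rew: float
    name: str = "custom"

    def __post_init__(self):
        if not (0.0 < self.theta_wp < self.theta_fc < self.theta_sat <= 1.0):
            raise ValueError("require 0 < theta_wp < theta_fc < theta_sat <= 1")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("drainage coefficient tau must lie in (0, 1]")
        if not (0.0 < self.curve_number < 100.0):
            raise ValueError("curve number must lie in (0, 100)")


#: pedotransfer table for the three texture classes of the synthetic world
TEXTURE_CLASSES = {
    "sand": SoilHydraulics(0.36, 0.15, 0.06, 0.80, 65.0, 4.0, name="sand"),
    "loam": SoilHydraulics(0.46, 0.31, 0.15, 0.50, 75.0, 9.0, name="loam"),
    "clay": SoilHydraulics(0.50, 0.39, 0.27, 0.30, 85.0, 10.0, name="clay"),
}


class SoilProfile:
    """Vertical discretisation of the soil column into compartments."""

    def __init__(self, thicknesses_m):
        t = np.asarray(thicknesses_m, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(t <= 0):
            raise ValueError("thicknesses must be a non-empty positive 1-D sequence")
        self.thicknesses = t
        self.n = t.size
        self.depth = float(t.sum())
        self.bottoms = np.cumsum(t)
        self.tops = self.bottoms - t
        self.centres = (self.tops + self.bottoms) / 2.0

    @classmethod
    def deep(cls) -> "SoilProfile":
        """Default 3 m profile in 8 compartments (0.1-0.7 m thick)."""
        return cls([0.1, 0.2, 0.3, 0.4, 0.5, 0.5, 0.6, 0.4])

    @classmethod
    def shallow(cls) -> "SoilProfile":
        """2 m profile in 7 compartments for shallow-rooting crops."""
        return cls([0.1, 0.15, 0.25, 0.3, 0.35, 0.4, 0.45])

    def capacity_mm(self, theta: float) -> np.ndarray:
        """Per-compartment storage (mm) at volumetric content ``theta``."""
        return theta * self.thicknesses * 1000.0


@dataclass
class SoilState:
    """Water storage and colour composition of the whole column.

    ``w`` holds mm of water per compartment; ``frac`` the (n, 3) colour
    fractions, summing to 1 wherever w > 0. ``ponding``/``ponding_frac``
    form an optional surface store used for flooded rice.
    ``evap_depletion`` tracks mm evaporated from the surface layer since it
    was last wetted (two-stage evaporation bookkeeping).
    """

    w: np.ndarray
    frac: np.ndarray
    ponding: float = 0.0
    ponding_frac: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    evap_depletion: float = 0.0

    @classmethod
    def at_content(cls, profile: SoilProfile, hydraulics: SoilHydraulics,
                   theta=None, colour: int = GREEN) -> "SoilState":
        """Uniform initial state; defaults to field capacity, all one colour."""
        theta = hydraulics.theta_fc if theta is None else theta
        w = profile.capacity_mm(theta).copy()
        frac = np.zeros((profile.n, N_COLOURS))
        frac[:, colour] = 1.0
        return cls(w=w, frac=frac)

    def copy(self) -> "SoilState":
        return SoilState(
            w=self.w.copy(),
            frac=self.frac.copy(),
            ponding=self.ponding,
            ponding_frac=self.ponding_frac.copy(),
            evap_depletion=self.evap_depletion,
        )

    def colour_storage(self) -> np.ndarray:
        """Total stored water per colour (mm), including ponding."""
        return self.w @ self.frac + self.ponding * self.ponding_frac

    def total(self) -> float:
        return float(self.w.sum() + self.ponding)

    def validate(self):
        if np.any(self.w < -1e-9):
            raise ValueError("negative storage")
        mask = self.w > 1e-12
        if mask.any() and not np.allclose(self.frac[mask].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("colour fractions must sum to 1 where water is stored")


@dataclass
class DailyFluxes:
    """Colour-split fluxes of one day; every array is (green, blue_i, blue_cr) mm."""

    rain_in: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    irrigation_in: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    capillary_in: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    runoff_out: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    evaporation_out: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    transpiration_out: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))
    deep_percolation_out: np.ndarray = field(default_factory=lambda: np.zeros(N_COLOURS))

    def inflow(self) -> np.ndarray:
        return self.rain_in + self.irrigation_in + self.capillary_in

    def outflow(self) -> np.ndarray:
        return (self.runoff_out + self.evaporation_out
                + self.transpiration_out + self.deep_percolation_out)


# ---------------------------------------------------------------------------
# elementary operations


def curve_number_runoff(precip_mm: float, curve_number: float,
                        bund_height_mm: float = 0.0, ponded_mm: float = 0.0) -> float:
    """Daily storm runoff (mm) by the SCS curve-number method.

    With bunds (flooded rice), runoff is suppressed entirely until ponded
    water exceeds the bund height; only the excess spills.
    """
    if precip_mm < 0:
        raise ValueError("precipitation must be non-negative")
    if not (0.0 < curve_number < 100.0):
        raise ValueError("curve number must lie in (0, 100)")
    if bund_height_mm > 0.0:
        return max(0.0, ponded_mm + precip_mm - bund_height_mm)
    s = 254.0 * (100.0 / curve_number - 1.0)
    ia = 0.2 * s
    if precip_mm <= ia:
        return 0.0
    return (precip_mm - ia) ** 2 / (precip_mm + 0.8 * s)


def _mix(w: np.ndarray, frac: np.ndarray, i: int, amounts: np.ndarray):
    """In-place: add a colour-amount vector (mm per colour) into compartment i."""
    total = amounts.sum()
    if total <= 0.0:
        return
    new_w = w[i] + total
    frac[i] = (w[i] * frac[i] + amounts) / new_w
    w[i] = new_w


def mix_inflow(state: SoilState, compartment: int, amount_mm: float, colour: int,
               capacity_mm: float | None = None) -> SoilState:
    """Mix an inflow of one colour into a compartment (mass-weighted).

    If ``capacity_mm`` is given and the inflow would overfill the store,
    an :class:`OverfillError` carrying the excess is raised so the caller
    can route it onward — overfilling is never silently clipped.
    """
    if amount_mm < 0:
        raise ValueError("inflow must be non-negative")
    if capacity_mm is not None and state.w[compartment] + amount_mm > capacity_mm + 1e-9:
        raise OverfillError(state.w[compartment] + amount_mm - capacity_mm)
    out = state.copy()
    amounts = np.zeros(N_COLOURS)
    amounts[colour] = amount_mm
    _mix(out.w, out.frac, compartment, amounts)
    return out


def _infiltrate_inplace(state: SoilState, amounts: np.ndarray,
                        hydraulics: SoilHydraulics, profile: SoilProfile) -> np.ndarray:
    """Route a colour-amount vector downward, filling compartments to
    saturation top-down; whatever passes the bottom leaves as deep
    percolation (returned per colour)."""
    moving = amounts.astype(float).copy()
    sat = profile.capacity_mm(hydraulics.theta_sat)
    for i in range(profile.n):
        total = moving.sum()
        if total <= 1e-15:
            moving[:] = 0.0
            break
        room = sat[i] - state.w[i]
        if room <= 0.0:
            continue
        take = min(total, room)
        taken = moving * (take / total)
        _mix(state.w, state.frac, i, taken)
        moving -= taken
    return moving


def infiltrate(state: SoilState, amount_mm: float, colour: int,
               hydraulics: SoilHydraulics, profile: SoilProfile):
    """Infiltrate an inflow of one colour at the surface.

    Returns ``(new_state, deep_percolation_by_colour)``.
    """
    if amount_mm < 0:
        raise ValueError("inflow must be non-negative")
    out = state.copy()
    amounts = np.zeros(N_COLOURS)
    amounts[colour] = amount_mm
    dp = _infiltrate_inplace(out, amounts, hydraulics, profile)
    return out, dp


def _drain_inplace(state: SoilState, hydraulics: SoilHydraulics,
                   profile: SoilProfile) -> np.ndarray:
    """Tau-cascade: per compartment top-down, a fraction tau of the excess
    above field capacity moves to the compartment below (carrying donor
    colours); bottom drainage leaves as deep percolation."""
    fc = profile.capacity_mm(hydraulics.theta_fc)
    sat = profile.capacity_mm(hydraulics.theta_sat)
    moving = np.zeros(N_COLOURS)
    for i in range(profile.n):
        # receive from above, up to saturation; surplus keeps moving down
        total = moving.sum()
        if total > 0.0:
            room = max(sat[i] - state.w[i], 0.0)
            take = min(total, room)
            if take > 0.0:
                taken = moving * (take / total)
                _mix(state.w, state.frac, i, taken)
                moving -= taken
        # drain own excess above field capacity
        excess = state.w[i] - fc[i]
        if excess > 0.0:
            out = hydraulics.tau * excess
            moving += out * state.frac[i]
            state.w[i] -= out
    return moving


def drain(state: SoilState, hydraulics: SoilHydraulics, profile: SoilProfile):
    """Drainage cascade. Returns ``(new_state, deep_percolation_by_colour)``."""
    out = state.copy()
    dp = _drain_inplace(out, hydraulics, profile)
    return out, dp


def interpolate_monthly_to_daily(monthly: np.ndarray, day_of_year: int) -> float:
    """Linear interpolation of a 12-value monthly climatology to one day.

    Monthly values are anchored at mid-month and wrapped across new year.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape != (12,):
        raise ValueError("monthly climatology must have 12 values")
    mids = np.array([15.5, 45.0, 74.5, 105.0, 135.5, 166.0,
                     196.5, 227.5, 258.0, 288.5, 319.0, 349.5])
    x = np.concatenate([[mids[-1] - 365.0], mids, [mids[0] + 365.0]])
    y = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    return float(np.interp(float(day_of_year), x, y))


def capillary_rise(state: SoilState, water_table_depth_m: float, system: str,
                   crop_is_rice: bool, hydraulics: SoilHydraulics,
                   profile: SoilProfile):
    """Capillary inflow (colour ``blue_cr``) into the bottom compartment.

    Only rainfed crops access shallow groundwater — farmers are assumed not
    to irrigate land that is fed from below — with flooded rice as the only
    irrigated exception. Water tables at the surface are treated as drained
    to 1 m; no flux below the 4 m cutoff. The potential flux declines
    linearly with depth and is gated by how dry the bottom compartment is
    relative to field capacity.

    Returns ``(new_state, inflow_mm)``.
    """
    if water_table_depth_m < 0:
        raise ValueError("water-table depth must be non-negative")
    if system == "irrigated" and not crop_is_rice:
        return state, 0.0
    depth = max(water_table_depth_m, CR_DRAINED_M)
    if depth > CR_CUTOFF_M:
        return state, 0.0
    potential = CR_MAX_MM_DAY * (CR_CUTOFF_M - depth) / (CR_CUTOFF_M - CR_DRAINED_M)
    i = profile.n - 1
    fc = profile.capacity_mm(hydraulics.theta_fc)[i]
    wp = profile.capacity_mm(hydraulics.theta_wp)[i]
    headroom = max(fc - state.w[i], 0.0)
    dryness = min(max((fc - state.w[i]) / max(fc - wp, 1e-9), 0.0), 1.0)
    flux = min(potential * dryness, headroom)
    if flux <= 0.0:
        return state, 0.0
    out = state.copy()
    amounts = np.zeros(N_COLOURS)
    amounts[BLUE_CR] = flux
    _mix(out.w, out.frac, i, amounts)
    return out, flux


def root_weights(profile: SoilProfile, root_depth_m: float) -> np.ndarray:
    """Transpiration extraction weights over compartments.

    Proportional to the overlap of each compartment with the root zone,
    tapered towards depth (more uptake near the surface); normalised to 1.
    Returns zeros if the root zone is empty.
    """
    z = max(root_depth_m, 0.0)
    if z <= 0.0:
        return np.zeros(profile.n)
    overlap = np.clip(np.minimum(profile.bottoms, z) - profile.tops, 0.0, None)
    taper = np.clip(1.0 - 0.8 * (profile.centres / z), 0.2, 1.0)
    w = overlap * taper
    s = w.sum()
    return w / s if s > 0 else w


def root_zone_depletion(state: SoilState, hydraulics: SoilHydraulics,
                        profile: SoilProfile, root_depth_m: float):
    """Root-zone depletion Dr and total available water TAW (both mm).

    Dr is the water missing from field capacity within the root zone; TAW
    is the capacity between field capacity and wilting point there.
    """
    z = max(root_depth_m, 1e-6)
    overlap = np.clip(np.minimum(profile.bottoms, z) - profile.tops, 0.0, None)
    f = overlap / profile.thicknesses
    fc = profile.capacity_mm(hydraulics.theta_fc)
    wp = profile.capacity_mm(hydraulics.theta_wp)
    taw = float(((fc - wp) * f).sum())
    dr = float(np.clip((fc - state.w) * f, 0.0, None).sum())
    return min(dr, taw), taw


def extract_evapotranspiration(state: SoilState, evap_demand: float,
                               transp_demand: float, weights: np.ndarray,
                               hydraulics: SoilHydraulics, profile: SoilProfile):
    """Remove soil evaporation and transpiration, colour-tagged.

    Evaporation comes from ponded water first (energy-limited), then from
    the top compartment under two-stage drying: full rate while cumulative
    surface depletion is below REW, then a linearly falling rate until the
    totally evaporable water (TEW) is exhausted. Transpiration is drawn from
    the root zone by ``weights``, limited per compartment by water above
    wilting point, with a compensation pass redistributing unmet demand.
    Each millimetre removed carries its donor store's colour fractions.

    Returns ``(new_state, evap_by_colour, transp_by_colour, unmet_demand)``.
    """
    if evap_demand < 0 or transp_demand < 0:
        raise ValueError("demands must be non-negative")
    out = state.copy()
    evap = np.zeros(N_COLOURS)
    transp = np.zeros(N_COLOURS)

    # --- evaporation: ponding first
    e_left = evap_demand
    if out.ponding > 0.0 and e_left > 0.0:
        take = min(out.ponding, e_left)
        evap += take * out.ponding_frac
        out.ponding -= take
        e_left -= take
    if e_left > 0.0:
        dz = profile.thicknesses[0]
        tew = max((hydraulics.theta_fc - 0.5 * hydraulics.theta_wp) * dz * 1000.0,
                  hydraulics.rew)
        floor = 0.5 * hydraulics.theta_wp * dz * 1000.0
        supply = max(out.w[0] - floor, 0.0)
        de = out.evap_depletion
        stage1 = min(e_left, max(hydraulics.rew - de, 0.0))
        kr = max((tew - (de + stage1)) / max(tew - hydraulics.rew, 1e-9), 0.0)
        stage2 = (e_left - stage1) * min(kr, 1.0)
        e_soil = min(stage1 + stage2, supply)
        if e_soil > 0.0:
            evap += e_soil * out.frac[0]
            out.w[0] -= e_soil
            out.evap_depletion = de + e_soil
        e_left -= min(e_soil, e_left)

    # --- transpiration: weighted first pass + compensation pass
    wp = profile.capacity_mm(hydraulics.theta_wp)
    t_left = transp_demand
    for _ in range(2):
        if t_left <= 1e-12:
            break
        avail = np.maximum(out.w - wp, 0.0)
        # gate on a small threshold: exact-zero tests on float residuals
        # would make uptake depend on rounding noise
        weighted = weights * (avail > 1e-9)
        s = weighted.sum()
        if s <= 0.0:
            break
        share = t_left * weighted / s
        take = np.minimum(share, avail)
        removed = take.sum()
        if removed <= 0.0:
            break
        transp += take @ out.frac
        out.w -= take
        t_left -= removed

    unmet = e_left + t_left
    return out, evap, transp, unmet


def step_water_balance(state: SoilState, precip_mm: float, et0_mm: float,
                       canopy_cover: float, root_depth_m: float,
                       irrigation_mm: float, water_table_depth_m: float,
                       hydraulics: SoilHydraulics, profile: SoilProfile,
                       system: str = "rainfed", crop_is_rice: bool = False,
                       bund_height_mm: float = 0.0, kcb: float = 1.05,
                       ks_stomatal: float = 1.0, ke_max: float = 1.1,
                       wetted_fraction: float = 1.0):
    """Advance the soil column one day; returns ``(new_state, DailyFluxes)``.

    Transpiration demand is ``et0 * kcb * CC * Ks_stomatal``; evaporation
    demand is ``et0 * ke_max * (1 - CC)``, reduced by the wetted surface
    fraction on irrigation days (localised drip wetting).
    """
    out = state.copy()
    fx = DailyFluxes()

    # 1. capillary rise
    out, cr = capillary_rise(out, water_table_depth_m, system, crop_is_rice,
                             hydraulics, profile)
    fx.capillary_in[BLUE_CR] = cr

    # 2. rainfall -> runoff / infiltration (or ponding behind bunds)
    if precip_mm > 0.0:
        fx.rain_in[GREEN] = precip_mm
        if bund_height_mm > 0.0:
            spill = curve_number_runoff(precip_mm, hydraulics.curve_number,
                                        bund_height_mm, out.ponding)
            amounts = np.zeros(N_COLOURS)
            amounts[GREEN] = precip_mm
            _mix_surface(out, amounts)
            if spill > 0.0:
                fx.runoff_out += spill * out.ponding_frac
                out.ponding -= spill
        else:
            runoff = curve_number_runoff(precip_mm, hydraulics.curve_number)
            fx.runoff_out[GREEN] = runoff
            inf = precip_mm - runoff
            amounts = np.zeros(N_COLOURS)
            amounts[GREEN] = inf
            dp = _infiltrate_inplace(out, amounts, hydraulics, profile)
            fx.deep_percolation_out += dp
            out.evap_depletion = max(out.evap_depletion - inf, 0.0)

    # 3. irrigation
    if irrigation_mm > 0.0:
        fx.irrigation_in[BLUE_I] = irrigation_mm
        amounts = np.zeros(N_COLOURS)
        amounts[BLUE_I] = irrigation_mm
        if crop_is_rice and bund_height_mm > 0.0:
            _mix_surface(out, amounts)
        else:
            dp = _infiltrate_inplace(out, amounts, hydraulics, profile)
            fx.deep_percolation_out += dp
            out.evap_depletion = max(
                out.evap_depletion - irrigation_mm * wetted_fraction, 0.0)

    # ponded water percolates into the profile at a fixed paddy rate
    if out.ponding > 0.0:
        perc = min(out.ponding, PONDING_PERC_MM_DAY)
        amounts = perc * out.ponding_frac
        out.ponding -= perc
        dp = _infiltrate_inplace(out, amounts, hydraulics, profile)
        fx.deep_percolation_out += dp
        out.evap_depletion = 0.0

    # 4. drainage cascade
    dp = _drain_inplace(out, hydraulics, profile)
    fx.deep_percolation_out += dp

    # 5. evaporation + transpiration
    cc = min(max(canopy_cover, 0.0), 1.0)
    transp_demand = et0_mm * kcb * cc * ks_stomatal
    evap_demand = et0_mm * ke_max * (1.0 - cc)
    if irrigation_mm > 0.0 and wetted_fraction < 1.0:
        evap_demand *= wetted_fraction
    weights = root_weights(profile, root_depth_m)
    out, evap, transp, _ = extract_evapotranspiration(
        out, evap_demand, transp_demand, weights, hydraulics, profile)
    fx.evaporation_out = evap
    fx.transpiration_out = transp
    return out, fx


def _mix_surface(state: SoilState, amounts: np.ndarray):
    """Mix a colour-amount vector into the ponded surface store."""
    total = amounts.sum()
    if total <= 0.0:
        return
    new_p = state.ponding + total
    state.ponding_frac = (state.ponding * state.ponding_frac + amounts) / new_p
    state.ponding = new_p
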