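"""Post-processing: census scaling, unit and production water footprints.

Turns per-season simulation results plus national census tables into the
headline quantities: harvested-area time series projected from a base
year and scaled to census totals, national yield scaling factors (applied
uniformly to all rainfed and irrigated cell yields of a country; crop
water use is never scaled), dry-to-fresh yield conversion, unit water
footprints uWF = 10 x CWU / yield (m3/t, with CWU in mm and yield in
t/ha), and production water footprints pWF = uWF x production (m3/yr).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dry_to_fresh",
    "multi_season_cwu",
    "aggregate_seasons",
    "project_and_scale_areas",
    "yield_scaling_factors",
    "apply_yield_scaling",
    "compute_uwf",
    "compute_pwf",
]


def dry_to_fresh(dry_yield, water_content):
    """Convert dry yield (t/ha) to fresh using the crop's water-content
    fraction: fresh = dry / (1 - wc). Vectorises."""
    wc = np.asarray(water_content, dtype=float)
    if np.any((wc < 0) | (wc >= 1)):
        raise ValueError("water content fraction must lie in [0, 1)")
    return np.asarray(dry_yield, dtype=float) / (1.0 - wc)


def multi_season_cwu(cwu_values, season_areas=None):
    """Reported CWU of a multi-season crop: the area-weighted *average*
    of the season values, never their sum."""
    v = np.asarray(cwu_values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one season")
    w = None if season_areas is None else np.asarray(season_areas, dtype=float)
    return float(np.average(v, weights=w))


def aggregate_seasons(seasons: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-season results to one row per (cell, crop, system, year).

    CWU components are averaged across the year's seasons (equal per-season
    areas within a cell); dry yields are summed, since every season's
    harvest adds to production. ``n_seasons`` records how many seasons
    actually completed.
    """
    grp = seasons.groupby(["coarse_cell", "crop", "system", "harvest_year"])
    out = grp.agg(
        cwu_green=("cwu_green", "mean"),
        cwu_blue_cr=("cwu_blue_cr", "mean"),
        cwu_blue_i=("cwu_blue_i", "mean"),
        dry_yield_total=("dry_yield_t_ha", "sum"),
        irrigation_mm=("irrigation_applied_mm", "sum"),
        n_seasons=("season", "count"),
    ).reset_index()
    return out.rename(columns={"harvest_year": "year"})


def project_and_scale_areas(cell_areas: pd.DataFrame, trend,
                            census_areas: pd.DataFrame,
                            n_seasons) -> tuple[pd.DataFrame, list]:
    """Per-year fine-cell harvested areas, scaled to census national totals.

    ``cell_areas`` holds base-year areas (columns crop, system, fine_row,
    fine_col, coarse_cell, country, base_area_ha); ``trend(country, crop,
    year)`` is the projection index; ``census_areas`` has columns country,
    crop, year, harvarea_ha; ``n_seasons(crop)`` counts growing seasons per
    year (harvested area counts each). Cell areas are first multiplied by
    the trend, then uniformly rescaled per (country, crop, year) — with
    rainfed and irrigated systems summed — so national totals match the
    census exactly. Returns the long table plus a list of (country, crop,
    year) flagged unallocatable (census > 0 with no projected area).
    """
    frames = []
    flagged = []
    years = sorted(census_areas["year"].unique())
    for year in years:
        df = cell_areas.copy()
        df["year"] = year
        df["area_ha"] = df["base_area_ha"] * [
            trend(r.country, r.crop, year) for r in df.itertuples()]
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)

    totals = long.groupby(["country", "crop", "year"])["area_ha"].sum().rename(
        "projected_total").reset_index()
    totals["projected_total"] *= [n_seasons(c) for c in totals["crop"]]
    merged = totals.merge(census_areas, on=["country", "crop", "year"],
                          how="right")
    merged["area_scale"] = np.where(
        merged["projected_total"] > 0,
        merged["harvarea_ha"] / merged["projected_total"].replace(0, np.nan),
        np.nan)
    for r in merged.itertuples():
        if (not np.isfinite(r.area_scale)) and r.harvarea_ha > 0:
            flagged.append((r.country, r.crop, r.year))
    long = long.merge(merged[["country", "crop", "year", "area_scale"]],
                      on=["country", "crop", "year"], how="left")
    long["area_ha"] = long["area_ha"] * long["area_scale"].fillna(0.0)
    return long.drop(columns=["base_area_ha"]), flagged


def yield_scaling_factors(sim_production: pd.DataFrame,
                          census: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """National yield scaling factors k = census production / simulated.

    Both inputs have columns country, crop, year and production_t. A
    country-crop-year with positive census but zero simulated production
    has no defined factor and is flagged (k left at NaN).
    """
    df = sim_production.rename(columns={"production_t": "sim_production_t"}) \
        .merge(census[["country", "crop", "year", "production_t"]],
               on=["country", "crop", "year"], how="outer")
    df["yield_scale"] = np.where(
        df["sim_production_t"] > 0,
        df["production_t"] / df["sim_production_t"].replace(0, np.nan),
        np.nan)
    flagged = [(r.country, r.crop, r.year) for r in df.itertuples()
               if not np.isfinite(r.yield_scale) and r.production_t > 0]
    return df[["country", "crop", "year", "yield_scale"]], flagged


def apply_yield_scaling(cells: pd.DataFrame,
                        factors: pd.DataFrame) -> pd.DataFrame:
    """Multiply every rainfed and irrigated cell yield by its national
    factor (a factor of 0.5 halves every yield in the country). CWU
    columns are left untouched."""
    out = cells.merge(factors, on=["country", "crop", "year"], how="left")
    out["yield_scale"] = out["yield_scale"].fillna(1.0)
    for col in ("fresh_yield_total_t_ha", "cell_yield_t_ha"):
        if col in out.columns:
            out[col] = out[col] * out["yield_scale"]
    return out


def compute_uwf(cwu_mm, yield_t_ha):
    """Unit water footprint (m3/t) of one CWU colour component:
    uWF = 10 x CWU / yield. Zero or missing yields give NaN (masked)."""
    cwu = np.asarray(cwu_mm, dtype=float)
    y = np.asarray(yield_t_ha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(y > 0, 10.0 * cwu / np.where(y > 0, y, 1.0), np.nan)
    return out


def compute_pwf(uwf_m3_t, production_t):
    """Production water footprint (m3/yr) = uWF x production; zero
    production gives exactly zero regardless of uWF masking."""
    uwf = np.asarray(uwf_m3_t, dtype=float)
    prod = np.asarray(production_t, dtype=float)
    out = uwf * prod
    return np.where(prod == 0, 0.0, out)
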