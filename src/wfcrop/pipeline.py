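"""End-to-end run: synthetic world -> simulation -> accounting -> reports.

The pipeline simulates every (coarse cell, crop, system) combination with
harvested area, aggregates seasons to years, projects and census-scales
harvested areas on the fine grid, scales national yields to the census,
computes unit and production water footprints per fine cell, and builds
the national table and gridded decade-average layers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accounting as acc
from . import reporting as rep
from .season_engine import RunLedger, run_cell
from .synthetic_world import World, WorldConfig, generate_world

__all__ = ["PipelineResult", "simulate_world", "postprocess", "run_pipeline"]


@dataclass
class PipelineResult:
    world: World
    seasons: pd.DataFrame  # one row per completed season
    cells: pd.DataFrame  # fine-cell accounting table
    national: pd.DataFrame  # the 13-column national table
    census: pd.DataFrame
    yield_factors: pd.DataFrame
    ledgers: dict = field(default_factory=dict)  # (cell, crop, system) -> RunLedger
    flagged: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Headline global quantities over the reported period."""
        c = self.cells
        years = sorted(c["year"].unique())
        pwf_green = c["pwf_green"].sum() / len(years)
        pwf_blue = (c["pwf_blue_cr"].sum() + c["pwf_blue_i"].sum()) / len(years)
        total = pwf_green + pwf_blue
        residual = max(float(np.abs(led.residual()).max())
                       for led in self.ledgers.values()) if self.ledgers else 0.0
        return {
            "global_pwf_green_m3_yr": float(pwf_green),
            "global_pwf_blue_m3_yr": float(pwf_blue),
            "green_share_pct": float(100.0 * pwf_green / total) if total else float("nan"),
            "max_colour_residual_mm": residual,
            "n_seasons_simulated": int(len(self.seasons)),
            "n_reported_years": len(years),
        }

    def save(self, directory):
        os.makedirs(directory, exist_ok=True)
        self.seasons.to_csv(os.path.join(directory, "seasons.csv"), index=False)
        self.cells.to_csv(os.path.join(directory, "cells.csv"), index=False)
        self.census.to_csv(os.path.join(directory, "census.csv"), index=False)
        rep.write_national_csv(
            self.national, os.path.join(directory, "national_wf_crop_production.csv"))
        years = sorted(self.cells["year"].unique())[-10:]
        shape = self.world.fine_shape
        for crop in self.world.crops:
            layers = rep.gridded_decade_layers(self.cells, crop, shape, years)
            wf = {k: v for k, v in layers.items() if k.startswith("wf_unit")}
            cwu = {k: v for k, v in layers.items() if k.startswith("cwu")}
            rep.write_gridded_netcdf(
                wf, os.path.join(directory, f"wf_unit_{crop}_average.nc"),
                kind="wf_unit")
            rep.write_gridded_netcdf(
                cwu, os.path.join(directory, f"cwu_{crop}_average.nc"),
                kind="cwu")


def simulate_world(world: World):
    """Run the season engine on every combination with harvested area.

    Returns the per-season results table and the colour mass ledgers.
    """
    cfg = world.config
    f = cfg.fine_factor
    rows = []
    ledgers: dict = {}
    for (crop, system), grid in world.base_areas_ha.items():
        coarse_tot = grid.reshape(cfg.coarse_rows, f, cfg.coarse_cols, f) \
            .sum(axis=(1, 3))
        for cell in np.flatnonzero(coarse_tot.ravel() > 0):
            res = run_cell(world, int(cell), crop, system)
            ledgers[(int(cell), crop, system)] = res.ledger
            for s in res.seasons:
                rows.append({
                    "coarse_cell": int(cell), "crop": crop, "system": system,
                    "season": s.season, "harvest_year": s.harvest_year,
                    "planting_year": s.planting_year,
                    "emergence_doy": s.emergence_doy,
                    "harvest_doy": s.harvest_doy,
                    "cwu_green": s.cwu_green, "cwu_blue_cr": s.cwu_blue_cr,
                    "cwu_blue_i": s.cwu_blue_i,
                    "dry_yield_t_ha": s.dry_yield_t_ha,
                    "irrigation_applied_mm": s.irrigation_applied_mm,
                    "matured": s.matured,
                })
    seasons = pd.DataFrame(rows)
    return seasons, ledgers


def postprocess(world: World, seasons: pd.DataFrame):
    """Accounting chain: areas -> production -> scaling -> uWF/pWF."""
    cfg = world.config
    flagged: dict = {}

    season_cell = acc.aggregate_seasons(seasons)
    areas_long, flagged["unallocatable_area"] = acc.project_and_scale_areas(
        world.cell_area_table(), world.trend, world.census_areas(),
        world.n_seasons)

    cells = areas_long.merge(
        season_cell, on=["coarse_cell", "crop", "system", "year"], how="left")
    cells["dry_yield_total"] = cells["dry_yield_total"].fillna(0.0)
    cells["n_seasons"] = cells["n_seasons"].fillna(0).astype(int)
    wc = {name: p.wc for name, p in world.crops.items()}
    cells["fresh_yield_total_t_ha"] = acc.dry_to_fresh(
        cells["dry_yield_total"], cells["crop"].map(wc))

    # simulated-truth national production (pre-scaling bookkeeping)
    cells["production_t"] = cells["fresh_yield_total_t_ha"] * cells["area_ha"]
    true_production = cells.groupby(["country", "crop", "year"])[
        "production_t"].sum().reset_index()

    census = world.finalize_census(true_production)
    factors, flagged["undefined_yield_factor"] = acc.yield_scaling_factors(
        true_production, census)
    cells = acc.apply_yield_scaling(cells, factors)

    # per-harvest yield, production, footprints
    n_nominal = cells["crop"].map({c: world.n_seasons(c) for c in world.crops})
    with np.errstate(invalid="ignore", divide="ignore"):
        cells["cell_yield_t_ha"] = np.where(
            cells["n_seasons"] > 0,
            cells["fresh_yield_total_t_ha"] / cells["n_seasons"].replace(0, 1),
            np.nan)
    cells["production_t"] = cells["fresh_yield_total_t_ha"] * cells["area_ha"]
    cells["harvarea_ha"] = cells["area_ha"] * n_nominal
    cells["cwu_total_mm"] = (cells["cwu_green"] + cells["cwu_blue_cr"]
                             + cells["cwu_blue_i"])
    for comp in ("green", "blue_cr", "blue_i"):
        cells[f"uwf_{comp}"] = acc.compute_uwf(cells[f"cwu_{comp}"],
                                               cells["cell_yield_t_ha"])
        cells[f"pwf_{comp}"] = acc.compute_pwf(cells[f"uwf_{comp}"],
                                               cells["production_t"])
    cells["uwf_total"] = (cells["uwf_green"] + cells["uwf_blue_cr"]
                          + cells["uwf_blue_i"])

    national = _national_table(world, cells)
    return cells, national, census, factors, flagged


def _national_table(world: World, cells: pd.DataFrame) -> pd.DataFrame:
    crop_codes = {c: i + 1 for i, c in enumerate(sorted(world.crops))}
    rows = []
    for (country, crop, year), sub in cells.groupby(["country", "crop", "year"]):
        harvarea = sub["harvarea_ha"].sum()
        production = sub["production_t"].sum()
        irr = sub.loc[sub["system"] == "irrigated", "harvarea_ha"].sum()
        wfg = rep.national_aggregate(sub["uwf_green"], sub["production_t"])
        wfb_cr = rep.national_aggregate(sub["uwf_blue_cr"], sub["production_t"])
        wfb_i = rep.national_aggregate(sub["uwf_blue_i"], sub["production_t"])
        rows.append({
            "crop_code": crop_codes[crop],
            "crop_name": crop,
            "country_code": int(country) + 1,
            "country_name": f"Country {chr(65 + int(country))}",
            "year": int(year),
            "harvarea_ha": harvarea,
            "irrigated_harvarea_fraction": irr / harvarea if harvarea else np.nan,
            "production_t": production,
            "crop_yield_t_ha": production / harvarea if harvarea else np.nan,
            "wfg_m3_t": wfg,
            "wfb_cr_m3_t": wfb_cr,
            "wfb_i_m3_t": wfb_i,
            "wf_tot_m3_t": wfg + wfb_cr + wfb_i,
        })
    df = pd.DataFrame(rows, columns=rep.NATIONAL_CSV_COLUMNS)
    return df.sort_values(["crop_code", "country_code", "year"]).reset_index(drop=True)


def run_pipeline(config: WorldConfig | None = None,
                 world: World | None = None) -> PipelineResult:
    """Generate (or accept) a world, simulate it, and post-process."""
    if world is None:
        world = generate_world(config or WorldConfig())
    seasons, ledgers = simulate_world(world)
    cells, national, census, factors, flagged = postprocess(world, seasons)
    return PipelineResult(world=world, seasons=seasons, cells=cells,
                          national=national, census=census,
                          yield_factors=factors, ledgers=ledgers,
                          flagged=flagged)
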