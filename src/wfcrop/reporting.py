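"""Coarse-to-fine allocation, weighted aggregation, and dataset writers.

Simulation happens on the coarse grid; outputs are allocated to the fine
grid according to harvested-area distributions: intensive quantities
(uWF, CWU, yield) are copied to fine cells with positive area, extensive
ones (pWF, production) are distributed proportionally to area so totals
are conserved. National uWFs are production-weighted averages; national
CWU and yields are harvested-area-weighted. Decade-average gridded layers
are weighted the same way. Writers reproduce the published dataset
schemas: a national CSV with thirteen fixed columns and per-crop NetCDF
files with ``wf_unit_{wf_type}`` and ``cwu_{cwu_type}`` layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

#: the national CSV schema, in order
NATIONAL_CSV_COLUMNS = [
    "crop_code", "crop_name", "country_code", "country_name", "year",
    "harvarea_ha", "irrigated_harvarea_fraction", "production_t",
    "crop_yield_t_ha", "wfg_m3_t", "wfb_cr_m3_t", "wfb_i_m3_t",
    "wf_tot_m3_t",
]

WF_UNIT_LAYERS = ["wf_unit_rainfed", "wf_unit_rainfed_blue",
                  "wf_unit_rainfed_green", "wf_unit_irrigated",
                  "wf_unit_irrigated_blue", "wf_unit_irrigated_green",
                  "wf_unit_total"]
CWU_LAYERS = ["cwu_rainfed", "cwu_irrigated", "cwu_total"]

__all__ = [
    "NATIONAL_CSV_COLUMNS", "WF_UNIT_LAYERS", "CWU_LAYERS",
    "AllocationError", "SchemaError",
    "allocate_coarse_to_fine", "national_aggregate", "decade_average",
    "gridded_decade_layers", "write_national_csv", "write_gridded_netcdf",
    "read_gridded_netcdf",
]


class AllocationError(ValueError):
    """A nonzero coarse value cannot be allocated (no fine area)."""


class SchemaError(ValueError):
    """Output violates the published schema; the writer refuses."""


def allocate_coarse_to_fine(coarse_value: float, fine_areas,
                            kind: str = "intensive") -> np.ndarray:
    """Spread one coarse-cell value over its fine cells.

    ``intensive`` quantities are copied unchanged to every fine cell with
    positive area (NaN elsewhere); ``extensive`` ones are split
    proportionally to area so the fine values sum to the coarse value.
    """
    areas = np.asarray(fine_areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    total = areas.sum()
    if total == 0.0:
        if coarse_value not in (0.0,) and np.isfinite(coarse_value) \
                and coarse_value != 0:
            raise AllocationError(
                f"cannot allocate {coarse_value!r}: all fine areas are zero")
        return np.where(areas > 0, 0.0, np.nan)
    if kind == "intensive":
        return np.where(areas > 0, coarse_value, np.nan)
    if kind == "extensive":
        return coarse_value * areas / total
    raise ValueError(f"unknown allocation kind {kind!r}")


def national_aggregate(values, weights, kind: str = "production-weighted") -> float:
    """Weighted national mean: sum(v*w)/sum(w) over cells with data.

    uWFs use production weights; CWU and yields use harvested-area
    weights (``kind`` documents the caller's intent). All-zero weights
    leave the aggregate undefined (NaN).
    """
    if kind not in ("production-weighted", "area-weighted"):
        raise ValueError(f"unknown aggregation kind {kind!r}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    ok = np.isfinite(v) & np.isfinite(w)
    if not ok.any() or w[ok].sum() <= 0:
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def decade_average(values_by_year, weights_by_year) -> float:
    """Weighted multi-year average (production weights for uWF, harvested
    area for CWU) damping years with extreme values."""
    v = np.asarray(values_by_year, dtype=float)
    w = np.asarray(weights_by_year, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one year")
    ok = np.isfinite(v) & np.isfinite(w) & (w >= 0)
    if not ok.any() or w[ok].sum() <= 0:
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def _grid_weighted_mean(df: pd.DataFrame, value: str, weight: str,
                        shape) -> np.ndarray:
    """Fine-grid map of the per-cell weighted mean of ``value`` over years."""
    out = np.full(shape, np.nan)
    sub = df[np.isfinite(df[value]) & (df[weight] > 0)]
    if len(sub):
        g = sub.assign(vw=sub[value] * sub[weight]).groupby(
            ["fine_row", "fine_col"])[["vw", weight]].sum()
        means = g["vw"] / g[weight]
        for (r, c), m in means.items():
            out[int(r), int(c)] = m
    return out


def gridded_decade_layers(cells: pd.DataFrame, crop: str, fine_shape,
                          years=None) -> dict[str, np.ndarray]:
    """Decade-average gridded layers for one crop.

    ``cells`` is the fine-cell table (one row per fine cell, crop, system,
    year) with uwf components, cwu_total_mm, production_t and harvested
    area. uWF layers are production-weighted over years; CWU layers are
    harvested-area-weighted. Per-system layers are sums of their green and
    blue components; the ``total`` layers combine the systems weighted by
    production (uWF) or harvested area (CWU).
    """
    df = cells[cells["crop"] == crop]
    if years is not None:
        df = df[df["year"].isin(list(years))]
    layers: dict[str, np.ndarray] = {}
    per_system: dict[str, dict[str, np.ndarray]] = {}
    for system in ("rainfed", "irrigated"):
        sub = df[df["system"] == system].copy()
        sub["uwf_blue"] = sub["uwf_blue_cr"] + sub["uwf_blue_i"]
        green = _grid_weighted_mean(sub, "uwf_green", "production_t", fine_shape)
        blue = _grid_weighted_mean(sub, "uwf_blue", "production_t", fine_shape)
        cwu = _grid_weighted_mean(sub, "cwu_total_mm", "harvarea_ha", fine_shape)
        prod = np.zeros(fine_shape)
        area = np.zeros(fine_shape)
        if len(sub):
            g = sub.groupby(["fine_row", "fine_col"])[
                ["production_t", "harvarea_ha"]].mean()
            for (r, c), row in g.iterrows():
                prod[int(r), int(c)] = row["production_t"]
                area[int(r), int(c)] = row["harvarea_ha"]
        layers[f"wf_unit_{system}_green"] = green
        layers[f"wf_unit_{system}_blue"] = blue
        layers[f"wf_unit_{system}"] = green + blue
        layers[f"cwu_{system}"] = cwu
        per_system[system] = {"prod": prod, "area": area}

    # totals: production-weighted (uWF) / area-weighted (CWU) across systems
    pr, pi = per_system["rainfed"]["prod"], per_system["irrigated"]["prod"]
    ar, ai = per_system["rainfed"]["area"], per_system["irrigated"]["area"]
    layers["wf_unit_total"] = _combine(layers["wf_unit_rainfed"],
                                       layers["wf_unit_irrigated"], pr, pi)
    layers["cwu_total"] = _combine(layers["cwu_rainfed"],
                                   layers["cwu_irrigated"], ar, ai)
    return layers


def _combine(a: np.ndarray, b: np.ndarray, wa: np.ndarray,
             wb: np.ndarray) -> np.ndarray:
    """Cellwise weighted mean of two layers, tolerating one-sided data."""
    wa = np.where(np.isfinite(a), wa, 0.0)
    wb = np.where(np.isfinite(b), wb, 0.0)
    tot = wa + wb
    with np.errstate(invalid="ignore"):
        out = (np.nan_to_num(a) * wa + np.nan_to_num(b) * wb) / np.where(
            tot > 0, tot, np.nan)
    return out


def write_national_csv(df: pd.DataFrame, path):
    """Write the national table; refuses any schema deviation."""
    if list(df.columns) != NATIONAL_CSV_COLUMNS:
        raise SchemaError(
            f"national table columns must be exactly {NATIONAL_CSV_COLUMNS}")
    bad = df["irrigated_harvarea_fraction"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise SchemaError("irrigated_harvarea_fraction outside [0, 1]")
    df.to_csv(path, index=False)


def write_gridded_netcdf(layers: dict[str, np.ndarray], path,
                         lat=None, lon=None, kind: str = "wf_unit"):
    """Write per-crop gridded layers to NetCDF (WGS84 lat/lon grid).

    ``kind`` selects the published layer-name set (``wf_unit`` or
    ``cwu``); unexpected layer names are refused. Masked cells are stored
    as the fill value (NaN), never zero.
    """
    allowed = set(WF_UNIT_LAYERS if kind == "wf_unit" else CWU_LAYERS)
    extra = [k for k in layers if k not in allowed]
    if extra:
        raise SchemaError(f"unexpected layer names {extra}; allowed: {sorted(allowed)}")
    shapes = {v.shape for v in layers.values()}
    if len(shapes) != 1:
        raise SchemaError("all layers must share one grid")
    (nr, nc), = shapes
    lat = np.arange(nr, dtype=float) if lat is None else np.asarray(lat, float)
    lon = np.arange(nc, dtype=float) if lon is None else np.asarray(lon, float)
    ds = xr.Dataset(
        {name: (("lat", "lon"), np.asarray(grid, dtype=float))
         for name, grid in layers.items()},
        coords={"lat": lat, "lon": lon},
        attrs={"crs": "WGS84"},
    )
    encoding = {name: {"_FillValue": np.nan} for name in layers}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def read_gridded_netcdf(path) -> dict[str, np.ndarray]:
    """Read back a gridded file written by :func:`write_gridded_netcdf`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return {name: ds[name].values.copy() for name in ds.data_vars}
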