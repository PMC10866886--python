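"""Loaders for the shipped crop archetype tables.

Five archetypes span the habit/physiology space the simulator handles:
a C3 annual (wheat), a stress-tolerant C4 annual (maize), flooded paddy
rice with two seasons per year, a deciduous perennial (grape) and an
evergreen perennial (citrus).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .crop_growth import CropCalendar, CropParameters
from .irrigation import RICE_BUND_HEIGHT_MM, IrrigationPolicy

__all__ = ["load_crop_parameters", "load_irrigation_policies", "load_crop_calendars"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("wfcrop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_crop_parameters() -> dict[str, CropParameters]:
    """Archetype name -> CropParameters, from the packaged CSV."""
    df = _read("crop_parameters.csv")
    out = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["is_rice"] = bool(d["is_rice"] is True or str(d["is_rice"]) == "True")
        d["shallow_soil"] = bool(d["shallow_soil"] is True or str(d["shallow_soil"]) == "True")
        out[d["name"]] = CropParameters(**d)
    return out


def load_irrigation_policies() -> dict[str, IrrigationPolicy]:
    """Crop name -> IrrigationPolicy (method, depletion trigger, flooding)."""
    df = _read("irrigation_policies.csv")
    out = {}
    for row in df.itertuples(index=False):
        flooding = bool(row.rice_flooding is True or str(row.rice_flooding) == "True")
        out[row.crop] = IrrigationPolicy(
            method=row.method,
            trigger_depletion=float(row.trigger_depletion),
            rice_flooding=flooding,
            bund_height_mm=RICE_BUND_HEIGHT_MM if flooding else 0.0,
        )
    return out


def load_crop_calendars() -> dict[str, list[CropCalendar]]:
    """Crop name -> reference calendars (rice has two growing seasons)."""
    df = _read("crop_calendars.csv").sort_values(["crop", "season"])
    out: dict[str, list[CropCalendar]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.crop, []).append(
            CropCalendar(int(row.planting_doy), int(row.harvest_doy)))
    return out
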