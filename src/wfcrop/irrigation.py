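"""Irrigation scheduling by root-zone soil-moisture depletion.

Non-rice crops are irrigated when depletion exceeds a crop-specific
fraction of total available water (0.50 for tolerant crops such as maize
and chickpea down to 0.25 for sensitive ones such as tomato and onion);
the application refills the root zone exactly to field capacity. Rice has
no threshold: paddies are kept flooded daily behind 300 mm bunds. Water
availability and conveyance losses are not modelled — applications are
net field-level requirements, so blue consumption reflects potential
rather than actual withdrawals.
"""

from __future__ import annotations

from dataclasses import dataclass

RICE_BUND_HEIGHT_MM = 300.0
RICE_TARGET_PONDING_MM = 50.0

#: wetted surface fraction by application method (affects evaporation only)
WETTED_FRACTION = {"surface": 1.0, "sprinkler": 1.0, "drip": 0.3}

__all__ = [
    "IrrigationPolicy",
    "irrigation_decision",
    "RICE_BUND_HEIGHT_MM",
    "RICE_TARGET_PONDING_MM",
]


@dataclass(frozen=True)
class IrrigationPolicy:
    """Per-crop irrigation practice."""

    method: str  # surface | sprinkler | drip
    trigger_depletion: float  # fraction of TAW; ignored for rice
    rice_flooding: bool = False
    bund_height_mm: float = 0.0

    def __post_init__(self):
        if self.method not in WETTED_FRACTION:
            raise ValueError(f"unknown irrigation method {self.method!r}")
        if not self.rice_flooding and not (0.25 <= self.trigger_depletion <= 0.50):
            raise ValueError("trigger depletion must lie in [0.25, 0.50]")

    @property
    def wetted_fraction(self) -> float:
        return WETTED_FRACTION[self.method]


def irrigation_decision(depletion_mm: float, taw_mm: float,
                        policy: IrrigationPolicy, system: str,
                        ponding_mm: float = 0.0) -> float:
    """Application depth (mm, colour blue_i) for one in-season day.

    Non-rice: apply exactly the root-zone deficit (refill to field
    capacity) once depletion exceeds the trigger fraction of TAW, else 0.
    Rice: top the ponded layer back up to its 50 mm target every day.
    Supply is never limiting.
    """
    if system != "irrigated":
        raise ValueError("irrigation decisions apply to irrigated systems only")
    if policy.rice_flooding:
        return max(RICE_TARGET_PONDING_MM - ponding_mm, 0.0)
    if taw_mm <= 0:
        raise ValueError("TAW must be positive")
    if depletion_mm > policy.trigger_depletion * taw_mm:
        return max(depletion_mm, 0.0)
    return 0.0
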