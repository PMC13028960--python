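"""Inhaler airflow arithmetic.

Passive DPIs obey the square-root orifice law ΔP = (Q·R)², where R is the
intrinsic device resistance in kPa^(1/2)·min/L, ΔP the pressure drop across
the device in kPa and Q the volumetric flow in L/min.  These helpers link
resistance, pressure drop, flow and actuation duration; computations keep
full precision and reporting conventionally rounds to one decimal place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .psd import ResistanceClass

__all__ = ["DeviceSpec", "flow_for_pressure_drop", "actuation_duration"]

#: manufacturer-reported intrinsic resistance of the medium-resistance RS01
#: capsule device, kPa^(1/2)·min/L; low/high variants must come from user
#: configuration
MEDIUM_RS01_RESISTANCE = 0.025


@dataclass(frozen=True)
class DeviceSpec:
    """A DPI device with its intrinsic airflow resistance."""

    resistance: float  # kPa^(1/2)·min/L
    resistance_class: ResistanceClass = ResistanceClass.MEDIUM
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.resistance > 0 and math.isfinite(self.resistance)):
            raise ValueError("device resistance must be positive and finite")
        object.__setattr__(self, "resistance_class", ResistanceClass(self.resistance_class))


def flow_for_pressure_drop(device: Union[DeviceSpec, float], pressure_drop: float) -> float:
    """Volumetric flow (L/min) producing ``pressure_drop`` (kPa) across a device.

    Q = sqrt(ΔP) / R.  Accepts a :class:`DeviceSpec` or a bare resistance.
    """
    resistance = device.resistance if isinstance(device, DeviceSpec) else float(device)
    if resistance <= 0:
        raise ValueError("device resistance must be positive")
    if pressure_drop <= 0:
        raise ValueError("pressure drop must be positive")
    return math.sqrt(pressure_drop) / resistance


def actuation_duration(total_volume: float, flow_rate: float) -> float:
    """Seconds needed to draw ``total_volume`` litres at ``flow_rate`` L/min."""
    if total_volume <= 0:
        raise ValueError("total volume must be positive")
    if flow_rate <= 0:
        raise ValueError("flow rate must be positive")
    return 60.0 * total_volume / flow_rate
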