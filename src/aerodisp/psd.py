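"""Cumulative volume-based particle size distributions (Q3 curves).

The universal currency of the package is the cumulative volume fraction
undersize F(x): the fraction of total particle volume carried by particles of
optical diameter <= x (µm).  Laser-diffraction instruments export Q3 in
percent on a fixed diameter grid; this module canonicalizes those exports
(percent -> probability, monotonicity repair, tail-completeness checks),
pools replicates, and interpolates curves onto shared grids so that any two
conditions can be compared point by point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Disperser",
    "ResistanceClass",
    "DispersionCondition",
    "SizeGrid",
    "CumulativePSD",
    "ReplicateSet",
    "normalize_from_percent",
    "pool_replicates",
    "interpolate_to_grid",
    "common_grid",
]

#: tolerance below which a local decrease in F is attributed to numerical
#: round-off rather than a corrupted export
MONOTONE_TOL = 1e-9
#: largest absolute dip (probability scale) repaired by the running maximum;
#: anything deeper is rejected as a corrupted export
MONOTONE_REPAIR_TOL = 0.01
#: minimum final cumulative value (probability scale) for an export to be
#: considered complete rather than truncated
TAIL_COMPLETE_MIN = 0.98


class Disperser(str, Enum):
    """How the powder was aerosolized for the size measurement."""

    REFERENCE = "reference"  # high-energy compressed-air dry disperser (RODOS)
    INHALER = "inhaler"      # DPI mouthpiece under controlled depression


class ResistanceClass(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


_CLASS_ORDER = {ResistanceClass.LOW: 0, ResistanceClass.MEDIUM: 1, ResistanceClass.HIGH: 2}


@dataclass(frozen=True)
class DispersionCondition:
    """One experimental condition under which a PSD was measured.

    Reference conditions describe the maximally dispersed state (compressed-air
    dispersion at ``rodos_pressure`` bar) and carry no device fields.  Inhaler
    conditions carry the device resistance class, the applied pressure drop in
    kPa and optionally the intrinsic device resistance in kPa^(1/2)·min/L.
    """

    formulation: str
    disperser: Disperser
    device_resistance_class: ResistanceClass | None = None
    resistance: float | None = None
    pressure_drop: float | None = None
    rodos_pressure: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "disperser", Disperser(self.disperser))
        if self.device_resistance_class is not None:
            object.__setattr__(
                self, "device_resistance_class", ResistanceClass(self.device_resistance_class)
            )
        if not self.formulation:
            raise ValueError("formulation identifier must be non-empty")
        if self.disperser is Disperser.REFERENCE:
            if self.rodos_pressure is None or self.rodos_pressure <= 0:
                raise ValueError("reference condition requires a positive rodos_pressure (bar)")
            if (
                self.device_resistance_class is not None
                or self.resistance is not None
                or self.pressure_drop is not None
            ):
                raise ValueError("reference condition must not carry device fields")
        else:
            if self.rodos_pressure is not None:
                raise ValueError("inhaler condition must not carry rodos_pressure")
            if self.device_resistance_class is None:
                raise ValueError("inhaler condition requires device_resistance_class")
            if self.pressure_drop is None or self.pressure_drop <= 0:
                raise ValueError("inhaler condition requires a positive pressure_drop (kPa)")
            if self.resistance is not None and self.resistance <= 0:
                raise ValueError("device resistance must be positive when given")

    def to_dict(self) -> dict:
        d = {"formulation": self.formulation, "disperser": self.disperser.value}
        if self.disperser is Disperser.REFERENCE:
            d["rodos_pressure"] = self.rodos_pressure
        else:
            d["device_resistance_class"] = self.device_resistance_class.value
            d["pressure_drop"] = self.pressure_drop
            if self.resistance is not None:
                d["resistance"] = self.resistance
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DispersionCondition":
        return cls(
            formulation=d["formulation"],
            disperser=Disperser(d["disperser"]),
            device_resistance_class=d.get("device_resistance_class"),
            resistance=d.get("resistance"),
            pressure_drop=d.get("pressure_drop"),
            rodos_pressure=d.get("rodos_pressure"),
        )


def _sort_key(condition: DispersionCondition) -> tuple:
    """Deterministic ordering: reference first, then by class then pressure."""
    if condition.disperser is Disperser.REFERENCE:
        return (0, 0, condition.rodos_pressure)
    return (1, _CLASS_ORDER[condition.device_resistance_class], condition.pressure_drop)


@dataclass(frozen=True, eq=False)
class SizeGrid:
    """Strictly increasing particle diameter grid in µm."""

    diameters: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("size grid needs at least 2 diameters")
        if not np.all(np.isfinite(d)):
            raise ValueError("size grid contains non-finite diameters")
        if d[0] <= 0:
            raise ValueError("diameters must be positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing")
        d = d.copy()
        d.setflags(write=False)
        object.__setattr__(self, "diameters", d)

    def __len__(self) -> int:
        return int(self.diameters.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeGrid):
            return NotImplemented
        return np.array_equal(self.diameters, other.diameters)

    def __hash__(self) -> int:
        return hash(self.diameters.tobytes())

    @property
    def min(self) -> float:
        return float(self.diameters[0])

    @property
    def max(self) -> float:
        return float(self.diameters[-1])

    def to_dict(self) -> dict:
        return {"diameters": self.diameters.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SizeGrid":
        return cls(np.asarray(d["diameters"], dtype=float))


@dataclass(frozen=True, eq=False)
class CumulativePSD:
    """A cumulative volume-undersize curve F(x) on a diameter grid.

    Values are dimensionless probabilities in [0, 1], non-decreasing along the
    grid.  The final value equals 1 for complete, normalized exports; curves
    restricted to a sub-range (after :func:`interpolate_to_grid` onto a
    :func:`common_grid`) legitimately end below 1.
    """

    grid: SizeGrid
    values: np.ndarray
    label: str = ""
    condition: DispersionCondition | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"values length {v.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("cumulative values contain non-finite entries")
        if np.any(v < -MONOTONE_TOL) or np.any(v > 1.0 + MONOTONE_TOL):
            raise ValueError("cumulative values outside [0, 1]")
        if np.any(np.diff(v) < -MONOTONE_TOL):
            raise ValueError("cumulative values decrease beyond tolerance")
        v = np.clip(v, 0.0, 1.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CumulativePSD):
            return NotImplemented
        return (
            self.grid == other.grid
            and np.array_equal(self.values, other.values)
            and self.label == other.label
            and self.condition == other.condition
        )

    def to_dict(self) -> dict:
        d = {"grid": self.grid.to_dict(), "values": self.values.tolist(), "label": self.label}
        if self.condition is not None:
            d["condition"] = self.condition.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CumulativePSD":
        cond = d.get("condition")
        return cls(
            grid=SizeGrid.from_dict(d["grid"]),
            values=np.asarray(d["values"], dtype=float),
            label=d.get("label", ""),
            condition=DispersionCondition.from_dict(cond) if cond else None,
        )


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate PSD measurements (typically triplicate) for one condition."""

    condition: DispersionCondition
    replicates: tuple

    def __post_init__(self) -> None:
        reps = tuple(self.replicates)
        if not reps:
            raise ValueError("replicate set must be non-empty")
        for r in reps:
            if not isinstance(r, CumulativePSD):
                raise TypeError("replicates must be CumulativePSD instances")
            if r.condition is not None and r.condition != self.condition:
                raise ValueError(
                    f"replicate condition {r.condition} differs from set condition "
                    f"{self.condition}"
                )
        object.__setattr__(self, "replicates", reps)

    def __len__(self) -> int:
        return len(self.replicates)


def normalize_from_percent(
    raw_values: Sequence[float],
    grid: SizeGrid,
    label: str = "",
    condition: DispersionCondition | None = None,
) -> CumulativePSD:
    """Convert an instrument Q3 export in percent to a valid probability curve.

    Values are divided by 100, clipped to [0, 1] and made non-decreasing by a
    running maximum (repairing dips up to 1 percentage point attributed to
    instrument rounding).  A final value in [98%, 100%) is rescaled to exactly
    1; lower final values indicate a truncated size range and are rejected.
    """
    raw = np.asarray(raw_values, dtype=float)
    if raw.shape != (len(grid),):
        raise ValueError("raw values length does not match grid length")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw export contains non-finite values")
    if np.any(raw < -0.5) or np.any(raw > 100.5):
        raise ValueError("raw export outside the plausible 0-100% range")
    f = raw / 100.0
    dips = np.diff(f)
    if np.any(dips < -(MONOTONE_REPAIR_TOL + 1e-12)):
        worst = float(-dips.min())
        raise ValueError(
            f"corrupted export: cumulative values decrease by {worst:.4f} "
            f"(repair threshold {MONOTONE_REPAIR_TOL})"
        )
    f = np.maximum.accumulate(np.clip(f, 0.0, 1.0))
    last = float(f[-1])
    if last < TAIL_COMPLETE_MIN:
        raise ValueError(
            f"truncated distribution: final cumulative value {100 * last:.2f}% < "
            f"{100 * TAIL_COMPLETE_MIN:.0f}%"
        )
    if last < 1.0:
        f = np.clip(f / last, 0.0, 1.0)
    return CumulativePSD(grid=grid, values=f, label=label, condition=condition)


def pool_replicates(reps: ReplicateSet) -> CumulativePSD:
    """Average replicate curves pointwise into one representative curve.

    All replicates must already share the same grid; interpolate first with
    :func:`interpolate_to_grid` when grids differ.
    """
    grids = [r.grid for r in reps.replicates]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError(
            f"replicates for condition {reps.condition.to_dict()} are on mixed "
            "grids; interpolate to a common grid before pooling"
        )
    # sort values per grid point before averaging: the mean becomes exactly
    # invariant to replicate order (summation order is fixed)
    mean = np.sort(np.stack([r.values for r in reps.replicates]), axis=0).mean(axis=0)
    return CumulativePSD(
        grid=grids[0],
        values=mean,
        label=f"pooled({len(reps)})",
        condition=reps.condition,
    )


def interpolate_to_grid(psd: CumulativePSD, target: SizeGrid) -> CumulativePSD:
    """Monotone piecewise-linear interpolation of F onto a target grid.

    Interpolation is linear in diameter (matching the linear-increment
    integral used by the transport distance).  Endpoint values extend flat by
    at most one source grid step; a target reaching further below the source
    minimum would require information about unresolved fines and is rejected.
    """
    src = psd.grid.diameters
    step_lo = float(src[1] - src[0])
    step_hi = float(src[-1] - src[-2])
    tol = 1e-12 * max(1.0, float(src[-1]))
    if target.min < src[0] - step_lo - tol:
        raise ValueError(
            f"target grid extends to {target.min:g} µm, more than one source step "
            f"below the source minimum {src[0]:g} µm (unresolved fines)"
        )
    if target.max > src[-1] + step_hi + tol:
        raise ValueError(
            f"target grid extends to {target.max:g} µm, more than one source step "
            f"above the source maximum {src[-1]:g} µm"
        )
    vals = np.interp(target.diameters, src, psd.values)
    return CumulativePSD(grid=target, values=vals, label=psd.label, condition=psd.condition)


def common_grid(a: CumulativePSD, b: CumulativePSD) -> SizeGrid:
    """Sorted union of both grids restricted to the intersection of ranges."""
    lo = max(a.grid.min, b.grid.min)
    hi = min(a.grid.max, b.grid.max)
    if lo > hi:
        raise ValueError(
            f"disjoint diameter ranges: [{a.grid.min:g}, {a.grid.max:g}] µm vs "
            f"[{b.grid.min:g}, {b.grid.max:g}] µm"
        )
    pts = np.union1d(a.grid.diameters, b.grid.diameters)
    pts = pts[(pts >= lo) & (pts <= hi)]
    if pts.size < 2:
        raise ValueError("fewer than 2 common grid points; ranges barely touch")
    return SizeGrid(pts)


def align_replicates(sets: Sequence[ReplicateSet]) -> tuple[SizeGrid, list[ReplicateSet]]:
    """Interpolate every replicate of every set onto one shared grid.

    The shared grid is the union of all grid points restricted to the
    intersection of all ranges.  Returns the grid and the re-gridded sets.
    """
    all_psds = [r for s in sets for r in s.replicates]
    lo = max(p.grid.min for p in all_psds)
    hi = min(p.grid.max for p in all_psds)
    if lo > hi:
        raise ValueError("replicate sets have disjoint diameter ranges")
    pts = all_psds[0].grid.diameters
    for p in all_psds[1:]:
        pts = np.union1d(pts, p.grid.diameters)
    pts = pts[(pts >= lo) & (pts <= hi)]
    if pts.size < 2:
        raise ValueError("fewer than 2 shared grid points across replicate sets")
    grid = SizeGrid(pts)
    out = [
        ReplicateSet(
            condition=s.condition,
            replicates=tuple(interpolate_to_grid(r, grid) for r in s.replicates),
        )
        for s in sets
    ]
    return grid, out
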