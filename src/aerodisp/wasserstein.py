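"""Wasserstein-1 dispersibility metric on cumulative size distributions.

In one dimension the Wasserstein-1 (earth mover's) distance between two
distributions is the integral of the absolute difference of their CDFs,

    W1(F_R, F_D) = ∫ |F_R(x) − F_D(x)| dx ,

here in µm: the total particle volume that must be moved, times the distance
along the size axis, for an inhaler-generated aerosol (F_D) to match the
maximally dispersed reference state (F_R).  On the discrete diameter grid of
a laser-diffraction export the integral is approximated by the left-endpoint
Riemann sum

    W1 ≈ Σ_{i=1}^{n−1} |F_R(x_i) − F_D(x_i)| · (x_{i+1} − x_i) ,

evaluated over the common diameter range of the paired curves.  Lower values
mean the aerosol more closely approximates the reference (more complete
deagglomeration); the final grid point carries no weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .psd import (
    CumulativePSD,
    DispersionCondition,
    ReplicateSet,
    ResistanceClass,
    SizeGrid,
    _CLASS_ORDER,
    common_grid,
    interpolate_to_grid,
    pool_replicates,
)

__all__ = [
    "W1Result",
    "DispersibilityProfile",
    "TitrationCurve",
    "TruncationBound",
    "wasserstein1",
    "dispersibility_profile",
    "titration_convergence",
    "fines_truncation_bound",
]


@dataclass(frozen=True)
class W1Result:
    """A single reference-vs-dispersed transport distance in µm."""

    value: float
    reference_condition: DispersionCondition | None
    dispersed_condition: DispersionCondition | None
    grid_min: float
    grid_max: float
    n_grid_points: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("W1 distance cannot be negative")
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be below grid_max")


@dataclass(frozen=True)
class DispersibilityProfile:
    """W1 per (device resistance class, pressure drop) for one formulation."""

    formulation: str
    entries: tuple  # of (ResistanceClass, pressure_kPa, W1Result)

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        keys = [(e[0], e[1]) for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (device, pressure) entries in profile")
        object.__setattr__(self, "entries", entries)


@dataclass(frozen=True)
class TitrationCurve:
    """W1 toward the high-pressure reference, per disperser pressure (bar)."""

    formulation: str
    points: tuple  # of (rodos_pressure_bar, w1_um)

    def __post_init__(self) -> None:
        points = tuple(self.points)
        pressures = [p for p, _ in points]
        if len(set(pressures)) != len(pressures):
            raise ValueError("titration pressures must be distinct")
        object.__setattr__(self, "points", points)


@dataclass(frozen=True)
class TruncationBound:
    """Worst-case W1 contribution of the sub-lens (unresolved) fines tail."""

    bound_um: float
    fraction_of_w1: float
    delta_f_max: float


def _w1_on_grid(x: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> float:
    """Left-endpoint Riemann sum of |fa − fb| over the grid x (last point unweighted)."""
    return float(np.sum(np.abs(fa[:-1] - fb[:-1]) * np.diff(x)))


def wasserstein1(f_ref: CumulativePSD, f_disp: CumulativePSD) -> W1Result:
    """W1 distance (µm) between two cumulative curves.

    The curves are brought onto their common grid (union of points over the
    intersection of ranges) by linear interpolation before summation.  The
    operation is symmetric in its arguments.
    """
    grid = common_grid(f_ref, f_disp)
    a = interpolate_to_grid(f_ref, grid)
    b = interpolate_to_grid(f_disp, grid)
    value = _w1_on_grid(grid.diameters, a.values, b.values)
    return W1Result(
        value=value,
        reference_condition=f_ref.condition,
        dispersed_condition=f_disp.condition,
        grid_min=grid.min,
        grid_max=grid.max,
        n_grid_points=len(grid),
    )


def dispersibility_profile(
    reference: ReplicateSet,
    dispersed: Mapping[tuple, ReplicateSet],
) -> DispersibilityProfile:
    """Flow-dependent dispersibility profile against one pooled reference.

    ``dispersed`` maps (device resistance class, pressure drop kPa) to the
    replicate measurements at that condition.  Each side is pooled to a single
    representative curve before the distance is taken — never an average of
    pairwise replicate distances.
    """
    formulation = reference.condition.formulation
    for key, rs in dispersed.items():
        if rs.condition.formulation != formulation:
            raise ValueError(
                f"formulation mismatch at condition {key}: "
                f"{rs.condition.formulation!r} vs reference {formulation!r}"
            )
    ref_pooled = pool_replicates(reference)
    entries = []
    for key in sorted(
        dispersed, key=lambda k: (_CLASS_ORDER[ResistanceClass(k[0])], float(k[1]))
    ):
        device_class = ResistanceClass(key[0])
        pressure = float(key[1])
        disp_pooled = pool_replicates(dispersed[key])
        entries.append((device_class, pressure, wasserstein1(ref_pooled, disp_pooled)))
    return DispersibilityProfile(formulation=formulation, entries=tuple(entries))


def titration_convergence(
    measurements: Mapping[float, Union[ReplicateSet, CumulativePSD]],
    reference_pressure: float,
) -> TitrationCurve:
    """Distributional convergence toward the high-energy reference state.

    ``measurements`` maps disperser pressure (bar) to either a replicate set
    (pooled before comparison) or a single curve.  W1 of each pressure's
    pooled curve is taken against the pooled reference-pressure curve; the
    reference point itself reports exactly 0.
    """
    if reference_pressure not in measurements:
        raise ValueError(
            f"reference pressure {reference_pressure:g} bar missing from measurements"
        )

    def _pooled(m):
        return pool_replicates(m) if isinstance(m, ReplicateSet) else m

    ref = _pooled(measurements[reference_pressure])
    formulation = ref.condition.formulation if ref.condition is not None else ""
    points = []
    for pressure in sorted(measurements):
        if pressure == reference_pressure:
            points.append((float(pressure), 0.0))
        else:
            points.append(
                (float(pressure), wasserstein1(ref, _pooled(measurements[pressure])).value)
            )
    return TitrationCurve(formulation=formulation, points=tuple(points))


def fines_truncation_bound(
    f_ref: CumulativePSD,
    f_disp: CumulativePSD,
    lens_min: float = 0.5,
    assumed_floor: float = 0.25,
) -> TruncationBound:
    """Worst-case W1 error from particle volume below the lens cutoff.

    Diffraction lenses resolve diameters only down to ``lens_min`` (0.5 µm for
    an R3 lens); volume in finer particles is invisible to the measurement.
    Assuming the largest CDF gap observed near the cutoff (within twice
    ``lens_min``) persisted uniformly over the whole unresolved interval
    [``assumed_floor``, ``lens_min``], the missed transport cost is at most

        ΔF_max · (lens_min − assumed_floor)   [µm].

    Also reported as a fraction of the resolved W1 distance.
    """
    if assumed_floor >= lens_min:
        raise ValueError("assumed_floor must lie strictly below lens_min")
    if lens_min > min(f_ref.grid.min, f_disp.grid.min):
        raise ValueError("lens_min must not exceed the minimum resolved diameter")
    grid = common_grid(f_ref, f_disp)
    a = interpolate_to_grid(f_ref, grid).values
    b = interpolate_to_grid(f_disp, grid).values
    mask = grid.diameters <= 2.0 * lens_min
    delta_f_max = float(np.max(np.abs(a - b)[mask])) if np.any(mask) else 0.0
    bound = delta_f_max * (lens_min - assumed_floor)
    w1 = _w1_on_grid(grid.diameters, a, b)
    fraction = bound / w1 if w1 > 0 else 0.0
    return TruncationBound(bound_um=bound, fraction_of_w1=fraction, delta_f_max=delta_f_max)
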