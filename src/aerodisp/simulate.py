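"""Synthetic laser-diffraction and cascade-impaction data generators.

These generators emulate the statistical structure the analysis assumes so
the full pipeline is testable without instrument data:

* Replicate Q3 curves are drawn from a bimodal volume-weighted log-normal:
  a fine primary-particle mode plus a coarse agglomerate mode whose weight
  responds to device resistance and pressure drop.  Replicate-to-replicate
  variability is smooth correlated noise applied on the logit of F, then
  re-monotonized, which always yields a valid CDF.
* NGI deposition runs place an emitted fraction of the recovered mass past
  the device, divert an induction-port fraction, and apportion the rest to
  stages by sharp-cut differences of an aerodynamic log-normal CDF between
  consecutive flow-scaled D50 cutoffs (the MOC catches everything below the
  stage-7 cut).

Everything is deterministic given the spec seed; per-condition sub-seeds are
derived by hashing the condition so conditions are statistically isolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .impaction import STAGES, ImpactionRun, stage_cutoffs
from .psd import (
    CumulativePSD,
    DispersionCondition,
    Disperser,
    ReplicateSet,
    ResistanceClass,
    SizeGrid,
)
from .uncertainty import condition_seed

__all__ = [
    "PSDGeneratorSpec",
    "ImpactionGeneratorSpec",
    "ConditionGrid",
    "default_grid",
    "lognormal_cdf",
    "mixture_cdf",
    "generate_psd_replicates",
    "generate_condition_grid",
    "generate_impaction_run",
]


def default_grid(n: int = 100, lo: float = 0.5, hi: float = 100.0) -> SizeGrid:
    """Log-spaced diameter grid mimicking an R3-lens diffraction export."""
    return SizeGrid(np.geomspace(lo, hi, n))


def lognormal_cdf(x: np.ndarray, median: float, gsd: float) -> np.ndarray:
    """CDF of a log-normal with geometric median and geometric SD."""
    return stats.norm.cdf((np.log(x) - math.log(median)) / math.log(gsd))


@dataclass(frozen=True)
class PSDGeneratorSpec:
    """Parameters of the bimodal replicate-PSD generator.

    Defaults portray a spray-dried respirable powder: a ~2 µm fine primary
    mode (GSD 1.6) and a ~20 µm agglomerate mode (GSD 1.8), triplicate
    measurements, and mild correlated replicate noise (logit SD 0.05).
    """

    grid: SizeGrid = field(default_factory=default_grid)
    fine_mode: tuple = (2.0, 1.6)    # (geometric median µm, geometric SD)
    coarse_mode: tuple = (20.0, 1.8)
    coarse_weight: float = 0.3
    replicate_noise: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fm, fs = self.fine_mode
        cm, cs = self.coarse_mode
        if fs <= 1 or cs <= 1:
            raise ValueError("geometric SDs must exceed 1")
        if not (self.grid.min <= fm <= self.grid.max and self.grid.min <= cm <= self.grid.max):
            raise ValueError("mode medians must lie within the grid range")
        if cm <= fm:
            raise ValueError("coarse median must exceed fine median")
        if not 0.0 <= self.coarse_weight <= 1.0:
            raise ValueError("coarse_weight must be in [0, 1]")
        if self.replicate_noise < 0:
            raise ValueError("replicate_noise must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ImpactionGeneratorSpec:
    """Parameters of the sharp-cut NGI deposition generator."""

    mmad: float = 3.0
    gsd: float = 2.0
    ef: float = 0.8
    induction_port_fraction: float = 0.15
    total_recovered: float = 1000.0
    nominal_dose: float = 1000.0
    flow_rate: float = 56.6
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mmad <= 0:
            raise ValueError("mmad must be positive")
        if self.gsd < 1:
            raise ValueError("gsd must be >= 1")
        if not 0.0 <= self.ef <= 1.0:
            raise ValueError("ef must be in [0, 1]")
        if not 0.0 <= self.induction_port_fraction <= 1.0:
            raise ValueError("induction_port_fraction must be in [0, 1]")
        if self.total_recovered <= 0 or self.nominal_dose <= 0:
            raise ValueError("masses must be positive")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def mixture_cdf(grid: SizeGrid, spec: PSDGeneratorSpec) -> np.ndarray:
    """Ideal bimodal curve F(x) = (1−w)·LN(fine) + w·LN(coarse)."""
    x = grid.diameters
    fine = lognormal_cdf(x, *spec.fine_mode)
    coarse = lognormal_cdf(x, *spec.coarse_mode)
    w = spec.coarse_weight
    return (1.0 - w) * fine + w * coarse


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, sigma: float = 3.0) -> np.ndarray:
    """Correlated Gaussian noise with pointwise SD ``sd`` (unit-l2 kernel)."""
    half = int(math.ceil(3 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= np.linalg.norm(k)
    z = rng.standard_normal(n + 2 * half)
    return sd * np.convolve(z, k, mode="valid")


def generate_psd_replicates(
    spec: PSDGeneratorSpec,
    condition: DispersionCondition | None = None,
    label: str = "synthetic",
) -> ReplicateSet:
    """Draw replicate Q3 curves around the ideal bimodal mixture CDF.

    With ``replicate_noise = 0`` every replicate equals the ideal curve
    exactly.  Otherwise smooth noise is added on the logit scale, the result
    re-monotonized by running maximum and clipped to [0, 1]; the curve keeps
    the mixture's mass below the grid maximum at its endpoint (real exports
    saturate the same way).
    """
    if condition is None:
        condition = DispersionCondition(
            formulation="synthetic", disperser=Disperser.REFERENCE, rodos_pressure=3.0
        )
    ideal = mixture_cdf(spec.grid, spec)
    rng = np.random.default_rng(spec.seed)
    eps = 1e-9
    reps = []
    for i in range(spec.n_replicates):
        if spec.replicate_noise == 0:
            vals = ideal
        else:
            logit = np.log(np.clip(ideal, eps, 1 - eps) / np.clip(1 - ideal, eps, 1 - eps))
            noisy = logit + _smooth_noise(rng, len(spec.grid), spec.replicate_noise)
            vals = np.clip(np.maximum.accumulate(1.0 / (1.0 + np.exp(-noisy))), 0.0, 1.0)
        reps.append(
            CumulativePSD(
                grid=spec.grid,
                values=vals,
                label=f"{label}_rep{i + 1}",
                condition=condition,
            )
        )
    return ReplicateSet(condition=condition, replicates=tuple(reps))


@dataclass(frozen=True)
class ConditionGrid:
    """A synthetic study design: one reference set plus per-condition sets."""

    reference: ReplicateSet
    dispersed: Mapping[tuple, ReplicateSet]  # (ResistanceClass, pressure_kPa) -> set


def generate_condition_grid(
    base: PSDGeneratorSpec,
    weight_map: Mapping[tuple, float],
    formulation: str = "synthetic",
    reference_pressure: float = 3.0,
) -> ConditionGrid:
    """One replicate set per (device class, pressure drop) plus the reference.

    ``weight_map`` assigns the coarse-mode weight of each inhaler condition
    and must cover the full factorial of the device classes and pressures it
    mentions.  The reference set uses coarse weight 0 (fully deagglomerated).
    Per-condition sub-seeds derive from the base seed by hashing the
    condition, so conditions are mutually seed-isolated.
    """
    wmap = {(ResistanceClass(k[0]), float(k[1])): float(w) for k, w in weight_map.items()}
    classes = sorted({k[0] for k in wmap}, key=lambda c: c.value)
    pressures = sorted({k[1] for k in wmap})
    missing = [(c.value, p) for c in classes for p in pressures if (c, p) not in wmap]
    if missing:
        raise ValueError(f"weight map is not a full factorial; missing {missing}")

    ref_condition = DispersionCondition(
        formulation=formulation,
        disperser=Disperser.REFERENCE,
        rodos_pressure=reference_pressure,
    )
    ref_spec = replace(
        base,
        coarse_weight=0.0,
        seed=condition_seed(base.seed, (formulation, "reference", reference_pressure)),
    )
    reference = generate_psd_replicates(ref_spec, condition=ref_condition, label="reference")

    dispersed = {}
    for (cls, pressure) in sorted(wmap, key=lambda k: (k[0].value, k[1])):
        cond = DispersionCondition(
            formulation=formulation,
            disperser=Disperser.INHALER,
            device_resistance_class=cls,
            pressure_drop=pressure,
        )
        sub = replace(
            base,
            coarse_weight=wmap[(cls, pressure)],
            seed=condition_seed(base.seed, (formulation, cls.value, pressure)),
        )
        dispersed[(cls, pressure)] = generate_psd_replicates(
            sub, condition=cond, label=f"{cls.value}_{pressure:g}kPa"
        )
    return ConditionGrid(reference=reference, dispersed=dispersed)


def generate_impaction_run(spec: ImpactionGeneratorSpec) -> ImpactionRun:
    """Sharp-cut NGI deposition from an aerodynamic log-normal.

    The emitted dose is ``ef × total_recovered``; device retention is split
    3:1 between inhaler body and mouthpiece adaptor.  An induction-port
    fraction of the emitted dose deposits pre-classification; the remainder
    is apportioned to stages by log-normal CDF differences between
    consecutive D50 cutoffs (stage 1 collects everything above its cut, the
    MOC everything below stage 7's).  Component masses optionally receive
    mean-preserving multiplicative log-normal noise with the given CV.
    """
    cuts = stage_cutoffs(spec.flow_rate)
    emitted = spec.ef * spec.total_recovered
    retained = spec.total_recovered - emitted
    ip = spec.induction_port_fraction * emitted
    sized = emitted - ip

    d50 = np.array([cuts.d50[s] for s in STAGES])
    cdf = lognormal_cdf(d50, spec.mmad, spec.gsd)
    upper = np.concatenate([[1.0], cdf[:-1]])  # stage 1 upper bound = infinity
    stage_masses = sized * (upper - cdf)
    moc = sized * cdf[-1]

    masses = {
        "device": 0.75 * retained,
        "mouthpiece_adaptor": 0.25 * retained,
        "induction_port": ip,
        **{s: float(m) for s, m in zip(STAGES, stage_masses)},
        "moc": float(moc),
    }
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        for k in masses:
            factor = math.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)
            masses[k] *= factor
    return ImpactionRun(
        masses=masses,
        nominal_dose=spec.nominal_dose,
        flow_rate=spec.flow_rate,
        formulation="synthetic",
    )
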