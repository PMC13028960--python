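"""Bootstrap uncertainty for W1 and descriptive effect-to-noise ratios.

Each W1 value is a single distribution-to-distribution comparison built from
finitely many (typically three) replicate curves per side, so classical
inference does not apply directly.  Uncertainty is instead quantified by
nonparametric bootstrap: replicates are resampled with replacement on each
side independently, re-pooled by pointwise averaging, and the transport
distance recomputed; the bootstrap SD estimates the variability of W1 under
repeated experiments with the same finite replication.

Effect sizes for the three design factors (formulation, device resistance,
pressure drop) are summarized descriptively as the across-level spread of
bootstrap-mean W1 within fixed combinations of the remaining factors, and
compared with the mean bootstrap SD as an effect-to-noise ratio.  No p-values
are produced.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .psd import ReplicateSet, align_replicates
from .wasserstein import _w1_on_grid

__all__ = [
    "BootstrapSummary",
    "Factor",
    "EffectNoiseReport",
    "bootstrap_w1",
    "effect_to_noise",
    "condition_seed",
]

logger = logging.getLogger(__name__)

_CI_TOL = 1e-9


@dataclass(frozen=True)
class BootstrapSummary:
    """Observed W1 with its bootstrap mean, SD and 95% percentile CI (µm)."""

    condition: tuple  # (formulation, device_resistance_class, pressure_drop_kPa)
    observed_w1: float
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.boot_sd < 0:
            raise ValueError("boot_sd cannot be negative")
        if not (self.ci_low - _CI_TOL <= self.boot_mean <= self.ci_high + _CI_TOL):
            raise ValueError("bootstrap mean must lie inside the percentile CI")
        object.__setattr__(self, "condition", tuple(self.condition))


class Factor(str, Enum):
    FORMULATION = "formulation"
    DEVICE_RESISTANCE = "device_resistance"
    PRESSURE_DROP = "pressure_drop"


@dataclass(frozen=True)
class EffectNoiseReport:
    """Across-level effect magnitude of one factor relative to bootstrap noise."""

    factor: Factor
    effect_magnitude: float  # µm
    noise_level: float       # µm
    ratio: float

    def __post_init__(self) -> None:
        if self.effect_magnitude < 0:
            raise ValueError("effect magnitude cannot be negative")
        if self.noise_level <= 0:
            raise ValueError("noise level must be positive")


def condition_seed(root_seed: int, condition: tuple) -> int:
    """Stable per-condition sub-seed derived from a root seed.

    The sub-seed depends only on the root seed and the condition triple
    (via CRC32 of its canonical string), so adding or removing conditions
    never perturbs the draws of other conditions.
    """
    tag = zlib.crc32("|".join(str(c) for c in condition).encode("utf-8"))
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def bootstrap_w1(
    reference: ReplicateSet,
    dispersed: ReplicateSet,
    iterations: int = 2000,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap the pooled-curve W1 between two replicate sets.

    Per iteration, ``len(reference)`` reference and ``len(dispersed)``
    dispersed replicates are drawn with replacement (independently per side),
    pooled by pointwise mean, and the Riemann-sum W1 recomputed on the shared
    grid.  The bootstrap distribution is summarized by mean, sample SD
    (n−1 denominator) and the 2.5/97.5 empirical percentiles with linear
    interpolation between order statistics.  The observed W1 uses the
    unresampled pooled curves.  Deterministic given ``seed``.
    """
    if len(reference) < 2 or len(dispersed) < 2:
        raise ValueError("bootstrap requires at least 2 replicates on each side")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if iterations < 100:
        logger.warning(
            "bootstrap with only %d iterations; percentile CI will be coarse",
            iterations,
        )

    grid, (ref_a, disp_a) = align_replicates([reference, dispersed])
    x = grid.diameters
    dx = np.diff(x)
    R = np.stack([r.values for r in ref_a.replicates])   # (n_R, m)
    D = np.stack([r.values for r in disp_a.replicates])  # (n_D, m)

    observed = _w1_on_grid(x, R.mean(axis=0), D.mean(axis=0))

    rng = np.random.default_rng(seed)
    idx_r = rng.integers(0, R.shape[0], size=(iterations, R.shape[0]))
    idx_d = rng.integers(0, D.shape[0], size=(iterations, D.shape[0]))
    ref_means = R[idx_r].mean(axis=1)   # (iterations, m)
    disp_means = D[idx_d].mean(axis=1)
    draws = np.sum(np.abs(ref_means[:, :-1] - disp_means[:, :-1]) * dx, axis=1)

    boot_mean = float(draws.mean())
    if iterations > 1 and np.ptp(draws) > 0:
        boot_sd = float(draws.std(ddof=1))
    else:
        boot_sd = 0.0  # degenerate resampling: identical draws have zero spread
    ci_low, ci_high = (float(q) for q in np.percentile(draws, [2.5, 97.5]))

    cond = dispersed.condition
    triple = (
        cond.formulation,
        cond.device_resistance_class.value if cond.device_resistance_class else "",
        cond.pressure_drop if cond.pressure_drop is not None else float("nan"),
    )
    return BootstrapSummary(
        condition=triple,
        observed_w1=observed,
        boot_mean=boot_mean,
        boot_sd=boot_sd,
        ci_low=ci_low,
        ci_high=ci_high,
        iterations=iterations,
        seed=int(seed),
    )


def effect_to_noise(summaries: Sequence[BootstrapSummary]) -> list[EffectNoiseReport]:
    """Descriptive effect-to-noise ratios over a full factorial of conditions.

    Formulation effect: SD (n−1) of bootstrap-mean W1 across formulations
    within each device–pressure cell, averaged across cells.  Device and
    pressure effects: across-level range (max − min) of bootstrap-mean W1
    within each fixed combination of the remaining two factors, averaged
    across combinations.  The noise level for every factor is the mean
    bootstrap SD over all conditions.  Ratios are effect / noise.
    """
    table: dict[tuple, BootstrapSummary] = {}
    for s in summaries:
        if s.condition in table:
            raise ValueError(f"duplicate summary for condition {s.condition}")
        table[s.condition] = s
    forms = sorted({c[0] for c in table})
    devices = sorted({c[1] for c in table})
    pressures = sorted({c[2] for c in table})
    if min(len(forms), len(devices), len(pressures)) < 2:
        raise ValueError("effect-to-noise requires >= 2 levels per factor")
    missing = [
        (f, d, p)
        for f, d, p in itertools.product(forms, devices, pressures)
        if (f, d, p) not in table
    ]
    if missing:
        raise ValueError(f"incomplete factorial; missing cells: {missing}")

    def mean_of(cells: list[float]) -> float:
        return float(np.mean(cells))

    noise = mean_of([s.boot_sd for s in table.values()])
    if noise <= 0:
        raise ValueError("mean bootstrap SD is zero; effect-to-noise undefined")

    formulation_effect = mean_of(
        [
            float(np.std([table[(f, d, p)].boot_mean for f in forms], ddof=1))
            for d in devices
            for p in pressures
        ]
    )
    device_effect = mean_of(
        [
            float(np.ptp([table[(f, d, p)].boot_mean for d in devices]))
            for f in forms
            for p in pressures
        ]
    )
    pressure_effect = mean_of(
        [
            float(np.ptp([table[(f, d, p)].boot_mean for p in pressures]))
            for f in forms
            for d in devices
        ]
    )
    return [
        EffectNoiseReport(Factor.FORMULATION, formulation_effect, noise,
                          formulation_effect / noise),
        EffectNoiseReport(Factor.DEVICE_RESISTANCE, device_effect, noise,
                          device_effect / noise),
        EffectNoiseReport(Factor.PRESSURE_DROP, pressure_effect, noise,
                          pressure_effect / noise),
    ]
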