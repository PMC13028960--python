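"""Next Generation Impactor (NGI) cascade-impaction analytics.

Recovered tracer masses per impactor component are reduced to the standard
aerodynamic performance metrics for inhaled products:

* flow-scaled stage cut-size diameters (D50) from the archival NGI
  calibration of Marple et al. (d50 = C · (60/Q)^x per stage, valid for
  Q between 30 and 100 L/min, no pre-separator),
* emitted fraction (EF, % of total recovery leaving the device),
* fine particle fraction (FPF, % of emitted dose below a cut diameter,
  5 µm by default, with stage membership decided from the flow-scaled
  cutoffs rather than fixed stage indices),
* MMAD and GSD by least-squares regression of probit-transformed cumulative
  mass undersize against log10 aerodynamic diameter, and
* mass balance against the nominal loaded dose (85–115% acceptance window).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "COMPONENTS",
    "STAGES",
    "ImpactionRun",
    "StageCutoffs",
    "AerodynamicMetrics",
    "MmadFit",
    "MassBalance",
    "stage_cutoffs",
    "emitted_fraction",
    "fine_particle_fraction",
    "mmad_gsd",
    "mass_balance",
    "aerodynamic_metrics",
]

logger = logging.getLogger(__name__)

STAGES = tuple(f"stage{i}" for i in range(1, 8))
COMPONENTS = ("device", "mouthpiece_adaptor", "induction_port") + STAGES + ("moc",)

# Archival NGI calibration (no pre-separator): stage D50 at 60 L/min (µm) and
# the flow-scaling exponent per stage, d50(Q) = d50_60 · (60/Q)^x.
# Validated against the 4.60 µm stage-2 cutoff at 56.6 L/min.
NGI_D50_AT_60LPM = MappingProxyType(
    {
        "stage1": 8.06,
        "stage2": 4.46,
        "stage3": 2.82,
        "stage4": 1.66,
        "stage5": 0.94,
        "stage6": 0.55,
        "stage7": 0.34,
    }
)
NGI_FLOW_EXPONENT = MappingProxyType(
    {
        "stage1": 0.54,
        "stage2": 0.52,
        "stage3": 0.50,
        "stage4": 0.47,
        "stage5": 0.53,
        "stage6": 0.60,
        "stage7": 0.67,
    }
)
FLOW_VALIDITY_LPM = (30.0, 100.0)
MASS_BALANCE_WINDOW = (85.0, 115.0)


@dataclass(frozen=True)
class ImpactionRun:
    """Recovered tracer masses per component for one impaction experiment.

    Masses are in arbitrary but consistent units (e.g. µg of dye); every
    metric except mass balance is invariant to a common rescaling.
    """

    masses: Mapping[str, float]
    nominal_dose: float
    flow_rate: float  # L/min
    formulation: str = ""

    def __post_init__(self) -> None:
        m = dict(self.masses)
        if set(m) != set(COMPONENTS):
            extra = sorted(set(m) - set(COMPONENTS))
            missing = sorted(set(COMPONENTS) - set(m))
            raise ValueError(
                f"masses must cover exactly the NGI components; "
                f"missing={missing}, unexpected={extra}"
            )
        for k, v in m.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"mass for {k} must be finite and >= 0, got {v}")
        if self.nominal_dose <= 0:
            raise ValueError("nominal_dose must be positive")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        object.__setattr__(self, "masses", MappingProxyType(m))

    @property
    def total_recovered(self) -> float:
        return float(sum(self.masses.values()))

    @property
    def emitted_dose(self) -> float:
        return self.total_recovered - self.masses["device"] - self.masses["mouthpiece_adaptor"]


@dataclass(frozen=True)
class StageCutoffs:
    """Flow-scaled stage D50 diameters (µm), strictly decreasing stage1..7."""

    flow_rate: float
    d50: Mapping[str, float]

    def __post_init__(self) -> None:
        d = dict(self.d50)
        if tuple(d) != STAGES:
            raise ValueError("d50 must cover stage1..stage7 in order")
        vals = list(d.values())
        if any(v <= 0 for v in vals) or any(a >= b for a, b in zip(vals[1:], vals)):
            raise ValueError("stage cutoffs must be positive and strictly decreasing")
        object.__setattr__(self, "d50", MappingProxyType(d))


@dataclass(frozen=True)
class MmadFit:
    """Probit-regression fit of the cumulative aerodynamic size distribution."""

    mmad: float
    gsd: float
    slope: float
    intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class MassBalance:
    percent: float
    passed: bool


@dataclass(frozen=True)
class AerodynamicMetrics:
    """Headline impaction metrics for one run."""

    ef_percent: float
    fpf_percent: float
    mmad: float
    gsd: float
    mass_balance_percent: float
    mass_balance_pass: bool
    fit_r2: float
    n_fit_points: int

    def __post_init__(self) -> None:
        if not 0 <= self.ef_percent <= 100:
            raise ValueError("EF must be in [0, 100]%")
        if not 0 <= self.fpf_percent <= 100:
            raise ValueError("FPF must be in [0, 100]%")
        if self.gsd < 1:
            raise ValueError("GSD must be >= 1")


def stage_cutoffs(flow_rate: float) -> StageCutoffs:
    """Stage D50 cut diameters at the given volumetric flow (L/min)."""
    lo, hi = FLOW_VALIDITY_LPM
    if not lo <= flow_rate <= hi:
        raise ValueError(
            f"flow {flow_rate:g} L/min outside the {lo:g}-{hi:g} L/min validity "
            "range of the archival NGI cut-size equations"
        )
    ratio = 60.0 / flow_rate
    d50 = {s: NGI_D50_AT_60LPM[s] * ratio ** NGI_FLOW_EXPONENT[s] for s in STAGES}
    return StageCutoffs(flow_rate=float(flow_rate), d50=d50)


def emitted_fraction(run: ImpactionRun) -> float:
    """Percent of total recovered mass emitted from the device.

    Device retention counts the inhaler body plus the mouthpiece adaptor
    (both upstream of the induction port).
    """
    total = run.total_recovered
    if total <= 0:
        raise ValueError("zero total recovery; emitted fraction undefined")
    return 100.0 * run.emitted_dose / total


def fine_particle_fraction(run: ImpactionRun, threshold: float = 5.0) -> float:
    """Percent of the emitted dose below the aerodynamic cut ``threshold`` (µm).

    Membership is cutoff-driven: the mass on every stage whose flow-scaled
    D50 lies below the threshold, plus the MOC, over the emitted dose.  At
    56.6 L/min and the default 5 µm threshold this selects stage 2 (4.60 µm)
    through the MOC.
    """
    emitted = run.emitted_dose
    if emitted <= 0:
        raise ValueError("emitted dose is zero; FPF undefined")
    cuts = stage_cutoffs(run.flow_rate)
    fine_stages = [s for s in STAGES if cuts.d50[s] < threshold]
    if not fine_stages:
        logger.warning(
            "no stage cutoff below %g µm at %g L/min; FPF reduces to the MOC fraction",
            threshold,
            run.flow_rate,
        )
    fine_mass = sum(run.masses[s] for s in fine_stages) + run.masses["moc"]
    return 100.0 * fine_mass / emitted


def mmad_gsd(run: ImpactionRun, include_induction_port: bool = False) -> MmadFit:
    """MMAD and GSD from probit-transformed cumulative mass undersize.

    For each stage k with cutoff d50_k, the cumulative undersize U_k is the
    mass collected on stages k+1..7 plus the MOC, over the size-classified
    mass (stages 1–7 + MOC; optionally also the induction port in the
    denominator).  Stages with U strictly inside (0, 1) contribute a point
    (log10 d50_k, probit U_k); a least-squares line through >= 3 such points
    yields MMAD = 10^(−intercept/slope) and GSD = 10^(1/slope).
    """
    cuts = stage_cutoffs(run.flow_rate)
    sized = sum(run.masses[s] for s in STAGES) + run.masses["moc"]
    denom = sized + (run.masses["induction_port"] if include_induction_port else 0.0)
    if denom <= 0:
        raise ValueError("no size-classified mass; MMAD undefined")
    xs, ys = [], []
    for i, s in enumerate(STAGES):
        below = sum(run.masses[t] for t in STAGES[i + 1:]) + run.masses["moc"]
        u = below / denom
        if 0.0 < u < 1.0:
            xs.append(math.log10(cuts.d50[s]))
            ys.append(stats.norm.ppf(u))
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} stages with cumulative undersize strictly inside "
            "(0, 1); need >= 3 for the probit regression"
        )
    fit = stats.linregress(xs, ys)
    if fit.slope <= 0:
        raise ValueError("non-positive probit slope; size distribution is non-physical")
    mmad = 10.0 ** (-fit.intercept / fit.slope)
    gsd = 10.0 ** (1.0 / fit.slope)
    return MmadFit(
        mmad=float(mmad),
        gsd=float(gsd),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_points=len(xs),
    )


def mass_balance(run: ImpactionRun) -> MassBalance:
    """Total recovery as a percent of nominal dose; pass iff within 85–115%."""
    percent = 100.0 * run.total_recovered / run.nominal_dose
    lo, hi = MASS_BALANCE_WINDOW
    return MassBalance(percent=percent, passed=lo <= percent <= hi)


def aerodynamic_metrics(
    run: ImpactionRun,
    fpf_threshold: float = 5.0,
    include_induction_port: bool = False,
) -> AerodynamicMetrics:
    """All headline metrics for one run in a single record."""
    fit = mmad_gsd(run, include_induction_port=include_induction_port)
    mb = mass_balance(run)
    return AerodynamicMetrics(
        ef_percent=emitted_fraction(run),
        fpf_percent=fine_particle_fraction(run, threshold=fpf_threshold),
        mmad=fit.mmad,
        gsd=fit.gsd,
        mass_balance_percent=mb.percent,
        mass_balance_pass=mb.passed,
        fit_r2=fit.r2,
        n_fit_points=fit.n_points,
    )
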