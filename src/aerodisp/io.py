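"""CSV readers/writers and run configuration.

File dialects are deliberately plain: comma-separated, '.' decimal, UTF-8.
PSD files carry condition metadata in '#'-prefixed ``key: value`` header
lines followed by a ``diameter_um`` column and one ``q3_percent_<i>`` column
per replicate (cumulative volume undersize in percent, as instruments
export it).  Impaction files hold one run per row.  All outputs begin with a
provenance header (package version, seed, config hash) sufficient to re-run
the command.  Configuration is a single TOML file; CLI flags override it.
"""

from __future__ import annotations

import hashlib
import io as _io
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .impaction import COMPONENTS, AerodynamicMetrics, ImpactionRun
from .psd import (
    CumulativePSD,
    DispersionCondition,
    Disperser,
    ReplicateSet,
    SizeGrid,
    normalize_from_percent,
)
from .uncertainty import BootstrapSummary, EffectNoiseReport
from .wasserstein import DispersibilityProfile, TitrationCurve, W1Result

__all__ = [
    "RunConfig",
    "load_config",
    "read_psd_csv",
    "write_psd_csv",
    "read_impaction_csv",
    "write_impaction_csv",
    "write_metrics_csv",
    "write_profile_csv",
    "write_titration_csv",
    "write_bootstrap_csv",
    "read_bootstrap_csv",
    "write_effect_noise_csv",
    "provenance_header",
]

_CONDITION_KEYS = (
    "formulation",
    "disperser",
    "device_resistance_class",
    "resistance",
    "pressure_drop",
    "rodos_pressure",
)
_NUMERIC_CONDITION_KEYS = {"resistance", "pressure_drop", "rodos_pressure"}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings loaded from a TOML file."""

    psd_paths: tuple = ()
    impaction_path: str | None = None
    device_table: dict = field(default_factory=dict)  # name -> {class, resistance}
    reference_formulation: str | None = None
    bootstrap_iterations: int = 2000
    seed: int = 0
    fpf_threshold_um: float = 5.0
    lens_min_um: float = 0.5
    assumed_floor_um: float = 0.25
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        for name, value in (
            ("fpf_threshold_um", self.fpf_threshold_um),
            ("lens_min_um", self.lens_min_um),
            ("assumed_floor_um", self.assumed_floor_um),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for p in list(self.psd_paths) + ([self.impaction_path] if self.impaction_path else []):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return RunConfig(
        psd_paths=tuple(raw.get("psd_paths", ())),
        impaction_path=raw.get("impaction_path"),
        device_table=dict(raw.get("devices", {})),
        reference_formulation=raw.get("reference_formulation"),
        bootstrap_iterations=int(raw.get("bootstrap_iterations", 2000)),
        seed=int(raw.get("seed", 0)),
        fpf_threshold_um=float(raw.get("fpf_threshold_um", 5.0)),
        lens_min_um=float(raw.get("lens_min_um", 0.5)),
        assumed_floor_um=float(raw.get("assumed_floor_um", 0.25)),
        output_dir=raw.get("output_dir", "."),
    )


def provenance_header(seed: int | None = None, config_text: str | None = None,
                      command: str | None = None) -> str:
    """'#'-prefixed provenance block for output files."""
    lines = [f"# aerodisp_version: {__version__}"]
    if command:
        lines.append(f"# command: {command}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_text is not None:
        digest = hashlib.sha256(config_text.encode("utf-8")).hexdigest()[:16]
        lines.append(f"# config_sha256: {digest}")
    return "\n".join(lines) + "\n"


def _num(s: str) -> float:
    return float(s)


def read_psd_csv(path: str | Path) -> list[ReplicateSet]:
    """Read one PSD file (one condition, >= 1 replicate columns)."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise ValueError(f"{path}: no tabular content")
    try:
        frame = pd.read_csv(_io.StringIO("".join(body_lines)))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: cannot parse CSV body ({exc})") from exc
    if "diameter_um" not in frame.columns:
        raise ValueError(f"{path}: missing required 'diameter_um' column")
    if len(frame) < 2:
        raise ValueError(f"{path}: needs at least 2 diameter rows, found {len(frame)}")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data line {bad + 2}"
            )
    diameters = frame["diameter_um"].to_numpy(dtype=float)
    if np.any(np.diff(diameters) <= 0):
        raise ValueError(f"{path}: diameter_um must be strictly increasing")
    grid = SizeGrid(diameters)

    cond_kwargs = {}
    for key in _CONDITION_KEYS:
        if key in meta:
            cond_kwargs[key] = _num(meta[key]) if key in _NUMERIC_CONDITION_KEYS else meta[key]
    if "formulation" not in cond_kwargs or "disperser" not in cond_kwargs:
        raise ValueError(
            f"{path}: metadata header must set at least 'formulation' and 'disperser'"
        )
    condition = DispersionCondition(**cond_kwargs)

    rep_cols = [c for c in frame.columns if c.startswith("q3_percent")]
    if not rep_cols:
        raise ValueError(f"{path}: no 'q3_percent*' replicate columns found")
    replicates = tuple(
        normalize_from_percent(
            frame[c].to_numpy(dtype=float), grid, label=f"{path.stem}:{c}", condition=condition
        )
        for c in rep_cols
    )
    return [ReplicateSet(condition=condition, replicates=replicates)]


def write_psd_csv(path: str | Path, rs: ReplicateSet, seed: int | None = None) -> None:
    """Write a replicate set in the dialect :func:`read_psd_csv` consumes."""
    first = rs.replicates[0]
    for r in rs.replicates[1:]:
        if r.grid != first.grid:
            raise ValueError("replicates must share one grid to be written to a single file")
    lines = [provenance_header(seed=seed).rstrip("\n")]
    for key, value in rs.condition.to_dict().items():
        lines.append(f"# {key}: {value}")
    header = ["diameter_um"] + [f"q3_percent_{i + 1}" for i in range(len(rs))]
    lines.append(",".join(header))
    cols = [first.grid.diameters] + [100.0 * r.values for r in rs.replicates]
    for row in zip(*cols):
        lines.append(",".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_IMPACTION_COLUMNS = ("formulation", "flow_lpm", "nominal_dose") + COMPONENTS


def read_impaction_csv(path: str | Path) -> list[ImpactionRun]:
    """Read impaction runs, one per row."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _IMPACTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing impaction columns {missing}")
    runs = []
    for _, row in frame.iterrows():
        runs.append(
            ImpactionRun(
                masses={c: float(row[c]) for c in COMPONENTS},
                nominal_dose=float(row["nominal_dose"]),
                flow_rate=float(row["flow_lpm"]),
                formulation=str(row["formulation"]),
            )
        )
    return runs


def write_impaction_csv(path: str | Path, runs: Sequence[ImpactionRun],
                        seed: int | None = None) -> None:
    rows = [
        {
            "formulation": r.formulation,
            "flow_lpm": r.flow_rate,
            "nominal_dose": r.nominal_dose,
            **{c: r.masses[c] for c in COMPONENTS},
        }
        for r in runs
    ]
    _write_frame(path, pd.DataFrame(rows, columns=list(_IMPACTION_COLUMNS)), seed=seed)


def _write_frame(path: str | Path, frame: pd.DataFrame, seed: int | None = None,
                 config_text: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed=seed, config_text=config_text))
        frame.to_csv(fh, index=False)


def write_metrics_csv(path: str | Path, metrics: Sequence[tuple[str, AerodynamicMetrics]],
                      seed: int | None = None) -> None:
    rows = [
        {
            "formulation": name,
            "ef_percent": m.ef_percent,
            "fpf_percent": m.fpf_percent,
            "mmad_um": m.mmad,
            "gsd": m.gsd,
            "mass_balance_percent": m.mass_balance_percent,
            "mass_balance_pass": m.mass_balance_pass,
            "fit_r2": m.fit_r2,
            "n_fit_points": m.n_fit_points,
        }
        for name, m in metrics
    ]
    _write_frame(path, pd.DataFrame(rows), seed=seed)


def write_profile_csv(path: str | Path, profile: DispersibilityProfile,
                      seed: int | None = None) -> None:
    rows = [
        {
            "formulation": profile.formulation,
            "device": cls.value,
            "pressure_kPa": pressure,
            "w1_um": res.value,
            "grid_min_um": res.grid_min,
            "grid_max_um": res.grid_max,
            "n_points": res.n_grid_points,
        }
        for cls, pressure, res in profile.entries
    ]
    _write_frame(path, pd.DataFrame(rows), seed=seed)


def write_titration_csv(path: str | Path, curve: TitrationCurve,
                        seed: int | None = None) -> None:
    rows = [
        {"formulation": curve.formulation, "rodos_pressure_bar": p, "w1_um": w}
        for p, w in curve.points
    ]
    _write_frame(path, pd.DataFrame(rows), seed=seed)


_BOOT_COLUMNS = (
    "formulation",
    "device",
    "pressure_kPa",
    "observed_w1",
    "boot_mean",
    "boot_sd",
    "ci_low",
    "ci_high",
    "iterations",
    "seed",
)


def write_bootstrap_csv(path: str | Path, summaries: Sequence[BootstrapSummary],
                        seed: int | None = None) -> None:
    rows = [
        {
            "formulation": s.condition[0],
            "device": s.condition[1],
            "pressure_kPa": s.condition[2],
            "observed_w1": s.observed_w1,
            "boot_mean": s.boot_mean,
            "boot_sd": s.boot_sd,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "iterations": s.iterations,
            "seed": s.seed,
        }
        for s in summaries
    ]
    _write_frame(path, pd.DataFrame(rows, columns=list(_BOOT_COLUMNS)), seed=seed)


def read_bootstrap_csv(path: str | Path) -> list[BootstrapSummary]:
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _BOOT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing bootstrap columns {missing}")
    return [
        BootstrapSummary(
            condition=(str(row["formulation"]), str(row["device"]), float(row["pressure_kPa"])),
            observed_w1=float(row["observed_w1"]),
            boot_mean=float(row["boot_mean"]),
            boot_sd=float(row["boot_sd"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            iterations=int(row["iterations"]),
            seed=int(row["seed"]),
        )
        for _, row in frame.iterrows()
    ]


def write_effect_noise_csv(path: str | Path, reports: Sequence[EffectNoiseReport],
                           seed: int | None = None) -> None:
    rows = [
        {
            "factor": r.factor.value,
            "effect_magnitude_um": r.effect_magnitude,
            "noise_level_um": r.noise_level,
            "ratio": r.ratio,
        }
        for r in reports
    ]
    _write_frame(path, pd.DataFrame(rows), seed=seed)
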