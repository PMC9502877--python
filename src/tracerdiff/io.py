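"""CSV readers/writers and run configuration.

Formats (RFC-4180 CSV, ``.`` decimal separator, units fixed in the column
names to prevent silent unit drift):

* compound registry — ``name, M_g_mol, Tc_K, Vc_cm3_mol``
* measurement table — ``system_id, subset, solvent, solute, T_K, P_bar,
  rho1_g_cm3, D12_cm2_s`` (``P_bar`` may be empty: the model never uses
  pressure; density is mandatory)

Floats are written with full ``repr`` precision, so a written report
re-parses to its in-memory value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Compound, ModelParams, StatePoint
from .fitting import EvaluationReport, FitResult, MeasurementSet, SUBSET_TAGS

__all__ = [
    "RunConfig",
    "read_compound_registry",
    "write_compound_registry",
    "read_measurements",
    "write_measurements",
    "write_fit_report",
    "write_evaluation_report",
    "write_run_summary",
    "load_run_config",
]

REGISTRY_COLUMNS = ["name", "M_g_mol", "Tc_K", "Vc_cm3_mol"]
MEASUREMENT_COLUMNS = [
    "system_id", "subset", "solvent", "solute",
    "T_K", "P_bar", "rho1_g_cm3", "D12_cm2_s",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings of one fit/evaluate run; flags override file values."""

    registry: Optional[str] = None
    measurements: Optional[str] = None
    out_dir: str = "."
    init_k12: float = 0.0
    init_b12: float = 0.4
    tolerance: float = 1e-8
    max_evals: int = 2000
    b12_min: float = 0.0
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (flat key: value mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# Compound registry
# ---------------------------------------------------------------------------

def read_compound_registry(path: str | Path) -> dict[str, Compound]:
    """Read a compound registry CSV; returns name -> Compound."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry {path}: missing column(s) {missing}")
    registry: dict[str, Compound] = {}
    for i, row in df.iterrows():
        name = str(row["name"])
        if name in registry:
            raise ValueError(f"registry {path}, row {i}: duplicate name {name!r}")
        try:
            registry[name] = Compound(
                name=name,
                molar_mass=float(row["M_g_mol"]),
                critical_temperature=float(row["Tc_K"]),
                critical_volume=float(row["Vc_cm3_mol"]),
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"registry {path}, row {i} ({name!r}): {err}") from err
    return registry


def write_compound_registry(
    compounds: Sequence[Compound] | dict[str, Compound],
    path: str | Path,
) -> None:
    if isinstance(compounds, dict):
        compounds = list(compounds.values())
    df = pd.DataFrame({
        "name": [c.name for c in compounds],
        "M_g_mol": [c.molar_mass for c in compounds],
        "Tc_K": [c.critical_temperature for c in compounds],
        "Vc_cm3_mol": [c.critical_volume for c in compounds],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def read_measurements(
    path: str | Path,
    registry: dict[str, Compound],
) -> list[MeasurementSet]:
    """Read a measurement table, grouping rows into MeasurementSets.

    Rows are grouped by ``system_id`` (order of first appearance, row
    order preserved inside each system).  Every solvent/solute name must
    resolve in the registry.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurements {path}: missing column(s) {missing}")

    systems: list[MeasurementSet] = []
    for system_id, group in df.groupby("system_id", sort=False):
        first = group.iloc[0]
        for col in ("subset", "solvent", "solute"):
            if group[col].nunique() != 1:
                raise ValueError(
                    f"measurements {path}, system {system_id!r}: "
                    f"inconsistent {col} within system"
                )
        subset = str(first["subset"])
        if subset not in SUBSET_TAGS:
            raise ValueError(
                f"measurements {path}, system {system_id!r}: unknown subset "
                f"{subset!r} (expected one of {SUBSET_TAGS})"
            )
        for role, col in (("solvent", "solvent"), ("solute", "solute")):
            if str(first[col]) not in registry:
                raise ValueError(
                    f"measurements {path}, system {system_id!r}: unknown "
                    f"{role} name {first[col]!r}"
                )
        points = []
        for i, row in group.iterrows():
            try:
                pressure = float(row["P_bar"]) if pd.notna(row["P_bar"]) else None
                points.append(StatePoint(
                    temperature=float(row["T_K"]),
                    solvent_density=float(row["rho1_g_cm3"]),
                    d12_exp=float(row["D12_cm2_s"]),
                    pressure=pressure,
                ))
            except (ValueError, TypeError) as err:
                raise ValueError(
                    f"measurements {path}, row {i} (system {system_id!r}): {err}"
                ) from err
        systems.append(MeasurementSet(
            solvent=registry[str(first["solvent"])],
            solute=registry[str(first["solute"])],
            points=tuple(points),
            subset_tag=subset,
            system_id=str(system_id),
        ))
    if not systems:
        raise ValueError(f"measurements {path}: no data rows")
    return systems


def write_measurements(
    systems: Sequence[MeasurementSet],
    path: str | Path,
) -> None:
    rows = []
    for ms in systems:
        for p in ms.points:
            rows.append({
                "system_id": ms.label,
                "subset": ms.subset_tag,
                "solvent": ms.solvent.name,
                "solute": ms.solute.name,
                "T_K": p.temperature,
                "P_bar": p.pressure if p.pressure is not None else np.nan,
                "rho1_g_cm3": p.solvent_density,
                "D12_cm2_s": p.d12_exp,
            })
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def compounds_of(systems: Sequence[MeasurementSet]) -> dict[str, Compound]:
    """Unique compounds appearing in a database, keyed by name."""
    out: dict[str, Compound] = {}
    for ms in systems:
        out.setdefault(ms.solvent.name, ms.solvent)
        out.setdefault(ms.solute.name, ms.solute)
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_fit_report(
    systems: Sequence[MeasurementSet],
    fits: Sequence[FitResult],
    path: str | Path,
) -> None:
    """Per-system fitted parameters and metrics as CSV."""
    rows = []
    for ms, fit in zip(systems, fits):
        rows.append({
            "system_id": ms.label,
            "subset": ms.subset_tag,
            "ndp": fit.metrics.ndp,
            "k12": fit.params.k12,
            "B12": fit.params.b12,
            "aard_pct": fit.metrics.aard,
            "ard_pct": fit.metrics.ard,
            "n_excluded": fit.n_excluded,
            "converged": fit.converged,
            "n_evaluations": fit.n_evaluations,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_evaluation_report(report: EvaluationReport, path: str | Path) -> None:
    """Table-style report: per-system rows, then per-subset, then global."""
    per_system = report.per_system.copy()
    per_subset = report.per_subset.rename(columns={"subset": "system_id"}).copy()
    per_subset.insert(1, "subset", per_subset["system_id"])
    glob = pd.DataFrame([{
        "system_id": "GLOBAL",
        "subset": "",
        "ndp": report.ndp,
        "n_systems": report.n_systems,
        "aard_pct": report.global_metrics.aard,
        "ard_pct": report.global_metrics.ard,
        "n_excluded": report.n_excluded,
    }])
    pd.concat([per_system, per_subset, glob], ignore_index=True).to_csv(
        path, index=False)


def write_run_summary(
    path: str | Path,
    *,
    systems: Sequence[MeasurementSet],
    fits: Sequence[FitResult],
    report: Optional[EvaluationReport] = None,
    config: Optional[RunConfig] = None,
) -> None:
    """Machine-readable JSON run summary (parameters + metrics)."""
    payload: dict = {
        "n_systems": len(systems),
        "systems": [
            {
                "system_id": ms.label,
                "subset": ms.subset_tag,
                "k12": fit.params.k12,
                "B12": fit.params.b12,
                "aard_pct": fit.metrics.aard,
                "ard_pct": fit.metrics.ard,
                "ndp": fit.metrics.ndp,
                "n_excluded": fit.n_excluded,
                "converged": fit.converged,
            }
            for ms, fit in zip(systems, fits)
        ],
    }
    if report is not None:
        payload["global"] = {
            "aard_pct": report.global_metrics.aard,
            "ard_pct": report.global_metrics.ard,
            "ndp": report.ndp,
            "n_systems": report.n_systems,
            "n_excluded": report.n_excluded,
        }
        payload["subsets"] = report.per_subset.to_dict(orient="records")
    if config is not None:
        payload["config"] = {k: getattr(config, k)
                             for k in RunConfig.__dataclass_fields__}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
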