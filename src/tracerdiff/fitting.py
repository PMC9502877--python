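"""Per-system parameter estimation and deviation metrics.

Each binary system gets its own (k12, B12), found by Nelder-Mead simplex
minimization of the average absolute relative deviation

    AARD % = 100/NDP * sum_i |D12_calc,i - D12_exp,i| / D12_exp,i

over the system's state points.  Points where the density correction
factors F11 or F12 of the hard-sphere chain are non-positive lie outside
the physical domain of those polynomials and are excluded (from each
objective evaluation and from the reported metrics), mirroring how such
states are dropped from experimental databases.

Reporting pools points, not systems: subset and global AARD/ARD are sums
over all NDP retained points, so large systems weigh more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import Compound, ModelParams, StatePoint, predict_many

logger = logging.getLogger("tracerdiff")

__all__ = [
    "MeasurementSet",
    "Metrics",
    "ExcludedPoint",
    "FitResult",
    "EvaluationReport",
    "aard",
    "ard",
    "validity_filter",
    "fit_params",
    "evaluate_database",
]

SUBSET_TAGS = ("polar", "water", "nonpolar", "scco2", "unspecified")

#: Objective value returned for out-of-bounds parameters or states where no
#: point is physically valid; large enough to dominate any plausible AARD.
_PENALTY = 1e8


@dataclass(frozen=True)
class MeasurementSet:
    """Experimental D12 data for one binary system (solvent, solute)."""

    solvent: Compound
    solute: Compound
    points: tuple[StatePoint, ...]
    subset_tag: str = "unspecified"
    system_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 1:
            raise ValueError("MeasurementSet requires at least one point")
        if self.subset_tag not in SUBSET_TAGS:
            raise ValueError(
                f"subset_tag must be one of {SUBSET_TAGS}, got {self.subset_tag!r}"
            )
        if any(p.d12_exp is None for p in self.points):
            raise ValueError("every point of a MeasurementSet needs d12_exp")

    @property
    def label(self) -> str:
        return self.system_id or f"{self.solvent.name}/{self.solute.name}"

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(T, rho1, d12_exp) as float arrays, in point order."""
        t = np.array([p.temperature for p in self.points])
        rho = np.array([p.solvent_density for p in self.points])
        dexp = np.array([p.d12_exp for p in self.points])
        return t, rho, dexp


@dataclass(frozen=True)
class Metrics:
    """AARD/ARD (%) over ndp points. |ard| <= aard always (triangle inequality)."""

    aard: float
    ard: float
    ndp: int


@dataclass(frozen=True)
class ExcludedPoint:
    """One state point dropped for a non-physical correction factor."""

    index: int
    point: StatePoint
    factor: str   # "F11" or "F12"
    value: float


@dataclass(frozen=True)
class FitResult:
    params: ModelParams
    metrics: Metrics
    n_excluded: int
    converged: bool
    n_evaluations: int
    excluded: tuple[ExcludedPoint, ...] = field(default=())


def aard(d12_calc, d12_exp) -> float:
    """Average absolute relative deviation, percent."""
    calc = np.asarray(d12_calc, dtype=float)
    exp = np.asarray(d12_exp, dtype=float)
    if calc.size == 0:
        raise ValueError("aard requires at least one (calc, exp) pair")
    return float(100.0 * np.mean(np.abs(calc - exp) / exp))


def ard(d12_calc, d12_exp) -> float:
    """Signed average relative deviation, percent (negative = underprediction)."""
    calc = np.asarray(d12_calc, dtype=float)
    exp = np.asarray(d12_exp, dtype=float)
    if calc.size == 0:
        raise ValueError("ard requires at least one (calc, exp) pair")
    return float(100.0 * np.mean((calc - exp) / exp))


def validity_filter(
    measurements: MeasurementSet,
    params: ModelParams,
) -> tuple[list[StatePoint], list[ExcludedPoint]]:
    """Partition points into physically usable and excluded.

    A point is excluded iff F11 <= 0 or F12 <= 0 at its state.  Each
    exclusion is logged with the state and the offending factor.
    """
    t, rho, _ = measurements.arrays()
    pred = predict_many(measurements.solvent, measurements.solute, t, rho, params)
    usable: list[StatePoint] = []
    excluded: list[ExcludedPoint] = []
    for i, point in enumerate(measurements.points):
        if pred["f11"][i] <= 0:
            exc = ExcludedPoint(i, point, "F11", float(pred["f11"][i]))
        elif pred["f12"][i] <= 0:
            exc = ExcludedPoint(i, point, "F12", float(pred["f12"][i]))
        else:
            usable.append(point)
            continue
        excluded.append(exc)
        logger.warning(
            "system %s: excluding point %d (T=%.4g K, rho1=%.4g g/cm3, "
            "rho*=%.4g): %s=%.6g <= 0 (non-physical)",
            measurements.label, i, point.temperature, point.solvent_density,
            float(pred["rho_star"][i]), exc.factor, exc.value,
        )
    return usable, excluded


def fit_params(
    measurements: MeasurementSet,
    init: ModelParams = ModelParams(0.0, 0.4),
    tolerance: float = 1e-8,
    max_evals: int = 2000,
    b12_min: float = 0.0,
    multistart: int = 0,
) -> FitResult:
    """Fit (k12, B12) for one system by simplex minimization of AARD.

    The objective re-applies the validity filter at every candidate:
    points with non-positive F11/F12 under that candidate are dropped
    from that evaluation.  Constraints (k12 < 1, B12 >= b12_min) are
    enforced by a large penalty.  Deterministic given init and
    tolerances.  The default init (k12=0, B12=0.4) is the physical
    baseline of a non-polar system with no diameter correction.

    ``multistart`` > 0 restarts the simplex from that many additional
    fixed initial points (a deterministic coarse grid over the usual
    parameter ranges) and keeps the best optimum; off by default since
    the AARD surface is well behaved on physically sensible data.

    With fewer than two usable points the fit is underdetermined; a
    warning is logged and the (degenerate) fit is still returned.
    """
    t, rho, dexp = measurements.arrays()
    solvent, solute = measurements.solvent, measurements.solute

    def objective(x: np.ndarray) -> float:
        k12, b12 = x
        if k12 >= 1.0 or b12 < b12_min:
            return _PENALTY + abs(k12) + abs(b12)
        pred = predict_many(solvent, solute, t, rho, (k12, b12))
        mask = pred["valid"]
        if not mask.any():
            return _PENALTY
        return aard(pred["d12"][mask], dexp[mask])

    # F11/F12 depend only on the state, not on (k12, B12), so an everywhere-
    # undefined objective can be detected up front
    mask0 = predict_many(solvent, solute, t, rho, init)["valid"]
    if not mask0.any():
        raise ValueError(
            f"system {measurements.label}: no physically valid points; "
            "objective undefined everywhere"
        )
    if int(mask0.sum()) < 2:
        logger.warning(
            "system %s: only %d usable point(s); the two-parameter fit is "
            "underdetermined", measurements.label, int(mask0.sum()),
        )

    starts = [np.array([init.k12, init.b12])]
    if multistart > 0:
        # deterministic coarse grid over the usual parameter ranges
        ks = np.linspace(-0.3, 0.3, max(2, int(np.ceil(np.sqrt(multistart)))))
        bs = np.linspace(max(b12_min, 0.0), 5.0,
                         max(2, int(np.ceil(np.sqrt(multistart)))))
        extra = [np.array([k, b]) for k in ks for b in bs]
        starts.extend(extra[:multistart])

    res = None
    nfev_total = 0
    for x0 in starts:
        cand = minimize(
            objective,
            x0=x0,
            method="Nelder-Mead",
            options={
                "xatol": tolerance,
                "fatol": tolerance,
                "maxfev": max_evals,
                "adaptive": False,
            },
        )
        nfev_total += int(cand.nfev)
        if res is None or cand.fun < res.fun:
            res = cand
    k12_fit, b12_fit = float(res.x[0]), float(res.x[1])
    params = ModelParams(min(k12_fit, 1.0 - 1e-12), max(b12_fit, 0.0))

    usable, excluded = validity_filter(measurements, params)
    if usable:
        idx = [e.index for e in excluded]
        keep = np.setdiff1d(np.arange(len(measurements.points)), idx)
        pred = predict_many(solvent, solute, t[keep], rho[keep], params)
        metrics = Metrics(
            aard=aard(pred["d12"], dexp[keep]),
            ard=ard(pred["d12"], dexp[keep]),
            ndp=len(usable),
        )
    else:
        metrics = Metrics(aard=float("nan"), ard=float("nan"), ndp=0)

    return FitResult(
        params=params,
        metrics=metrics,
        n_excluded=len(excluded),
        converged=bool(res.success),
        n_evaluations=nfev_total,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Database-level evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    """Per-system, per-subset and global deviation tables.

    ``per_system`` has one row per system; ``per_subset`` and the global
    metrics pool raw point deviations across systems (the AARD/ARD sums
    run over NDP, not over systems).
    """

    per_system: pd.DataFrame
    per_subset: pd.DataFrame
    global_metrics: Metrics
    n_systems: int
    ndp: int
    n_excluded: int


def evaluate_database(
    systems: Sequence[MeasurementSet],
    fits: Sequence[FitResult],
) -> EvaluationReport:
    """Tabulate model performance for a database of fitted systems."""
    if len(systems) == 0:
        raise ValueError("evaluate_database requires at least one system")
    if len(systems) != len(fits):
        raise ValueError("need exactly one FitResult per MeasurementSet")

    rows = []
    rel_dev: dict[str, list[np.ndarray]] = {}
    n_excluded_total = 0
    for ms, fit in zip(systems, fits):
        t, rho, dexp = ms.arrays()
        excluded_idx = [e.index for e in fit.excluded]
        keep = np.setdiff1d(np.arange(len(ms.points)), excluded_idx)
        n_excluded_total += len(excluded_idx)
        if keep.size:
            pred = predict_many(ms.solvent, ms.solute, t[keep], rho[keep], fit.params)
            dev = (pred["d12"] - dexp[keep]) / dexp[keep]
        else:
            dev = np.array([])
        rel_dev.setdefault(ms.subset_tag, []).append(dev)
        rows.append({
            "system_id": ms.label,
            "subset": ms.subset_tag,
            "solvent": ms.solvent.name,
            "solute": ms.solute.name,
            "ndp": int(keep.size),
            "n_excluded": len(excluded_idx),
            "k12": fit.params.k12,
            "B12": fit.params.b12,
            "aard_pct": 100.0 * float(np.mean(np.abs(dev))) if keep.size else float("nan"),
            "ard_pct": 100.0 * float(np.mean(dev)) if keep.size else float("nan"),
        })
    per_system = pd.DataFrame(rows)

    subset_rows = []
    for tag, devs in rel_dev.items():
        pooled = np.concatenate(devs) if devs else np.array([])
        subset_rows.append({
            "subset": tag,
            "n_systems": sum(1 for ms in systems if ms.subset_tag == tag),
            "ndp": int(pooled.size),
            "aard_pct": 100.0 * float(np.mean(np.abs(pooled))) if pooled.size else float("nan"),
            "ard_pct": 100.0 * float(np.mean(pooled)) if pooled.size else float("nan"),
        })
    per_subset = pd.DataFrame(subset_rows)

    all_dev = np.concatenate([d for devs in rel_dev.values() for d in devs])
    if all_dev.size == 0:
        raise ValueError("no usable points in the database")
    global_metrics = Metrics(
        aard=100.0 * float(np.mean(np.abs(all_dev))),
        ard=100.0 * float(np.mean(all_dev)),
        ndp=int(all_dev.size),
    )
    return EvaluationReport(
        per_system=per_system,
        per_subset=per_subset,
        global_metrics=global_metrics,
        n_systems=len(systems),
        ndp=global_metrics.ndp,
        n_excluded=n_excluded_total,
    )
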