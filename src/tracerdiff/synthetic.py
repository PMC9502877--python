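"""Seeded generator of synthetic tracer-diffusion databases.

Emulates the structure of the experimental compilations used to validate
D12 correlations: a few hundred binary systems of 5-100 state points each,
split into four solvent subsets (polar, water, non-polar/weakly polar, and
supercritical CO2), with measurement noise that is multiplicative (relative
error is what diffusion experiments control, which is also why AARD is the
fitting objective).

Experimental D12 values are produced by running the forward model at known
"true" (k12, B12) and applying log-normal noise:

    d12_exp = D12_model * exp(eps),   eps ~ Normal(0, noise_cv)

so every generated database has a recoverable ground truth.  Each system
draws from its own named sub-stream of the master seed, so enlarging a
database never perturbs the systems already generated.

What this generator does NOT emulate: real equations of state (densities
are sampled, not derived from T and P), solvent-specific temperature-
density correlation, and heteroscedastic or systematic experimental error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import AVOGADRO
from .core import Compound, ModelParams, StatePoint, lj_params, predict_many, \
    reduced_temperature, effective_diameter
from .fitting import MeasurementSet

__all__ = ["GeneratorConfig", "gen_compound", "gen_system", "gen_database"]

#: Solvent mass-density sampling ranges, g/cm^3, chosen so liquid subsets
#: sit in the dense-liquid regime and scco2 spans dilute-to-liquid-like
#: supercritical densities.
DEFAULT_DENSITY_RANGES = {
    "polar": (0.5, 1.1),
    "water": (0.85, 1.05),
    "nonpolar": (0.5, 1.1),
    "scco2": (0.1, 1.0),
}

#: Subset proportions matching the system counts of the four solvent
#: families in large experimental D12 compilations.
DEFAULT_SUBSET_MIX = {"scco2": 0.32, "nonpolar": 0.28, "water": 0.24, "polar": 0.16}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic database generator.

    ``true_param_ranges`` bound the per-system ground-truth (k12, B12);
    ``noise_cv`` is the fractional standard deviation of the multiplicative
    measurement noise (0.03 = 3%, a typical relative precision of Taylor-
    dispersion and chromatographic D12 measurements).  ``max_rho_star``
    caps the solvent reduced number density below the threshold where the
    hard-sphere correction polynomials turn negative; ``n_invalid_points``
    forces that many points per system to rho* = 1.1 (non-physical, F11 < 0)
    to exercise the exclusion rule.
    """

    seed: int = 0
    n_systems: int = 10
    points_per_system: tuple[int, int] = (5, 100)
    subset_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSET_MIX))
    molar_mass_range: tuple[float, float] = (16.0, 1000.0)
    critical_temperature_range: tuple[float, float] = (150.0, 900.0)
    critical_volume_range: tuple[float, float] = (50.0, 1100.0)
    density_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_RANGES))
    temperature_range: tuple[float, float] = (283.15, 423.15)
    k12_range: tuple[float, float] = (-0.3, 0.3)
    b12_range: tuple[float, float] = (0.4, 5.0)
    noise_cv: float = 0.03
    max_rho_star: float = 0.95
    n_invalid_points: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not np.isclose(sum(self.subset_mix.values()), 1.0):
            raise ValueError("subset_mix proportions must sum to 1")
        lo, hi = self.points_per_system
        if not (1 <= lo <= hi):
            raise ValueError("points_per_system must be a non-empty range")
        for name in ("molar_mass_range", "critical_temperature_range",
                     "critical_volume_range", "temperature_range",
                     "k12_range", "b12_range"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"{name} must be non-degenerate, got ({a}, {b})")


def _system_stream(config: GeneratorConfig, index: int) -> np.random.Generator:
    """Independent named sub-stream for system ``index``."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def gen_compound(
    config: GeneratorConfig,
    stream: np.random.Generator,
    name: Optional[str] = None,
) -> Compound:
    """Sample one compound uniformly within the configured property ranges."""
    m = stream.uniform(*config.molar_mass_range)
    tc = stream.uniform(*config.critical_temperature_range)
    vc = stream.uniform(*config.critical_volume_range)
    if name is None:
        name = f"cmp-{stream.integers(0, 16**8):08x}"
    return Compound(name=name, molar_mass=m, critical_temperature=tc,
                    critical_volume=vc)


def _density_for_rho_star(solvent: Compound, temperature: float,
                          rho_star: float) -> float:
    """Mass density that yields a given reduced number density at T."""
    sigma1, eps1 = lj_params(solvent)
    se1 = effective_diameter(sigma1, reduced_temperature(temperature, eps1))
    return rho_star * solvent.molar_mass / (AVOGADRO * se1 ** 3)


def gen_system(
    config: GeneratorConfig,
    stream: np.random.Generator,
    subset_tag: str = "unspecified",
    system_id: Optional[str] = None,
    true_params: Optional[ModelParams] = None,
) -> tuple[MeasurementSet, ModelParams]:
    """Generate one system plus its ground-truth parameters.

    ``true_params`` pins the ground truth instead of sampling it (the same
    number of draws is consumed either way, so the states are unchanged).

    States are sampled with rho* <= ``config.max_rho_star`` (the valid
    regime); densities above the configured subset range are pulled down
    to respect the cap.  If ``config.n_invalid_points`` > 0, the first
    points of the system are instead placed at rho* = 1.1, where F11 < 0,
    so they must be excluded by the validity filter.
    """
    solvent = gen_compound(config, stream)
    solute = gen_compound(config, stream)
    sampled = ModelParams(
        k12=stream.uniform(*config.k12_range),
        b12=stream.uniform(*config.b12_range),
    )
    truth = true_params if true_params is not None else sampled
    lo_n, hi_n = config.points_per_system
    n = int(stream.integers(lo_n, hi_n + 1))
    n_invalid = min(config.n_invalid_points, n)

    dens_lo, dens_hi = config.density_ranges.get(
        subset_tag, (0.5, 1.1))
    temps = stream.uniform(*config.temperature_range, size=n)
    densities = np.empty(n)
    for i in range(n):
        if i < n_invalid:
            densities[i] = _density_for_rho_star(solvent, temps[i], 1.1)
            continue
        rho_cap = _density_for_rho_star(solvent, temps[i], config.max_rho_star)
        hi = min(dens_hi, rho_cap)
        lo = min(dens_lo, 0.5 * hi)
        densities[i] = stream.uniform(lo, hi)
        if densities[i] <= 0:
            raise ValueError("configured density range forces phi >= 1")

    pred = predict_many(solvent, solute, temps, densities, truth)
    noise = stream.normal(0.0, config.noise_cv, size=n) if config.noise_cv > 0 \
        else np.zeros(n)
    # forced-invalid points can have a negative forward-model D12 (F11 < 0);
    # they exist only to be excluded, so carry a positive placeholder magnitude
    d12_exp = np.abs(pred["d12"]) * np.exp(noise)

    points = tuple(
        StatePoint(temperature=float(temps[i]), solvent_density=float(densities[i]),
                   d12_exp=float(d12_exp[i]))
        for i in range(n)
    )
    ms = MeasurementSet(solvent=solvent, solute=solute, points=points,
                        subset_tag=subset_tag, system_id=system_id)
    return ms, truth


def gen_database(
    config: GeneratorConfig,
) -> list[tuple[MeasurementSet, ModelParams]]:
    """Generate ``config.n_systems`` systems, subset tags drawn per the mix.

    Fully reproducible from the seed; each system uses its own sub-stream,
    so increasing ``n_systems`` extends the database without changing the
    systems already present.
    """
    tags = sorted(config.subset_mix)
    probs = np.array([config.subset_mix[t] for t in tags])
    out = []
    for i in range(config.n_systems):
        stream = _system_stream(config, i)
        tag = tags[stream.choice(len(tags), p=probs)]
        ms, truth = gen_system(config, stream, subset_tag=tag,
                               system_id=f"sys-{i:04d}")
        out.append((ms, truth))
    return out
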