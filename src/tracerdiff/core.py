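"""Rice-Gray / Lennard-Jones / Stockmayer model for tracer diffusivities.

The tracer (infinite-dilution) binary diffusion coefficient D12 of a solute
(component 2) in a dense solvent (component 1) is obtained from the Einstein
relation D12 = kB*T/xi, with the friction coefficient xi split into a
hard-core Enskog part and a soft attractive part:

    xi = (8/3) * rho_n1 * sigma_eff_12^2 * sqrt(2*pi*m12*kB*T)
         * [ g12 * F12 + B12 / T12*^1.5 ]

Only four pure-compound properties are required (M, Tc, Vc of solvent and
solute) plus the solvent mass density at the state of interest.  Two
dimensionless parameters are fitted per binary system: the interaction
parameter k12 entering the Lennard-Jones diameter combining rule, and the
attractive-friction coefficient B12 = 0.4 + delta^2, which absorbs the
Stockmayer polar term so that no dipole moment is ever needed.

All lengths are in cm, masses in g (per molecule), energies as eps/kB in K,
densities in g/cm^3 on input and molecules/cm^3 internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import AVOGADRO, BOLTZMANN

__all__ = [
    "Compound",
    "StatePoint",
    "ModelParams",
    "DerivedState",
    "lj_params",
    "binary_lj",
    "reduced_temperature",
    "effective_diameter",
    "solvent_structure",
    "contact_rdf",
    "f11",
    "f12",
    "f12_coefficients",
    "reduced_mass",
    "predict_d12",
    "predict_many",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    """Immutable physical properties of one chemical species.

    Parameters
    ----------
    name : str
        Unique identifier.
    molar_mass : float
        Molar mass M, g/mol.
    critical_temperature : float
        Critical temperature Tc, K.
    critical_volume : float
        Critical volume Vc, cm^3/mol.
    """

    name: str
    molar_mass: float
    critical_temperature: float
    critical_volume: float

    def __post_init__(self) -> None:
        for field in ("molar_mass", "critical_temperature", "critical_volume"):
            value = getattr(self, field)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(
                    f"Compound {self.name!r}: {field} must be finite and "
                    f"strictly positive, got {value!r}"
                )

    @property
    def molecular_mass(self) -> float:
        """Mass of one molecule, g."""
        return self.molar_mass / AVOGADRO


@dataclass(frozen=True)
class StatePoint:
    """One (T, rho1[, D12_exp]) measurement or prediction state.

    Pressure is carried as metadata only; the model consumes density,
    never pressure.
    """

    temperature: float
    solvent_density: float
    d12_exp: Optional[float] = None
    pressure: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature!r}")
        if not self.solvent_density > 0:
            raise ValueError(
                f"solvent_density must be > 0 g/cm^3, got {self.solvent_density!r}"
            )
        if self.d12_exp is not None and not self.d12_exp > 0:
            raise ValueError(f"d12_exp must be > 0 cm^2/s, got {self.d12_exp!r}")


@dataclass(frozen=True)
class ModelParams:
    """The two fitted constants of the correlation.

    k12 is the binary interaction parameter of the LJ diameter combining
    rule (must be < 1 so the binary diameter stays positive); b12 is the
    dimensionless attractive-friction coefficient B12 = 0.4 + delta^2,
    which absorbs the Stockmayer parameter delta (so b12 >= 0; the
    physical baseline delta = 0 gives b12 = 0.4).
    """

    k12: float
    b12: float

    def __post_init__(self) -> None:
        if not self.k12 < 1.0:
            raise ValueError(f"k12 must be < 1, got {self.k12!r}")
        if not self.b12 >= 0.0:
            raise ValueError(f"b12 must be >= 0, got {self.b12!r}")


@dataclass(frozen=True)
class DerivedState:
    """Every intermediate of one D12 evaluation, for inspection and testing.

    Subscripts: 1 solvent, 2 solute, 12 binary.  Units: diameters cm,
    energies (eps/kB) K, masses g/molecule, rho_n1 molecules/cm^3,
    frictions g/s, d12 cm^2/s; everything else dimensionless.
    ``valid`` is False when F11 <= 0 or F12 <= 0 (states outside the
    physical domain of the correction-factor polynomials); d12 is still
    reported there but must not be trusted.
    """

    sigma_lj_1: float
    sigma_lj_2: float
    sigma_lj_12: float
    eps_kb_1: float
    eps_kb_2: float
    eps_kb_12: float
    t_star_1: float
    t_star_2: float
    t_star_12: float
    sigma_eff_1: float
    sigma_eff_2: float
    sigma_eff_12: float
    m_1: float
    m_2: float
    m_12: float
    rho_n1: float
    rho_star: float
    phi: float
    g12: float
    f11: float
    f12: float
    coeff_a: float
    coeff_b: float
    coeff_c: float
    coeff_d: float
    xi_hard: float
    xi_soft: float
    d12: float
    valid: bool


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def lj_params(compound: Compound) -> tuple[float, float]:
    """Lennard-Jones diameter (cm) and energy eps/kB (K) from criticals.

    sigma_LJ = 0.7889e-8 * Vc^(1/3)   (Vc in cm^3/mol)
    eps/kB   = Tc / 1.2593
    """
    sigma_lj = 0.7889e-8 * compound.critical_volume ** (1.0 / 3.0)
    eps_kb = compound.critical_temperature / 1.2593
    return sigma_lj, eps_kb


def binary_lj(
    sigma1: float, sigma2: float, eps1: float, eps2: float, k12: float
) -> tuple[float, float]:
    """Binary LJ parameters: corrected arithmetic-mean diameter, geometric-mean energy."""
    if not np.all(np.asarray(k12) < 1.0):
        raise ValueError(f"k12 must be < 1 (non-positive diameter), got {k12!r}")
    sigma12 = (1.0 - k12) * (sigma1 + sigma2) / 2.0
    eps12 = np.sqrt(eps1 * eps2)
    return sigma12, eps12


def reduced_temperature(t, eps_kb):
    """T* = T / (eps/kB); applies with j = 1, 2 or 12."""
    return t / eps_kb


def effective_diameter(sigma_lj, t_star):
    """Ben-Amotz–Herschbach effective hard-sphere diameter.

    sigma_eff = 1.1532 * sigma_lj * [1 + (1.8975*T*)^(1/2)]^(-1/6)

    Strictly decreasing in T*; equals 1.1532*sigma_lj at T* = 0.
    """
    t_star = np.asarray(t_star, dtype=float)
    if np.any(t_star < 0):
        raise ValueError(f"reduced temperature must be >= 0, got {t_star!r}")
    out = 1.1532 * sigma_lj * (1.0 + np.sqrt(1.8975 * t_star)) ** (-1.0 / 6.0)
    return out if out.ndim else float(out)


def solvent_structure(rho1, molar_mass1, sigma_eff_1):
    """Solvent number density, reduced number density and packing fraction.

    rho_n1   = rho1 * N_A / M1        molecules/cm^3
    rho*     = rho_n1 * sigma_eff_1^3
    phi      = (pi/6) * rho*
    """
    rho_n1 = rho1 * AVOGADRO / molar_mass1
    rho_star = rho_n1 * sigma_eff_1 ** 3
    phi = (np.pi / 6.0) * rho_star
    return rho_n1, rho_star, phi


def contact_rdf(phi, sigma_eff_1, sigma_eff_2):
    """Solvent-solute pair radial distribution function at contact.

    With r = 1/(1 + sigma_eff_1/sigma_eff_2):

        g12 = (1 - phi + 2*phi*r) * (1 - phi + phi*r) / (1 - phi)^3

    This product form is algebraically identical to the infinite-dilution
    Mansoori-Carnahan-Starling-Leland contact value and reduces to the
    Carnahan-Starling (1 - phi/2)/(1 - phi)^3 at equal diameters.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1.0) or np.any(phi < 0.0):
        raise ValueError(f"packing fraction must lie in [0, 1), got {phi!r}")
    r = 1.0 / (1.0 + sigma_eff_1 / sigma_eff_2)
    out = (1.0 - phi + 2.0 * phi * r) * (1.0 - phi + phi * r) / (1.0 - phi) ** 3
    return out if out.ndim else float(out)


def f11(rho_star):
    """Density correction factor for solvent self-diffusion.

    Polynomial in rho*; becomes negative above rho* ~ 1.02, which marks
    the state as outside the physical domain (flagged downstream, never
    clamped).
    """
    rho_star = np.asarray(rho_star, dtype=float)
    if np.any(rho_star < 0):
        raise ValueError(f"rho_star must be >= 0, got {rho_star!r}")
    out = (
        1.0
        + 0.94605 * rho_star ** 1.5
        + 1.4022 * rho_star ** 3
        - 5.6898 * rho_star ** 5
        + 2.6626 * rho_star ** 7
    )
    return out if out.ndim else float(out)


def f12_coefficients(rho_star):
    """Density-linear coefficients a, b, c, d of the binary correction factor."""
    a = -1.676382 * rho_star + 1.638561
    b = -8.516830 * rho_star + 8.631536
    c = -1.320347 * rho_star + 1.351067
    d = -5.062546 * rho_star + 5.409662
    return a, b, c, d


def f12(rho_star, sigma_eff_1, sigma_eff_2, m1, m2):
    """Hard-sphere correction factor for D12.

    F12 = F11 + rho*^1.7 * (a*L + b*L^2 + c*Q) / (1 + rho*^3 * d * L^2)

    with L = ln(sigma_eff_2/sigma_eff_1), Q = ln(m2/m1).  Equals F11 for
    identical species and 1 at zero density.
    """
    rho_star = np.asarray(rho_star, dtype=float)
    big_l = np.log(sigma_eff_2 / sigma_eff_1)
    big_q = np.log(m2 / m1)
    a, b, c, d = f12_coefficients(rho_star)
    correction = (
        rho_star ** 1.7
        * (a * big_l + b * big_l ** 2 + c * big_q)
        / (1.0 + rho_star ** 3 * d * big_l ** 2)
    )
    out = f11(rho_star) + correction
    return out if np.ndim(out) else float(out)


def reduced_mass(m1, m2):
    """Reduced mass m1*m2/(m1+m2), g."""
    return m1 * m2 / (m1 + m2)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def _chain(solvent: Compound, solute: Compound, temperature, density, k12, b12):
    """Evaluate the full property chain; temperature/density may be arrays."""
    sigma1, eps1 = lj_params(solvent)
    sigma2, eps2 = lj_params(solute)
    sigma12, eps12 = binary_lj(sigma1, sigma2, eps1, eps2, k12)

    t1 = reduced_temperature(temperature, eps1)
    t2 = reduced_temperature(temperature, eps2)
    t12 = reduced_temperature(temperature, eps12)

    se1 = effective_diameter(sigma1, t1)
    se2 = effective_diameter(sigma2, t2)
    se12 = effective_diameter(sigma12, t12)

    m1 = solvent.molecular_mass
    m2 = solute.molecular_mass
    m12 = reduced_mass(m1, m2)

    rho_n1, rho_star, phi = solvent_structure(density, solvent.molar_mass, se1)
    g12 = contact_rdf(phi, se1, se2)
    f11_val = f11(rho_star)
    f12_val = f12(rho_star, se1, se2, m1, m2)

    prefactor = (
        (8.0 / 3.0)
        * rho_n1
        * se12 ** 2
        * np.sqrt(2.0 * np.pi * m12 * BOLTZMANN * temperature)
    )
    xi_hard = prefactor * g12 * f12_val
    xi_soft = prefactor * b12 / t12 ** 1.5
    d12 = BOLTZMANN * temperature / (xi_hard + xi_soft)

    return {
        "sigma_lj_1": sigma1, "sigma_lj_2": sigma2, "sigma_lj_12": sigma12,
        "eps_kb_1": eps1, "eps_kb_2": eps2, "eps_kb_12": eps12,
        "t_star_1": t1, "t_star_2": t2, "t_star_12": t12,
        "sigma_eff_1": se1, "sigma_eff_2": se2, "sigma_eff_12": se12,
        "m_1": m1, "m_2": m2, "m_12": m12,
        "rho_n1": rho_n1, "rho_star": rho_star, "phi": phi,
        "g12": g12, "f11": f11_val, "f12": f12_val,
        "xi_hard": xi_hard, "xi_soft": xi_soft, "d12": d12,
    }


def predict_d12(
    solvent: Compound,
    solute: Compound,
    state: StatePoint,
    params: ModelParams,
) -> DerivedState:
    """Predict D12 for one state, exposing every intermediate quantity.

    Raises ValueError if the packing fraction reaches 1.  A state where
    F11 <= 0 or F12 <= 0 yields ``valid=False``; d12 is still reported.
    """
    c = _chain(
        solvent, solute, state.temperature, state.solvent_density,
        params.k12, params.b12,
    )
    a, b, cc, d = f12_coefficients(c["rho_star"])
    return DerivedState(
        **{k: float(v) for k, v in c.items()},
        coeff_a=float(a), coeff_b=float(b), coeff_c=float(cc), coeff_d=float(d),
        valid=bool(c["f11"] > 0 and c["f12"] > 0),
    )


def predict_many(
    solvent: Compound,
    solute: Compound,
    temperature: np.ndarray,
    density: np.ndarray,
    params: ModelParams | tuple[float, float],
) -> dict[str, np.ndarray]:
    """Vectorized D12 over arrays of (T, rho1) for one binary system.

    Returns arrays ``d12``, ``f11``, ``f12``, ``rho_star`` and the boolean
    ``valid`` mask (F11 > 0 and F12 > 0).  Used by the fitting objective.
    """
    if isinstance(params, ModelParams):
        k12, b12 = params.k12, params.b12
    else:
        k12, b12 = params
    temperature = np.asarray(temperature, dtype=float)
    density = np.asarray(density, dtype=float)
    c = _chain(solvent, solute, temperature, density, k12, b12)
    f11_a = np.asarray(c["f11"])
    f12_a = np.asarray(c["f12"])
    return {
        "d12": np.asarray(c["d12"]),
        "f11": f11_a,
        "f12": f12_a,
        "rho_star": np.asarray(c["rho_star"]),
        "valid": (f11_a > 0) & (f12_a > 0),
    }
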