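"""Unit and property tests for the D12 property chain."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tracerdiff import (
    Compound,
    ModelParams,
    StatePoint,
    binary_lj,
    contact_rdf,
    effective_diameter,
    f11,
    f12,
    lj_params,
    predict_d12,
    predict_many,
    reduced_mass,
    reduced_temperature,
    solvent_structure,
)

from _oracle import mcsl_contact, oracle_d12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    dict(molar_mass=-1.0, critical_temperature=300.0, critical_volume=100.0),
    dict(molar_mass=44.0, critical_temperature=0.0, critical_volume=100.0),
    dict(molar_mass=44.0, critical_temperature=300.0, critical_volume=-5.0),
    dict(molar_mass=float("inf"), critical_temperature=300.0, critical_volume=100.0),
])
def test_compound_rejects_nonphysical_properties(kwargs):
    with pytest.raises(ValueError):
        Compound("bad", **kwargs)


def test_state_point_validation():
    with pytest.raises(ValueError):
        StatePoint(temperature=-1.0, solvent_density=0.5)
    with pytest.raises(ValueError):
        StatePoint(temperature=300.0, solvent_density=0.0)
    with pytest.raises(ValueError):
        StatePoint(temperature=300.0, solvent_density=0.5, d12_exp=-1e-5)
    # pressure is optional metadata and never validated against the model
    p = StatePoint(temperature=300.0, solvent_density=0.5, pressure=150.0)
    assert p.d12_exp is None


def test_model_params_constraints():
    with pytest.raises(ValueError):
        ModelParams(k12=1.0, b12=0.4)
    with pytest.raises(ValueError):
        ModelParams(k12=0.0, b12=-0.1)
    ModelParams(k12=-0.3, b12=0.0)  # boundary values allowed


# ---------------------------------------------------------------------------
# Elementary operations, frozen values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("vc, tc, sigma_expected, eps_expected", [
    (1.0, 1.2593, 0.7889e-8, 1.0),
    (100.0, 304.13, 3.6617494308371213e-08, 304.13 / 1.2593),
])
def test_lj_params(vc, tc, sigma_expected, eps_expected):
    sigma, eps = lj_params(Compound("x", 44.0, tc, vc))
    assert sigma == pytest.approx(sigma_expected, rel=1e-12)
    assert eps == pytest.approx(eps_expected, rel=1e-12)


def test_binary_lj_combining_rules():
    s12, e12 = binary_lj(3e-8, 5e-8, 100.0, 400.0, k12=0.1)
    assert s12 == pytest.approx(3.6e-8, rel=1e-12)
    assert e12 == pytest.approx(200.0, rel=1e-12)
    # identity at k12 = 0, equal diameters
    s_same, _ = binary_lj(4e-8, 4e-8, 100.0, 100.0, k12=0.0)
    assert s_same == pytest.approx(4e-8, rel=1e-15)
    with pytest.raises(ValueError):
        binary_lj(3e-8, 5e-8, 100.0, 400.0, k12=1.0)


def test_reduced_temperature():
    assert reduced_temperature(300.0, 150.0) == pytest.approx(2.0)
    assert reduced_temperature(313.15, 241.51) == pytest.approx(1.296633679764813,
                                                                rel=1e-12)


def test_effective_diameter_frozen_values():
    sigma = 3e-8
    assert effective_diameter(sigma, 0.0) == pytest.approx(1.1532 * sigma, rel=1e-15)
    assert effective_diameter(sigma, 1.0) == pytest.approx(
        0.998200880268534 * sigma, rel=1e-12)
    assert effective_diameter(sigma, 2.0) == pytest.approx(
        0.9630485650694265 * sigma, rel=1e-12)
    with pytest.raises(ValueError):
        effective_diameter(sigma, -0.1)


@given(st.floats(0.0, 50.0), st.floats(1e-4, 49.0))
def test_effective_diameter_strictly_decreasing(t_star, delta):
    assert effective_diameter(1e-8, t_star + delta) < effective_diameter(1e-8, t_star)


def test_effective_diameter_bounded_by_zero_temperature_limit():
    t = np.linspace(0.0, 20.0, 101)
    assert np.all(effective_diameter(3e-8, t) <= 1.1532 * 3e-8)


def test_solvent_structure_chain():
    rho_n1, rho_star, phi = solvent_structure(0.6, 44.01, 3.6e-8)
    assert rho_n1 == pytest.approx(8.2102e21, rel=1e-4)
    assert rho_star == pytest.approx(0.3830522288687116, rel=1e-12)
    assert phi == pytest.approx(math.pi / 6 * rho_star, rel=1e-15)


def test_contact_rdf_frozen_values():
    assert contact_rdf(0.0, 3e-8, 5e-8) == pytest.approx(1.0, abs=1e-15)
    # equal diameters: Carnahan-Starling closed form
    assert contact_rdf(0.4, 3e-8, 3e-8) == pytest.approx(
        (1 - 0.2) / 0.6 ** 3, rel=1e-12)
    # infinitely large solute: planar-wall limit (1+phi)/(1-phi)^3
    assert contact_rdf(0.3, 3e-8, 3e4) == pytest.approx(
        1.3 / 0.7 ** 3, rel=1e-8)
    with pytest.raises(ValueError):
        contact_rdf(1.0, 3e-8, 3e-8)


@given(st.floats(0.0, 0.6), st.floats(0.1, 10.0))
def test_contact_rdf_equals_mcsl_expansion(phi, ratio):
    """The product form is algebraically the MCSL infinite-dilution value."""
    se2 = 3e-8
    se1 = ratio * se2
    got = contact_rdf(phi, se1, se2)
    want = mcsl_contact(phi, ratio)
    assert got == pytest.approx(want, rel=1e-12)


def test_f11_frozen_values():
    assert f11(0.0) == 1.0
    assert f11(1.0) == pytest.approx(0.32105, abs=1e-10)
    # above rho* ~ 1.02 the polynomial turns negative (non-physical regime)
    assert f11(1.1) == pytest.approx(-0.017049275647489814, rel=1e-10)
    assert f11(1.1) < 0
    with pytest.raises(ValueError):
        f11(-0.5)


def test_f12_reduces_to_f11_for_identical_species():
    for rho_star in (0.0, 0.3, 0.8):
        assert f12(rho_star, 3e-8, 3e-8, 1e-22, 1e-22) == pytest.approx(
            f11(rho_star), rel=1e-14)


def test_f12_is_one_at_zero_density():
    assert f12(0.0, 3e-8, 6e-8, 1e-22, 5e-22) == pytest.approx(1.0, abs=1e-15)


def test_f12_frozen_value():
    # rho*=0.5, diameter ratio 2, mass ratio 2
    got = f12(0.5, 3e-8, 6e-8, 1e-22, 2e-22)
    assert got == pytest.approx(2.1753758204356917, rel=1e-12)


def test_reduced_mass():
    assert reduced_mass(2.0, 2.0) == pytest.approx(1.0)
    assert reduced_mass(1e-26, 1e-18) == pytest.approx(1e-26, rel=1e-7)
    m12 = reduced_mass(44.01 / 6.0221367e23, 46.07 / 6.0221367e23)
    assert m12 == pytest.approx(3.737580830893691e-23, rel=1e-12)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def test_predict_d12_hard_sphere_limit(co2, benzene):
    """With B12 = 0 the soft friction vanishes: D12 = kB*T/xi_hard exactly."""
    state = StatePoint(313.15, 0.7)
    d = predict_d12(co2, benzene, state, ModelParams(0.0, 0.0))
    assert d.xi_soft == 0.0
    assert d.d12 == pytest.approx(
        1.380658e-16 * 313.15 / d.xi_hard, rel=1e-15)


def test_predict_d12_decreasing_in_b12(co2, benzene):
    state = StatePoint(313.15, 0.7)
    d1 = predict_d12(co2, benzene, state, ModelParams(0.0, 1.0))
    d2 = predict_d12(co2, benzene, state, ModelParams(0.0, 2.0))
    assert d2.d12 < d1.d12


def test_predict_d12_decreasing_in_density(co2, benzene):
    """Denser solvent -> more friction -> lower D12 (valid regime)."""
    densities = np.linspace(0.3, 0.9, 7)
    d12s = [predict_d12(co2, benzene, StatePoint(313.15, rho),
                        ModelParams(0.0, 1.0)).d12 for rho in densities]
    assert all(a > b for a, b in zip(d12s, d12s[1:]))


def test_predict_d12_frozen_reference_value(co2, benzene):
    """CO2/benzene at 313.15 K, 0.7 g/cm^3, k12=0, B12=1 (frozen from the
    independent chained-arithmetic oracle)."""
    d = predict_d12(co2, benzene, StatePoint(313.15, 0.7), ModelParams(0.0, 1.0))
    assert d.d12 == pytest.approx(5.936533983432335e-05, rel=1e-10)
    assert d.valid
    assert 1e-7 < d.d12 < 1e-2


def test_predict_d12_flags_nonphysical_states(water, benzene):
    """A state pushed past rho* ~ 1.02 has F11 < 0 and is flagged, not clamped."""
    from tracerdiff.synthetic import _density_for_rho_star
    rho = _density_for_rho_star(water, 300.0, 1.1)
    d = predict_d12(water, benzene, StatePoint(300.0, rho), ModelParams(0.0, 1.0))
    assert d.rho_star == pytest.approx(1.1, rel=1e-12)
    assert d.f11 < 0
    assert not d.valid


def test_predict_d12_exposes_consistent_intermediates(co2, benzene):
    d = predict_d12(co2, benzene, StatePoint(330.0, 0.8), ModelParams(0.05, 1.2))
    assert d.phi == pytest.approx(math.pi / 6 * d.rho_star, rel=1e-15)
    assert d.sigma_eff_1 <= 1.1532 * d.sigma_lj_1
    assert d.sigma_eff_2 <= 1.1532 * d.sigma_lj_2
    assert d.g12 >= 1.0
    assert d.m_12 == pytest.approx(
        d.m_1 * d.m_2 / (d.m_1 + d.m_2), rel=1e-15)
    assert d.t_star_12 == pytest.approx(330.0 / d.eps_kb_12, rel=1e-15)


def test_predict_d12_matches_oracle_on_random_valid_inputs():
    """Implementation agrees with the independent oracle to 1e-10 relative
    on 100 seeded random (compound, state, parameter) draws."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 100:
        m1 = rng.uniform(16, 1000); tc1 = rng.uniform(150, 900)
        vc1 = rng.uniform(50, 1100)
        m2 = rng.uniform(16, 1000); tc2 = rng.uniform(150, 900)
        vc2 = rng.uniform(50, 1100)
        t = rng.uniform(280, 450)
        k12 = rng.uniform(-0.3, 0.3); b12 = rng.uniform(0.0, 5.0)
        solvent = Compound("s1", m1, tc1, vc1)
        solute = Compound("s2", m2, tc2, vc2)
        from tracerdiff.synthetic import _density_for_rho_star
        rho = rng.uniform(0.2, 0.95) * _density_for_rho_star(solvent, t, 1.0)
        d = predict_d12(solvent, solute, StatePoint(t, rho), ModelParams(k12, b12))
        if not d.valid:
            continue
        expected, details = oracle_d12(m1, tc1, vc1, m2, tc2, vc2, t, rho, k12, b12)
        assert d.d12 == pytest.approx(expected, rel=1e-10)
        assert d.f12 == pytest.approx(details["f12"], rel=1e-10)
        assert d.g12 == pytest.approx(details["g12"], rel=1e-10)
        checked += 1


def test_predict_many_agrees_with_scalar_chain(co2, benzene):
    temps = np.array([305.0, 313.15, 333.15, 360.0])
    rhos = np.array([0.4, 0.7, 0.85, 0.6])
    params = ModelParams(0.08, 2.0)
    vec = predict_many(co2, benzene, temps, rhos, params)
    for i in range(temps.size):
        scalar = predict_d12(co2, benzene, StatePoint(temps[i], rhos[i]), params)
        assert vec["d12"][i] == pytest.approx(scalar.d12, rel=1e-14)
        assert bool(vec["valid"][i]) == scalar.valid


def test_d12_dimensional_sanity_across_fixtures(co2, benzene, water):
    """Liquid/supercritical states give D12 in the 1e-7..1e-2 cm^2/s window."""
    cases = [
        (co2, benzene, 313.15, 0.7),
        (co2, benzene, 330.0, 0.25),
        (water, benzene, 298.15, 0.997),
        (benzene, water, 298.15, 0.87),
    ]
    for solvent, solute, t, rho in cases:
        d = predict_d12(solvent, solute, StatePoint(t, rho), ModelParams(0.0, 1.0))
        assert 1e-7 < d.d12 < 1e-2, (solvent.name, solute.name, d.d12)
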