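"""Independent step-by-step oracle for the D12 property chain.

Deliberately written with the plain ``math`` module, one named step per
formula, with no imports from the package under test.  Used to check
``tracerdiff.core.predict_d12`` against a second, independently coded
evaluation of the same physics.
"""

import math

KB = 1.380658e-16   # g cm^2 s^-2 K^-1
NA = 6.0221367e23   # mol^-1


def oracle_d12(m1_gmol, tc1, vc1, m2_gmol, tc2, vc2, temperature, rho1,
               k12, b12):
    """Chained arithmetic for D12 (cm^2/s); returns (d12, details)."""
    sigma1 = 0.7889e-8 * vc1 ** (1.0 / 3.0)
    sigma2 = 0.7889e-8 * vc2 ** (1.0 / 3.0)
    eps1 = tc1 / 1.2593
    eps2 = tc2 / 1.2593

    sigma12 = (1.0 - k12) * (sigma1 + sigma2) / 2.0
    eps12 = math.sqrt(eps1 * eps2)

    t1 = temperature / eps1
    t2 = temperature / eps2
    t12 = temperature / eps12

    def eff(sigma, tstar):
        return 1.1532 * sigma * (1.0 + math.sqrt(1.8975 * tstar)) ** (-1.0 / 6.0)

    se1 = eff(sigma1, t1)
    se2 = eff(sigma2, t2)
    se12 = eff(sigma12, t12)

    m1 = m1_gmol / NA
    m2 = m2_gmol / NA
    m12 = m1 * m2 / (m1 + m2)

    rho_n1 = rho1 * NA / m1_gmol
    rho_star = rho_n1 * se1 ** 3
    phi = math.pi / 6.0 * rho_star

    r = 1.0 / (1.0 + se1 / se2)
    g12 = (1.0 - phi + 2.0 * phi * r) * (1.0 - phi + phi * r) / (1.0 - phi) ** 3

    f11 = (1.0 + 0.94605 * rho_star ** 1.5 + 1.4022 * rho_star ** 3
           - 5.6898 * rho_star ** 5 + 2.6626 * rho_star ** 7)

    big_l = math.log(se2 / se1)
    big_q = math.log(m2 / m1)
    a = -1.676382 * rho_star + 1.638561
    b = -8.516830 * rho_star + 8.631536
    c = -1.320347 * rho_star + 1.351067
    d = -5.062546 * rho_star + 5.409662
    f12 = f11 + (rho_star ** 1.7 * (a * big_l + b * big_l ** 2 + c * big_q)
                 / (1.0 + rho_star ** 3 * d * big_l ** 2))

    prefactor = (8.0 / 3.0) * rho_n1 * se12 ** 2 * math.sqrt(
        2.0 * math.pi * m12 * KB * temperature)
    xi_hard = prefactor * g12 * f12
    xi_soft = prefactor * b12 / t12 ** 1.5
    d12 = KB * temperature / (xi_hard + xi_soft)

    return d12, {
        "rho_star": rho_star, "phi": phi, "g12": g12,
        "f11": f11, "f12": f12, "xi_hard": xi_hard, "xi_soft": xi_soft,
        "sigma_eff_1": se1, "sigma_eff_2": se2, "sigma_eff_12": se12,
        "t_star_12": t12, "m_12": m12,
    }


def mcsl_contact(phi, ratio):
    """Infinite-dilution MCSL contact value, three-term expansion.

    ratio = sigma_eff_1 / sigma_eff_2; r = 1/(1+ratio).
    """
    r = 1.0 / (1.0 + ratio)
    return (1.0 / (1.0 - phi)
            + 3.0 * phi * r / (1.0 - phi) ** 2
            + 2.0 * phi ** 2 * r ** 2 / (1.0 - phi) ** 3)
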