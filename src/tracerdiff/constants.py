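"""Physical constants in cgs units.

The whole package computes internally in cgs (cm, g, s, K) because the
Boltzmann constant is fixed in g cm^2 s^-2 K^-1; I/O stays in the
conventional units of the field (K, bar, g/cm^3, cm^2/s).
"""

#: Boltzmann constant, g cm^2 s^-2 K^-1 (CODATA 1986 vintage).
BOLTZMANN = 1.380658e-16

#: Avogadro constant, mol^-1 (same CODATA vintage as BOLTZMANN).
AVOGADRO = 6.0221367e23
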