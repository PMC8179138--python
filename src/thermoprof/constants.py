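"""Physical constants and unit conventions.

The package works throughout in kcal/mol (energy), Angstrom (length) and
Kelvin (temperature); entropies are kcal/(mol K).
"""

#: Boltzmann constant, kcal/(mol K).  Multiplying by Avogadro's number is
#: implied, i.e. this equals the molar gas constant R in kcal/(mol K).
K_B: float = 0.0019872041

#: Molar gas constant in kcal/(mol K) — identical to K_B in molar units.
R: float = K_B

#: Standard-state reference concentration for Ki -> dG conversion, molar.
C_STANDARD: float = 1.0
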