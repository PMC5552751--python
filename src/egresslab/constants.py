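"""Physical constants and unit conventions.

Internal units throughout the package: length in Angstrom, time in ps,
energy in kcal/mol, mass in amu, temperature in K, charge in units of the
elementary charge.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 kcal/mol expressed in amu * A^2 / ps^2 (converts forces to accelerations)
ENERGY_CONV = 418.4

#: Coulomb prefactor, kcal * A / (mol * e^2)
COULOMB_CONST = 332.0636

#: pair distances are clamped below this value to avoid the r -> 0 singularity, A
R_MIN_CLAMP = 0.1
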