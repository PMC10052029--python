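"""Physical constants in the package's working units (kcal/mol, Å, K, ps, e)."""

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

#: Coulomb prefactor k_e, kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0
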