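"""Physical constants in the package unit system (nm, ps, K, kJ/mol, amu)."""

#: Boltzmann constant in kJ mol^-1 K^-1 (CODATA R/1000).
BOLTZMANN_KJ_MOL_K = 0.008314462618153241
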