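"""Physical constants and unit conventions.

Units are fixed package-wide: energies in kcal/mol, lengths in Angstrom,
angles in radians, masses in amu, time in fs, temperature in K.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Conversion from (kcal/mol/A)/amu to acceleration in A/fs^2.
#: 1 kcal/mol = 4184 J/mol; per amu (1 g/mol) this is 4.184e-4 A^2/fs^2 per A.
FORCE_TO_ACC = 4.184e-4
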