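"""Unit system and physical constants.

The package works in kJ/mol (energy), nm (length), ps (time), K
(temperature) and elementary charges throughout.  Masses are in Da;
with these units force is kJ/mol/nm and velocity nm/ps.
"""

#: Boltzmann constant, kJ/mol/K
KB = 0.00831446261815324

#: Coulomb prefactor e^2/(4 pi eps0) in kJ nm / mol (divide by relative
#: dielectric for the screened interaction strength)
COULOMB = 138.935458

#: 1 Da/nm^3 expressed in mg/mL
DA_PER_NM3_TO_MG_PER_ML = 1.66053906892

#: femtoseconds per picosecond (timesteps are specified in fs)
FS_PER_PS = 1000.0
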