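"""Project-wide unit conventions and physical constants.

Units are fixed across the package: metabolite concentrations in mM,
enzyme abundances in nM, time in seconds, temperature in kelvin and
activation energies in kJ/mol.
"""

#: Gas constant, J/(mol*K).
R = 8.314

#: Base temperature of the kinetic model, kelvin (37.5 degC).
T0_DEFAULT = 310.65

#: Total pyridine moiety in the closed system, mM.
PYRIDINE_TOTAL_DEFAULT = 0.3
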