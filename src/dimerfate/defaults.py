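"""Reference parameter values shared across the package.

These are the standing conditions of the model: a yeast-like gene encoding a
homodimer-forming protein with typical folding stability and binding affinity,
synthesis tuned so that pre-duplication total activity is ~38.2 h^-1 (and
therefore ~76.4 h^-1 immediately after duplication).
"""

#: Gas constant, kcal K^-1 mol^-1.
R_GAS = 1.987e-3

#: Temperature, K.
T_KELVIN = 298.0

#: R*T at the reference temperature, kcal/mol.
RT = R_GAS * T_KELVIN

#: Reference gene-level synthesis rate, concentration-units h^-1. This value
#: uniquely reproduces the 38.2/76.4 h^-1 reference activities together with
#: the other defaults below.
REF_SYNTHESIS_RATE = 100.0

#: Reference folding free energy, kcal/mol (typical globular protein).
REF_DG_FOLD = -5.0

#: Reference binding free energy for all dimers, kcal/mol.
REF_DG_BIND = -10.0

#: Decay rate for all folded species (monomers and dimers), h^-1, derived
#: from median yeast protein half-life plus dilution by cell division.
REF_DECAY = 1.3

#: Specific activity of free monomers (dimers are the functional unit).
ACTIVITY_MONOMER = 0.1

#: Specific activity of dimers.
ACTIVITY_DIMER = 1.0

#: Largest exponent passed to exp() when computing association constants;
#: beyond this the constant is clamped (documented overflow guard).
MAX_EXP_ARG = 700.0

#: Heterodimer association constants below this are treated as "no
#: heterodimer": the coupled 5-species system degenerates and the solver
#: falls back to two independent single-gene equilibria (continuous limit).
K_AB_FLOOR = 1e-12
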