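"""Physical constants and unit conventions.

The package works in a single internal unit system throughout:

=============  ==============
quantity       unit
=============  ==============
length         angstrom (A)
energy         kcal/mol
force          kcal/mol/A
mass           a.m.u. (g/mol)
time           fs
velocity       A/fs
temperature    K
=============  ==============
"""

#: Boltzmann constant in kcal/(mol*K).
KB = 0.0019872041

#: Converts (kcal/mol/A)/amu to acceleration in A/fs^2.
#: 1 kcal/mol = 4184 J/mol; 1 amu = 1e-3 kg/mol; 1 A/fs = 1e5 m/s.
FORCE_TO_ACC = 4.184e-4

#: Atomic masses (a.m.u.) of the elements allowed in protein inputs.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Elements accepted for protein systems (hydrogens are mapped away).
PROTEIN_ELEMENTS = frozenset(ELEMENT_MASSES)

#: Friction conversion: ps^-1 to fs^-1.
PS_INV_TO_FS_INV = 1e-3
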