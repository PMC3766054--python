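"""Physical constants shared by the model and the analysis pipeline.

Glucose and galactose are lumped as one hexose species; at the level of
redox-cofactor accounting the Embden-Meyerhof-Parnas and Leloir routes are
both redox-neutral and ATP-yielding, so a single 180 g/mol species suffices.
"""

#: Molar mass of the pooled hexose species (glucose + galactose), g/mol.
MM_HEXOSE = 180.0

#: Molar mass of ethanol, g/mol.
MM_ETHANOL = 46.069

#: Molar mass of glycerol, g/mol.
MM_GLYCEROL = 92.094

#: Molar mass of CO2, g/mol.
MM_CO2 = 44.01

#: Degrees of reduction (available electrons) per mole.
ELECTRONS_HEXOSE = 24.0
ELECTRONS_ETHANOL = 12.0
ELECTRONS_GLYCEROL = 14.0
ELECTRONS_CO2 = 0.0

#: Carbon atoms per molecule.
CARBON_HEXOSE = 6
CARBON_ETHANOL = 2
CARBON_GLYCEROL = 3

#: Normalization basis of every flux distribution: mmol hexose taken up.
HEXOSE_BASIS = 100.0
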