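# Benchmark chemostat steady states: anaerobic, sugar-limited cultures at
# D = 0.05 1/h on 12.5 g/l glucose + 12.5 g/l galactose, for the
# glycerol-producing reference strain and the PRK/Rubisco-expressing strain,
# each sparged with pure N2 or with a 10% CO2 / 90% N2 blend.
# Yields are averages +/- mean deviations of duplicate cultures; gas_flow was
# chosen once so the reference/N2 condition reproduces the benchmark outlet
# CO2 fraction (~0.9%) at the packaged gas molar volume.
dilution_rate: 0.05        # 1/h
glucose_in: 12.5           # g/l
galactose_in: 12.5         # g/l
glucose_residual: 0.02     # g/l (sugar-limited)
galactose_residual: 0.03   # g/l
gas_flow: 35.0             # l gas / h / l broth
conditions:
  reference_n2:
    strain: reference
    sparge: n2
    co2_in: 0.0
    yields: {y_biomass: 0.083, y_ethanol: 1.56, y_glycerol: 0.14}
    spread: {y_biomass: 0.000, y_ethanol: 0.03, y_glycerol: 0.00}
  reference_co2:
    strain: reference
    sparge: co2
    co2_in: 0.10
    yields: {y_biomass: 0.084, y_ethanol: 1.56, y_glycerol: 0.12}
    spread: {y_biomass: 0.000, y_ethanol: 0.02, y_glycerol: 0.00}
  engineered_n2:
    strain: prk_rubisco
    sparge: n2
    co2_in: 0.0
    yields: {y_biomass: 0.093, y_ethanol: 1.73, y_glycerol: 0.04}
    spread: {y_biomass: 0.001, y_ethanol: 0.02, y_glycerol: 0.00}
  engineered_co2:
    strain: prk_rubisco
    sparge: co2
    co2_in: 0.10
    yields: {y_biomass: 0.095, y_ethanol: 1.73, y_glycerol: 0.01}
    spread: {y_biomass: 0.000, y_ethanol: 0.01, y_glycerol: 0.00}
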