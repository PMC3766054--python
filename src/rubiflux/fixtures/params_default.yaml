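# Default model parameters.
#
# The biosynthetic coefficients (n_nadh, n_nadph) and the biomass yield on
# ATP (y_atp) are the exact calibration of the lumped network to the packaged
# reference chemostat steady state (anaerobic, sugar-limited, D = 0.05 1/h,
# glucose + galactose): biomass 0.083 g/g, ethanol 1.56 and glycerol
# 0.14 mol/mol hexose.  Re-derive at any time with `rubiflux calibrate`.
biomass_carbon_content: 24.6      # g dry weight per Cmol biomass
gamma_biomass: 4.2                # e- per Cmol (empirical CH1.8O0.5N0.2)
n_nadh: 0.23052208835341367       # mol NADH formed per Cmol biomass
n_nadph: 0.7238554216867475       # mol NADPH consumed per Cmol biomass
n_co2_biomass: 0.12               # mol CO2 released per Cmol biomass
y_atp: 0.4169317839322193         # Cmol biomass per mol ATP
atp_coeffs:
  fermentation: 2.0               # ATP per hexose fermented
  glycerol: -1.0                  # ATP per glycerol formed
  rubisco: 1.0                    # ATP per Ru5P carboxylated (2 PK - 1 PRK)
  oxppp: -1.0                     # ATP per hexose entering the oxidative PPP
  nonoxppp: -1.1666666666666667   # ATP per Ru5P from glycolytic intermediates (7/6)
k_evap: 0.008                     # 1/h, first-order ethanol evaporation
K_co2: 0.26                       # mM, form-II Rubisco half-saturation for CO2
maintenance_atp: 0.0              # mol ATP / g biomass / h
co2_henry_mM_per_atm: 29.7        # dissolved CO2 per atm CO2, water at 30 degC
gas_molar_volume: 24.06           # l/mol, off-gas analyzer basis (20 degC, 1 atm)
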