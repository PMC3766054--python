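# Benchmark anaerobic batch cultures on 20 g/l galactose, 10% CO2 sparging.
# Yields are a documented synthetic assumption: absolute batch yields are not
# available, so the reference condition carries the CO2-sparged reference
# chemostat yields and the engineered condition applies the observed batch
# deltas (glycerol -60%, ethanol +8%, biomass unchanged).  Growth rates are
# equal between strains (the observed difference was not significant); the
# engineered strain has a ~10 h longer lag phase.
initial_sugar: 20.0    # g/l galactose
inoculum: 0.1          # g/l biomass
t_end: 40.0            # h
dt_sample: 0.5         # h between samples
conditions:
  reference:
    strain: reference
    mu_max: 0.25       # 1/h
    lag: 5.0           # h
    yields: {y_biomass: 0.084, y_ethanol: 1.56, y_glycerol: 0.12}
  engineered:
    strain: prk_rubisco
    mu_max: 0.25
    lag: 15.0
    yields: {y_biomass: 0.084, y_ethanol: 1.6848, y_glycerol: 0.048}
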