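"""Generate synthetic chemostat duplicates and analyse them back.

Simulates the four benchmark conditions (two strains x two sparging
gases) with 1% measurement noise, computes evaporation-corrected yields,
and compares the strains with the t-test machinery.
"""

from rubiflux import (
    chemostat_yields,
    compare_strains,
    generate_chemostat,
    load_chemostat_condition,
    pool_yields,
)

arms = {}
for condition in ("reference_n2", "engineered_n2"):
    cfg = load_chemostat_condition(condition, noise_sd=0.01, seed=42)
    records = generate_chemostat(cfg)
    yields = [chemostat_yields(r, cfg.params) for r in records]
    arms[condition] = yields
    pooled = pool_yields(yields)
    print(f"{condition}: ethanol {pooled.y_ethanol:.3f} +/- "
          f"{pooled.spread['y_ethanol']:.3f} mol/mol, "
          f"glycerol {pooled.y_glycerol:.3f} mol/mol, "
          f"biomass {pooled.y_biomass:.4f} g/g  (n={pooled.n_replicates})")

result = compare_strains(arms["reference_n2"], arms["engineered_n2"])
print("\nengineered vs reference (N2-sparged):")
for name in ("y_ethanol", "y_biomass", "y_glycerol"):
    print(f"  {name}: {result.percent_change_rounded[name]:+d}% "
          f"(p = {result.p_value[name]:.3g}, "
          f"{'significant' if result.significant[name] else 'ns'} at p < 0.02)")

# Expected: ethanol ~+11%, biomass ~+12%, glycerol ~-71% -- the ethanol
# gain comes from redirecting the NADH that the reference strain dumps
# into glycerol.
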