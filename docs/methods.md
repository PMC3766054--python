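# Methods

## The model

`rubiflux` models anaerobic, sugar-limited growth of *Saccharomyces
cerevisiae* as a lumped, exactly balanced linear reaction network,
normalized to 100 mmol of combined hexose uptake. Glucose and galactose
are pooled as one 180 g/mol hexose species: at this level of lumping the
Embden–Meyerhof–Parnas and Leloir routes are both redox-neutral and
ATP-yielding, and any difference in activation ATP is absorbed into the
configurable ATP coefficients.

Six lumped pathways carry flux:

| flux | reaction (per unit flux) | NADH | NADPH | ATP |
|---|---|---|---|---|
| `v_ferment` | hexose → 2 ethanol + 2 CO₂ | 0 | 0 | +2 |
| `v_glycerol` | ½ hexose + NADH → glycerol | −1 | 0 | −1 |
| `v_oxppp` | hexose → Ru5P + CO₂ | 0 | +2 | −1 |
| `v_nonoxppp` | ⅚ hexose ↔ Ru5P (signed) | 0 | 0 | −7/6 |
| `v_rubisco` | Ru5P + CO₂ → 2 ethanol + 2 CO₂ | −2 | 0 | +1 |
| `v_biomass` | (1+`n_co2_biomass`)/6 hexose → 1 Cmol X + `n_co2_biomass` CO₂ | +`n_nadh` | −`n_nadph` | −1/`y_atp` |

Five balances are enforced exactly: hexose carbon (normalization to 100),
NADH, NADPH, Ru5P, and the ATP coupling `v_biomass = y_atp × net ATP`,
with the biomass yield on ATP held identical between scenarios.

**Scenarios.** In the *reference* scenario the PRK/Rubisco route is
absent (`v_rubisco = 0`) and glycerol formation closes the NADH balance.
In the *prk_rubisco* scenario the carboxylation route replaces glycerol
formation up to its capacity: the solver first assumes complete
replacement (`v_rubisco = n_nadh·v_biomass/2`, `v_glycerol = 0`); if the
required flux exceeds the effective Rubisco capacity, `v_rubisco` is
pinned at the capacity and glycerol closes the remainder. Each branch is
linear, so it is solved exactly as a 2×2 system in
(`v_ferment`, `v_biomass`); feasibility selects the branch, and the
reference scenario is the capacity-0 limit. No iteration or optimizer is
involved; infeasibility raises an error naming the violated balance
rather than clipping fluxes.

**Ru5P sourcing.** Ribulose-5-phosphate is preferentially drawn from the
oxidative pentose-phosphate pathway until its NADPH output matches the
biosynthetic demand (`v_oxppp = n_nadph·v_biomass/2`); any remaining
demand is met by the non-oxidative rearrangement reactions. The
non-oxidative flux is *signed*: when the oxidative branch makes more Ru5P
than the carboxylation route consumes (always in the reference scenario),
the surplus returns to glycolysis — the transhydrogenase-like conversion
NADH + NADP⁺ → NAD⁺ + NADPH at the whole-network level. The standalone
`allocate_ru5p` exposes both conventions (`min()` rule and recycle rule);
`solve_scenario` always enforces exact NADPH closure, which coincides
with the `min()` rule whenever the carboxylation demand is at least half
the NADPH demand and with the recycle rule otherwise.

**CO₂ limitation.** Dissolved CO₂ enters only through the Michaelis
fraction c/(K + c) (K = 0.26 mM for the form-II Rubisco), which scales a
*finite* capacity; balances are never rescaled. A Henry constant
(29.7 mM/atm, water at 30 °C) converts a sparging-gas CO₂ fraction to a
dissolved concentration when needed; with 10% CO₂ in the gas phase the
dissolved level (~3 mM) makes the factor ≈ 0.92, i.e. essentially
saturating.

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| `biomass_carbon_content` | 24.6 | g/Cmol | standard yeast biomass composition |
| `gamma_biomass` | 4.2 | e⁻/Cmol | CH₁.₈O₀.₅N₀.₂, used for measured-data electron recovery |
| `n_nadh` | 0.2305 | mol/Cmol | calibrated (see below) |
| `n_nadph` | 0.7239 | mol/Cmol | calibrated |
| `y_atp` | 0.4169 | Cmol/mol ATP | calibrated (≈10.3 g/mol ATP) |
| `n_co2_biomass` | 0.12 | mol/Cmol | fixed accounting choice |
| `k_evap` | 0.008 | 1/h | bioreactor ethanol evaporation constant |
| `K_co2` | 0.26 | mM | form-II Rubisco CO₂ affinity |
| `maintenance_atp` | 0 | mol/(g·h) | chemostats at one fixed, low dilution rate |
| ATP coefficients | +2, −1, +1, −1, −7/6 | mol/mol | see below |

**Calibration.** The published benchmark gives the reference strain's
yields (0.083 g/g biomass, 1.56 ethanol, 0.14 glycerol mol/mol) but not
the underlying biosynthesis coefficients. `calibrate` inverts the linear
balances: the glycerol yield pins `n_nadh` (= 14/60.73 per Cmol), exact
carbon closure pins the oxidative-PPP flux and hence `n_nadph`, and the
ATP balance pins `y_atp`. The packaged defaults are this calibration at
full precision, so `solve_scenario(reference)` reproduces the reference
yields to 1e-9 out of the box.

Because measured yields under-recover carbon (~0.963 before the PPP
term), the calibration absorbs the gap into the oxidative-PPP/CO₂ route,
which inflates `n_nadph` above its biochemical value (~0.72 vs the
0.2–0.5 expected from biosynthetic reaction counting). Consequently the
degree of reduction implied by the lumped coefficients,
γ = 4(1 + `n_co2_biomass`) + 2`n_nadph` − 2`n_nadh` ≈ 5.47, differs from
the empirical 4.2. The solver's electron-balance check therefore uses the
implied γ (with which closure is an exact linear consequence of the
C/NADH/NADPH balances, and serves as a redundancy check on the
implementation), while `balance_check` on measured data uses the
empirical `gamma_biomass`.

**ATP accounting for Ru5P sourcing.** The ⅙-hexose bookkeeping of the PPP
needs a phosphorylation-investment convention: 1 ATP per hexose entering
the oxidative branch (hexokinase), and 7/6 ATP per Ru5P built from an
F6P/GAP mix by the non-oxidative branch. These are documented defaults,
not measured facts; they are configurable, and the signed non-oxidative
flux returns the investment on recycle. The carboxylation route's net +1
ATP (two pyruvate-kinase ATP minus one PRK ATP) is fixed by its
stoichiometry.

**Engineered-strain encoding.** For an engineered strain with *residual*
glycerol formation, the inverse problem changes: measured product carbon
can exceed the hexose supply precisely because CO₂ is fixed into ethanol.
`calibrate_engineered` inherits `n_nadph` (strain-independent biology)
from the reference calibration, recovers the carboxylation flux from
exact carbon closure, and then `n_nadh` and `y_atp` from the NADH and ATP
balances. It returns the parameter set together with the Rubisco capacity
at which the capped scenario reproduces the measured yields exactly.

## Analysis pipeline

**Evaporation correction.** Ethanol leaves the broth with first-order
constant `k_evap`. At chemostat steady state, production balances washout
plus stripping, so the production-equivalent concentration is
C·(D + k)/D — an exact correction, configurable off (k = 0 is an exact
identity). In batch, produced(t) = C(t) + k∫₀ᵗC dτ with the integral by
trapezoid on the sample grid; on a 0.5 h grid the residual error is
≈2×10⁻⁴ relative, well below the 10⁻³ round-trip tolerance.

**Yields.** Mixed sugars are converted to moles of the pooled hexose
before molar yields; the gravimetric biomass yield uses total consumed
sugar mass. Replicates are summarized as average ± mean deviation (not
standard deviation); the strain comparison's two-sample t-test
(two-sided, equal variance) still uses sample variance, with significance
declared at p < 0.02. Headline percent changes are rounded to integer
percent only at the presentation layer.

**Growth rate.** μmax is the slope of ln(biomass) vs time over the
maximal contiguous window whose linear fit reaches R² ≥ 0.999 (ties
broken by R²), considering only windows where ln(biomass) rises by ≥ 0.1
— flat lag/stationary windows are perfectly linear and must be excluded
explicitly. The 0.999 default matters: at 0.99 the maximal-window rule
admits windows contaminated by lag or sugar-exhaustion samples and biases
μmax low by several percent. The lag time extrapolates the fitted line
back to the inoculum level. A constant-biomass series is reported as
μ = 0.

**Off-gas.** Net CO₂ evolution is gas_flow·(x_out − x_in)/V_m with
V_m = 24.06 l/mol (dry gas at the analyzer's 20 °C reference state). Net
fixation beyond tolerance triggers a warning flag, not an error.

## Synthetic data

The generator emulates the benchmark study design: duplicate independent
cultures; chemostats at D = 0.05 1/h on 12.5 + 12.5 g/l
glucose/galactose, sparged with N₂ or 10% CO₂, residual sugars near zero;
batch cultures on 20 g/l galactose with a lag phase. Noise is
multiplicative Gaussian (default 1% relative — realistic for HPLC and
dry-weight measurements), truncated at zero, with an independent
substream per replicate (`SeedSequence.spawn`), so fixed seeds give
bitwise-reproducible output.

Chemostat "truth" comes from the scenario solver: each packaged condition
is an effective parameter set calibrated so its scenario solution
reproduces that condition's benchmark yields exactly; broth ethanol is
pre-reduced by D/(D + k) so the analysis correction inverts the generator
exactly, and the off-gas fraction is the exact inverse of the
CO₂-evolution formula. The fixture gas flow (35 l/h per l broth, ~0.6
vvm) was chosen once so the reference/N₂ condition reproduces the
benchmark outlet CO₂ fraction (~0.9%).

Batch kinetics are the simplest growth-coupled model — lag, exponential
growth at μmax, product formation proportional to sugar consumption at
fixed yields until exhaustion — integrated by explicit sub-stepping
(0.01 h) with per-step exact exponential growth and an exact per-step
solution of the ethanol evaporation ODE. No Monod term is included
because only μmax, lag and final yields are compared. Absolute batch
yields are a documented assumption: the reference condition carries the
CO₂-sparged reference chemostat yields, the engineered condition applies
the observed batch deltas (glycerol −60%, ethanol +8%, biomass
unchanged); μmax = 0.25 1/h for both strains and lag 5 h vs 15 h.

What the generator does *not* emulate: CO₂ mass-transfer dynamics,
stochastic gene expression or PRK burden, Monod substrate kinetics,
autocorrelated sensor drift, or non-Gaussian outliers. Passing round
trips therefore validate the pipeline's arithmetic and inversion logic,
not its robustness to real-world artefacts beyond the simple noise model.

## Numerical choices and edge cases

- Balance residuals of every solved scenario must close to 1e-9 relative;
  the flux container enforces this on construction.
- `y_atp = 0` is allowed and gives the pure-fermentation limit (200 mmol
  ethanol per 100 mmol hexose, no biomass).
- Calibration rejects target yields whose carbon recovery (before the PPP
  term) falls outside a configurable band (default 0.95–1.05) or exceeds
  1 in the glycerol-closing mode (that would need a negative PPP flux);
  the engineered encoding must be used there.
- The capacity cap from CO₂ saturation multiplies finite capacities only;
  zero dissolved CO₂ disables the route entirely.
- Percent change against a zero reference yield is reported as undefined
  (flagged), never as infinity.
- Detection-limit censoring is monotone by construction (activity < lod).

## Problem sizes

All computations are desk-scale. The LP cross-check sweeps 120 random
parameter sets (~1 s); the noise-propagation check uses 1000 synthetic
replicates (~2 s); batch integration covers 40 h at 0.01 h sub-steps.
The full test suite runs in under ten seconds.

## Known limitations

- The model is stoichiometric only: no kinetics beyond the single CO₂
  saturation cap, no thermodynamics, no genome-scale detail, no modelling
  of GAL1-promoter regulation or PRK expression burden.
- The calibrated coefficients are *effective* values that absorb
  measurement non-closure; they reproduce the benchmark steady state
  exactly but should not be read as biochemical constants.
- The theoretical ethanol gain depends on the unprinted biosynthesis
  parameterization; with parameters calibrated to the reference strain
  the model predicts ~9% (1.70 mol/mol), a property checked as a band
  rather than a point value.
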