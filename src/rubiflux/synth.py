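"""Synthetic chemostat records and batch time series.

The generator emulates the study design the analysis pipeline assumes:
duplicate independent cultures, anaerobic sugar-limited chemostats at
D = 0.05 1/h on 12.5 + 12.5 g/l glucose/galactose sparged with N2 or 10%
CO2, and anaerobic batch cultures on 20 g/l galactose with a lag phase --
with first-order ethanol evaporation and small multiplicative Gaussian
measurement noise (concentrations are positive and HPLC / dry-weight
errors are relative, hence multiplicative, truncated at zero).

Chemostat "true" states are obtained from the scenario solver: each
packaged condition is an *effective* parameter set, calibrated so that the
glycerol-closing solution reproduces that condition's benchmark yields
exactly (the glycerol pathway is genomically intact in both strains, so a
glycerol-closing parameterization exists for each).  Broth ethanol is
reduced by the steady-state evaporation factor D/(D + k) so the analysis
correction inverts the generator exactly, and the off-gas CO2 fraction is
the exact inverse of :func:`rubiflux.ferm.net_co2_evolution`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .constants import MM_ETHANOL, MM_GLYCEROL, MM_HEXOSE
from .errors import RubifluxError
from .params import StoichParameters
from .records import BatchTimeSeries, ChemostatRecord, YieldSet
from .stoich import (
    PRK_RUBISCO,
    REFERENCE,
    ScenarioSpec,
    calibrate,
    calibrate_engineered,
    predict_yields,
    solve_scenario,
)

__all__ = [
    "ChemostatSettings",
    "BatchSettings",
    "GeneratorConfig",
    "generate_chemostat",
    "generate_batch",
    "load_chemostat_condition",
    "load_batch_condition",
    "CHEMOSTAT_CONDITIONS",
    "BATCH_CONDITIONS",
]

CHEMOSTAT_CONDITIONS = (
    "reference_n2",
    "reference_co2",
    "engineered_n2",
    "engineered_co2",
)
BATCH_CONDITIONS = ("reference", "engineered")


@dataclass(frozen=True)
class ChemostatSettings:
    dilution_rate: float = 0.05  # 1/h
    glucose_in: float = 12.5  # g/l
    galactose_in: float = 12.5
    glucose_residual: float = 0.02
    galactose_residual: float = 0.03
    gas_flow: float = 35.0  # l/h per l broth
    co2_in: float = 0.0  # inlet gas volume fraction


@dataclass(frozen=True)
class BatchSettings:
    initial_sugar: float = 20.0  # g/l galactose
    inoculum: float = 0.1  # g/l
    mu_max: float = 0.25  # 1/h
    lag: float = 5.0  # h
    t_end: float = 40.0  # h
    dt_sample: float = 0.5  # h
    dt_integration: float = 0.01  # h, explicit stepping grid


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one condition's replicates."""

    strain_mode: str = REFERENCE
    sparge: str = "n2"  # "n2" | "co2"
    params: StoichParameters = field(default_factory=StoichParameters)
    target_yields: YieldSet = field(
        default_factory=lambda: YieldSet(0.083, 1.56, 0.14)
    )
    noise_sd: float = 0.01  # relative Gaussian sd per measured quantity
    replicates: int = 2
    seed: int = 0
    chemostat: ChemostatSettings = field(default_factory=ChemostatSettings)
    batch: BatchSettings = field(default_factory=BatchSettings)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise RubifluxError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise RubifluxError("replicates must be >= 1")

    def with_(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)


def _fixture(name: str) -> dict:
    text = resources.files("rubiflux").joinpath(f"fixtures/{name}").read_text()
    return yaml.safe_load(text)


def load_chemostat_condition(
    condition: str, params: StoichParameters | None = None, **overrides
) -> GeneratorConfig:
    """Generator config for one packaged chemostat condition.

    ``condition`` is one of ``reference_n2``, ``reference_co2``,
    ``engineered_n2``, ``engineered_co2``.
    """
    raw = _fixture("chemostat_conditions.yaml")
    try:
        cond = raw["conditions"][condition]
    except KeyError:
        raise RubifluxError(
            f"unknown chemostat condition {condition!r}; "
            f"choose from {list(raw['conditions'])}"
        ) from None
    settings = ChemostatSettings(
        dilution_rate=raw["dilution_rate"],
        glucose_in=raw["glucose_in"],
        galactose_in=raw["galactose_in"],
        glucose_residual=raw["glucose_residual"],
        galactose_residual=raw["galactose_residual"],
        gas_flow=raw["gas_flow"],
        co2_in=cond["co2_in"],
    )
    yields = YieldSet(spread=dict(cond.get("spread", {})), **cond["yields"])
    return GeneratorConfig(
        strain_mode=cond["strain"],
        sparge=cond["sparge"],
        params=params or StoichParameters(),
        target_yields=yields,
        chemostat=settings,
        **overrides,
    )


def load_batch_condition(
    condition: str, params: StoichParameters | None = None, **overrides
) -> GeneratorConfig:
    """Generator config for one packaged batch condition (reference/engineered)."""
    raw = _fixture("batch_conditions.yaml")
    try:
        cond = raw["conditions"][condition]
    except KeyError:
        raise RubifluxError(
            f"unknown batch condition {condition!r}; "
            f"choose from {list(raw['conditions'])}"
        ) from None
    settings = BatchSettings(
        initial_sugar=raw["initial_sugar"],
        inoculum=raw["inoculum"],
        mu_max=cond["mu_max"],
        lag=cond["lag"],
        t_end=raw["t_end"],
        dt_sample=raw["dt_sample"],
    )
    return GeneratorConfig(
        strain_mode=cond["strain"],
        sparge="co2",
        params=params or StoichParameters(),
        target_yields=YieldSet(**cond["yields"]),
        batch=settings,
        **overrides,
    )


def _noisy(rng: np.random.Generator, value: float, sd: float) -> float:
    if sd == 0:
        return value
    return max(value * (1.0 + sd * rng.standard_normal()), 0.0)


def true_chemostat_state(config: GeneratorConfig) -> tuple[ChemostatRecord, YieldSet]:
    """Noise-free steady state implied by the configured target yields.

    The target yields are encoded as an effective parameter set (via the
    glycerol-closing calibration for the reference strain, or the
    carbon-closure carboxylation calibration for the engineered strain);
    the scenario solution of that parameter set reproduces the yields to
    solver precision, and its net CO2 flux -- which closes the carbon
    balance exactly -- sets the off-gas composition.
    """
    cs = config.chemostat
    if config.strain_mode == PRK_RUBISCO:
        params, capacity = calibrate_engineered(config.params, config.target_yields)
        spec = ScenarioSpec(
            mode=PRK_RUBISCO,
            co2_dissolved="saturating",
            rubisco_capacity=capacity,
            dilution_rate=cs.dilution_rate,
        )
    else:
        params = calibrate(config.params, config.target_yields)
        spec = ScenarioSpec(mode=REFERENCE, dilution_rate=cs.dilution_rate)
    flux = solve_scenario(params, spec)
    yields = predict_yields(flux, params)

    sugar_g = (cs.glucose_in - cs.glucose_residual) + (
        cs.galactose_in - cs.galactose_residual
    )
    sugar_mol = sugar_g / MM_HEXOSE  # mol/l
    d, k = cs.dilution_rate, params.k_evap

    ethanol_produced = yields.y_ethanol * sugar_mol * MM_ETHANOL  # g/l equivalent
    ethanol_broth = ethanol_produced * d / (d + k)  # steady-state evaporation loss
    q_co2 = (flux.co2_net / 100.0) * sugar_mol * d  # mol/l/h
    co2_out = cs.co2_in + q_co2 * params.gas_molar_volume / cs.gas_flow

    record = ChemostatRecord(
        dilution_rate=d,
        glucose_in=cs.glucose_in,
        galactose_in=cs.galactose_in,
        glucose_residual=cs.glucose_residual,
        galactose_residual=cs.galactose_residual,
        biomass=yields.y_biomass * sugar_g,
        ethanol=ethanol_broth,
        glycerol=yields.y_glycerol * sugar_mol * MM_GLYCEROL,
        gas_flow=cs.gas_flow,
        co2_in=cs.co2_in,
        co2_out=co2_out,
    )
    return record, yields


def generate_chemostat(config: GeneratorConfig) -> list[ChemostatRecord]:
    """Replicate chemostat records for one condition.

    Each replicate draws from an independent random substream of
    ``config.seed``; with ``noise_sd = 0`` replicates are identical and
    the analysis pipeline recovers the target yields exactly.
    """
    base, _ = true_chemostat_state(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    sd = config.noise_sd
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        glc_in = _noisy(rng, base.glucose_in, sd)
        gal_in = _noisy(rng, base.galactose_in, sd)
        records.append(
            ChemostatRecord(
                dilution_rate=base.dilution_rate,
                glucose_in=glc_in,
                galactose_in=gal_in,
                # residuals stay below their inlets even at extreme noise
                glucose_residual=min(_noisy(rng, base.glucose_residual, sd), glc_in),
                galactose_residual=min(
                    _noisy(rng, base.galactose_residual, sd), gal_in
                ),
                biomass=_noisy(rng, base.biomass, sd),
                ethanol=_noisy(rng, base.ethanol, sd),
                glycerol=_noisy(rng, base.glycerol, sd),
                gas_flow=base.gas_flow,
                co2_in=base.co2_in,
                co2_out=_noisy(rng, base.co2_out, sd),
                replicate_id=f"r{i + 1}",
            )
        )
    return records


def _simulate_batch_grid(config: GeneratorConfig) -> dict:
    """Explicit time-stepping of the growth-coupled batch model (noise-free)."""
    bs = config.batch
    y = config.target_yields
    k = config.params.k_evap
    if bs.inoculum <= 0:
        raise RubifluxError("inoculum must be positive")
    if y.y_biomass <= 0:
        raise RubifluxError("batch generation needs a positive biomass yield")

    eth_per_sugar = y.y_ethanol / MM_HEXOSE * MM_ETHANOL  # g ethanol / g sugar
    gly_per_sugar = y.y_glycerol / MM_HEXOSE * MM_GLYCEROL

    n_sub = max(int(round(bs.dt_sample / bs.dt_integration)), 1)
    dt = bs.dt_sample / n_sub
    times = np.arange(0.0, bs.t_end + 1e-9, bs.dt_sample)

    x, s, e, g = bs.inoculum, bs.initial_sugar, 0.0, 0.0
    decay = np.exp(-k * dt) if k > 0 else 1.0
    out = {"time": times, "biomass": [], "sugar": [], "ethanol": [], "glycerol": []}
    t = 0.0
    for target in times:
        while t < target - 1e-9:
            if t + dt / 2 >= bs.lag and s > 0 and bs.mu_max > 0:
                dx = x * (np.exp(bs.mu_max * dt) - 1.0)
                ds = dx / y.y_biomass
                if ds > s:  # sugar exhaustion mid-step
                    ds = s
                    dx = ds * y.y_biomass
                x += dx
                s -= ds
                produced = ds * eth_per_sugar
                g += ds * gly_per_sugar
            else:
                produced = 0.0
            if k > 0:
                # exact solution of dE/dt = -kE + p/dt over one step
                e = e * decay + (produced / dt) / k * (1.0 - decay)
            else:
                e += produced
            t += dt
        out["biomass"].append(x)
        out["sugar"].append(s)
        out["ethanol"].append(e)
        out["glycerol"].append(g)
    return {k2: np.asarray(v) for k2, v in out.items()}


def generate_batch(config: GeneratorConfig) -> list[BatchTimeSeries]:
    """Replicate batch time series: lag, exponential growth with
    growth-coupled product formation at the configured yields until sugar
    exhaustion, first-order ethanol evaporation during integration, and
    multiplicative measurement noise per sample."""
    grid = _simulate_batch_grid(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    sd = config.noise_sd
    series = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        def noisy_arr(values):
            if sd == 0:
                return values.copy()
            noise = 1.0 + sd * rng.standard_normal(values.shape)
            return np.maximum(values * noise, 0.0)
        series.append(
            BatchTimeSeries(
                time=grid["time"].copy(),
                biomass=noisy_arr(grid["biomass"]),
                sugar=noisy_arr(grid["sugar"]),
                ethanol=noisy_arr(grid["ethanol"]),
                glycerol=noisy_arr(grid["glycerol"]),
                replicate_id=f"r{i + 1}",
            )
        )
    return series
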