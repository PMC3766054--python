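"""Yields, rates, balances and strain comparisons from fermentation records.

Ethanol concentrations measured in the broth underestimate production
because ethanol is continuously stripped by the sparging gas with a
first-order evaporation constant ``k_evap`` (default 0.008 1/h for the
bioreactor setup modelled here).  Both the chemostat and the batch
analyses correct for this before computing yields.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import MM_ETHANOL, MM_GLYCEROL, MM_HEXOSE
from .errors import GrowthFitError, RubifluxError
from .params import StoichParameters
from .records import BatchTimeSeries, ChemostatRecord, ComparisonResult, GrowthFit, YieldSet

__all__ = [
    "correct_evaporation_chemostat",
    "correct_evaporation_batch",
    "chemostat_yields",
    "batch_yields",
    "pool_yields",
    "fit_growth_rate",
    "net_co2_evolution",
    "balance_check",
    "compare_strains",
]

YIELD_NAMES = ("y_biomass", "y_ethanol", "y_glycerol")


def correct_evaporation_chemostat(
    ethanol_conc: float, dilution_rate: float, k_evap: float
) -> float:
    """Production-equivalent ethanol concentration at chemostat steady state.

    At steady state the volumetric production rate balances washout plus
    evaporation, ``q = (D + k) * C``, so yield arithmetic should use
    ``C * (D + k) / D`` in place of the measured broth concentration.
    """
    if dilution_rate <= 0:
        raise RubifluxError("dilution_rate must be positive")
    if ethanol_conc < 0 or k_evap < 0:
        raise RubifluxError("ethanol_conc and k_evap must be non-negative")
    if k_evap == 0.0:  # exact identity, no float round-trip
        return ethanol_conc
    return ethanol_conc * (dilution_rate + k_evap) / dilution_rate


def correct_evaporation_batch(series: BatchTimeSeries, k_evap: float) -> np.ndarray:
    """Cumulative *produced* ethanol per time point of a batch culture, g/l.

    produced(t) = C(t) + k * integral_0^t C(tau) dtau, with the integral
    evaluated by the trapezoid rule on the sample grid.
    """
    if k_evap < 0:
        raise RubifluxError("k_evap must be non-negative")
    c = series.ethanol
    integral = np.concatenate(
        [[0.0], np.cumsum(np.diff(series.time) * (c[1:] + c[:-1]) / 2.0)]
    )
    return c + k_evap * integral


def chemostat_yields(record: ChemostatRecord, params: StoichParameters) -> YieldSet:
    """Biomass, ethanol and glycerol yields on consumed sugar for one steady state."""
    sugar_g = record.sugar_consumed
    if sugar_g <= 0:
        raise RubifluxError("no sugar consumed; yields undefined")
    sugar_mol = sugar_g / MM_HEXOSE
    ethanol_g = correct_evaporation_chemostat(
        record.ethanol, record.dilution_rate, params.k_evap
    )
    return YieldSet(
        y_biomass=record.biomass / sugar_g,
        y_ethanol=(ethanol_g / MM_ETHANOL) / sugar_mol,
        y_glycerol=(record.glycerol / MM_GLYCEROL) / sugar_mol,
        evaporation_corrected=params.k_evap > 0,
    )


def batch_yields(series: BatchTimeSeries, params: StoichParameters) -> YieldSet:
    """Yields on consumed sugar over the whole batch, evaporation-corrected."""
    sugar_g = series.sugar[0] - series.sugar[-1]
    if sugar_g <= 0:
        raise RubifluxError("no sugar consumed over the series; yields undefined")
    produced = correct_evaporation_batch(series, params.k_evap)
    d_eth = produced[-1] - produced[0]
    d_gly = series.glycerol[-1] - series.glycerol[0]
    d_bio = series.biomass[-1] - series.biomass[0]
    sugar_mol = sugar_g / MM_HEXOSE
    return YieldSet(
        y_biomass=max(d_bio, 0.0) / sugar_g,
        y_ethanol=max(d_eth, 0.0) / MM_ETHANOL / sugar_mol,
        y_glycerol=max(d_gly, 0.0) / MM_GLYCEROL / sugar_mol,
        evaporation_corrected=params.k_evap > 0,
    )


def pool_yields(replicates: Sequence[YieldSet]) -> YieldSet:
    """Pool replicate yield sets as average +/- mean deviation."""
    if not replicates:
        raise RubifluxError("no replicates to pool")
    means = {}
    spread = {}
    for name in YIELD_NAMES:
        values = np.array([getattr(y, name) for y in replicates], dtype=float)
        means[name] = float(values.mean())
        spread[name] = float(np.abs(values - values.mean()).mean())
    return YieldSet(
        y_biomass=means["y_biomass"],
        y_ethanol=means["y_ethanol"],
        y_glycerol=means["y_glycerol"],
        spread=spread,
        evaporation_corrected=all(y.evaporation_corrected for y in replicates),
        n_replicates=len(replicates),
    )


def fit_growth_rate(
    series: BatchTimeSeries,
    r2_threshold: float = 0.999,
    min_points: int = 4,
    min_log_growth: float = 0.1,
) -> GrowthFit:
    """Maximum specific growth rate from the log-linear part of a growth curve.

    mu_max is the slope of ln(biomass) vs time over the *maximal
    contiguous window* whose linear fit reaches ``r2_threshold`` (ties
    broken by R^2), considering only windows in which ln(biomass) rises
    by at least ``min_log_growth`` -- this excludes the lag phase and the
    stationary plateau, which are perfectly linear but flat.  If no
    window grows, the series is treated as non-growing (mu = 0).  The lag
    time extrapolates the fitted line back to the inoculum level:
    ``lag = (ln X0 - intercept) / slope``.
    """
    mask = series.biomass > 0
    if mask.sum() < min_points:
        raise GrowthFitError("need at least 4 positive-biomass samples")
    t = series.time[mask]
    ln_x = np.log(series.biomass[mask])

    best = None  # (n_points, r2, slope, intercept, i, j); growing windows only
    best_flat = None
    n = t.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            tt, yy = t[i:j], ln_x[i:j]
            ss_tot = np.sum((yy - yy.mean()) ** 2)
            if ss_tot < 1e-30:  # constant biomass: perfect zero-slope fit
                slope, intercept, r2 = 0.0, yy.mean(), 1.0
            else:
                res = stats.linregress(tt, yy)
                slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
            if r2 < r2_threshold:
                continue
            key = (j - i, r2, slope, intercept, i, j)
            if yy[-1] - yy[0] >= min_log_growth:
                if best is None or key[:2] > best[:2]:
                    best = key
            elif best_flat is None or key[:2] > best_flat[:2]:
                best_flat = key
    if best is None:
        best = best_flat
    if best is None:
        raise GrowthFitError(
            f"no contiguous window of >= {min_points} samples reaches "
            f"R^2 >= {r2_threshold}"
        )
    npts, r2, slope, intercept, i, j = best
    mu = max(slope, 0.0)
    if mu > 0:
        lag = (ln_x[0] - intercept) / slope
    else:
        lag = 0.0
    return GrowthFit(
        mu_max=mu, lag_time=lag, window=(float(t[i]), float(t[j - 1])),
        r_squared=float(r2), n_points=npts,
    )


def net_co2_evolution(
    record: ChemostatRecord, params: StoichParameters, tolerance: float = 1e-9
) -> float:
    """Net volumetric CO2 evolution rate, mmol CO2 per hour per litre broth.

    ``gas_flow * (co2_out - co2_in) / molar volume``; roughly zero net
    when sparging with CO2-enriched gas and fixation balances evolution.
    A warning is emitted when fixation exceeds evolution beyond tolerance.
    """
    if record.gas_flow <= 0:
        raise RubifluxError("gas_flow must be positive")
    delta = record.co2_out - record.co2_in
    if delta < -tolerance:
        warnings.warn(
            "net CO2 fixation exceeds evolution (co2_out < co2_in)",
            RuntimeWarning,
            stacklevel=2,
        )
    return record.gas_flow * delta / params.gas_molar_volume * 1000.0


def balance_check(
    yields: YieldSet,
    params: StoichParameters,
    co2_yield: float,
    band: tuple[float, float] = (0.95, 1.05),
) -> dict:
    """Carbon and electron recovery of a yield set plus a CO2 estimate.

    ``co2_yield`` is in mol CO2 per mol hexose.  Recoveries are fractions
    of the substrate carbon / electrons found in products; PASS iff both
    lie within ``band``.  Electron recovery uses the empirical biomass
    degree of reduction ``params.gamma_biomass``.
    """
    biomass_cmol = yields.y_biomass * MM_HEXOSE / params.biomass_carbon_content
    carbon = (
        2.0 * yields.y_ethanol + 3.0 * yields.y_glycerol + biomass_cmol + co2_yield
    ) / 6.0
    electrons = (
        12.0 * yields.y_ethanol
        + 14.0 * yields.y_glycerol
        + params.gamma_biomass * biomass_cmol
    ) / 24.0
    ok = band[0] <= carbon <= band[1] and band[0] <= electrons <= band[1]
    return {
        "carbon_recovery": carbon,
        "electron_recovery": electrons,
        "pass": bool(ok),
        "band": band,
    }


def compare_strains(
    ref: Sequence[YieldSet], eng: Sequence[YieldSet], alpha: float = 0.02
) -> ComparisonResult:
    """Percent yield changes (engineered vs reference) with t-test significance.

    Percent change is computed on replicate means, reported at full
    precision and rounded to the nearest integer percent; p-values come
    from the two-sided, equal-variance two-sample t-test on the
    replicates.  Requires at least two replicates per arm.
    """
    if len(ref) < 2 or len(eng) < 2:
        raise RubifluxError("need at least 2 replicates per strain")
    change, rounded, pvals, signif, undefined = {}, {}, {}, {}, []
    for name in YIELD_NAMES:
        a = np.array([getattr(y, name) for y in ref], dtype=float)
        b = np.array([getattr(y, name) for y in eng], dtype=float)
        if a.mean() == 0:
            undefined.append(name)
            change[name] = math.nan
            rounded[name] = math.nan
        else:
            pct = 100.0 * (b.mean() - a.mean()) / a.mean()
            change[name] = pct
            rounded[name] = int(round(pct))
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and a.mean() == b.mean():
            p = 1.0  # identical arms with zero variance
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            if math.isnan(p):
                p = 1.0
        pvals[name] = p
        signif[name] = p < alpha
    return ComparisonResult(
        percent_change=change,
        percent_change_rounded=rounded,
        p_value=pvals,
        significant=signif,
        alpha=alpha,
        undefined=tuple(undefined),
    )
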