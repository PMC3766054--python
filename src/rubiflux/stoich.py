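"""Lumped redox-balance scenarios for anaerobic yeast fermentation.

Two scenarios of anaerobic sugar catabolism are solved as an exactly
balanced linear reaction network, normalized to 100 mmol combined hexose
(glucose + galactose) uptake:

* ``reference`` -- the wild-type network, in which excess NADH from
  biosynthesis is reoxidized by glycerol formation;
* ``prk_rubisco`` -- an engineered network in which phosphoribulokinase
  (PRK) and ribulose-1,5-bisphosphate carboxylase (Rubisco) carboxylate
  ribulose-5-phosphate, so that CO2 serves as the electron acceptor:
  each Ru5P + CO2 yields two 3-phosphoglycerate, hence two extra ethanol
  and two CO2 while reoxidizing two NADH.

Five balances are enforced exactly: carbon (as hexose equivalents), NADH,
NADPH, Ru5P, and ATP, the latter through the coupling
``v_biomass = y_atp * net ATP`` with the biomass yield on ATP held
identical between scenarios.  Ru5P is sourced preferentially from the
oxidative pentose-phosphate pathway until its NADPH output matches the
biosynthetic NADPH demand, and from the non-oxidative rearrangement
reactions beyond that point; in the reference scenario the oxidative
branch still runs to meet NADPH demand, with the Ru5P returned to
glycolysis (a signed, negative non-oxidative flux -- the
transhydrogenase-like conversion NADH + NADP+ -> NAD+ + NADPH).

All relations are linear within each min()-branch of the allocation rule,
so each branch is solved exactly and feasibility selects the branch; no
iteration or optimizer is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Union

import numpy as np

from .constants import HEXOSE_BASIS, MM_HEXOSE
from .errors import CalibrationError, InfeasibleScenarioError, RubifluxError
from .params import StoichParameters
from .records import YieldSet

__all__ = [
    "ScenarioSpec",
    "FluxDistribution",
    "RubiscoRouteDeltas",
    "GlobalProjection",
    "rubisco_route_stoichiometry",
    "allocate_ru5p",
    "co2_saturation_factor",
    "solve_scenario",
    "predict_yields",
    "calibrate",
    "scenario_gain",
    "project_global_gain",
    "electron_balance_residual",
]

REFERENCE = "reference"
PRK_RUBISCO = "prk_rubisco"

#: Relative tolerance on balance residuals of a solved scenario.
BALANCE_RTOL = 1e-9

Saturating = Union[float, str]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which scenario to solve and under what CO2/capacity constraints.

    ``co2_dissolved`` is the dissolved CO2 concentration in mM, or the
    string ``"saturating"``.  ``rubisco_capacity`` is the maximal Ru5P
    carboxylation flux in mmol per 100 mmol hexose, or ``"unlimited"``;
    the dissolved-CO2 saturation factor scales a finite capacity only.
    """

    mode: str = REFERENCE
    co2_dissolved: Saturating = "saturating"
    rubisco_capacity: Saturating = "unlimited"
    dilution_rate: float = 0.05  # used only when maintenance_atp > 0

    def __post_init__(self) -> None:
        if self.mode not in (REFERENCE, PRK_RUBISCO):
            raise RubifluxError(f"unknown scenario mode {self.mode!r}")
        if not _is_saturating(self.co2_dissolved) and float(self.co2_dissolved) < 0:
            raise RubifluxError("co2_dissolved must be >= 0 or 'saturating'")
        if not _is_unlimited(self.rubisco_capacity) and float(self.rubisco_capacity) < 0:
            raise RubifluxError("rubisco_capacity must be >= 0 or 'unlimited'")
        if self.dilution_rate <= 0:
            raise RubifluxError("dilution_rate must be positive")


def _is_saturating(value: Saturating) -> bool:
    return (isinstance(value, str) and value == "saturating") or (
        isinstance(value, float) and math.isinf(value)
    )


def _is_unlimited(value: Saturating) -> bool:
    return (isinstance(value, str) and value == "unlimited") or (
        isinstance(value, float) and math.isinf(value)
    )


@dataclass(frozen=True)
class FluxDistribution:
    """Named pathway fluxes in mmol per 100 mmol combined hexose uptake.

    ``v_nonoxppp`` is signed: negative values represent Ru5P re-entering
    glycolysis through the rearrangement reactions (reference scenario).
    ``residuals`` maps balance name to its absolute residual.
    """

    v_ferment: float
    v_glycerol: float
    v_oxppp: float
    v_nonoxppp: float
    v_rubisco: float
    v_biomass: float  # Cmol (mmol basis)
    ethanol_out: float
    glycerol_out: float
    co2_fixed: float
    co2_emitted: float
    co2_net: float
    residuals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tol = BALANCE_RTOL * HEXOSE_BASIS
        for name in ("v_ferment", "v_glycerol", "v_oxppp", "v_rubisco", "v_biomass"):
            if getattr(self, name) < -tol:
                raise RubifluxError(f"pathway flux {name} is negative")
        for balance, value in self.residuals.items():
            if abs(value) > tol:
                raise RubifluxError(
                    f"{balance} balance residual {value:.3e} exceeds tolerance"
                )

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "v_ferment", "v_glycerol", "v_oxppp", "v_nonoxppp", "v_rubisco",
                "v_biomass", "ethanol_out", "glycerol_out", "co2_fixed",
                "co2_emitted", "co2_net",
            )
        }
        d.update({f"residual_{k}": v for k, v in self.residuals.items()})
        return d


class RubiscoRouteDeltas(NamedTuple):
    """Per-route net changes caused by carboxylating Ru5P (mmol)."""

    ethanol: float
    nadh: float
    co2_fixed: float
    co2_emitted: float
    atp: float


def rubisco_route_stoichiometry(
    v_rubisco: float, atp_per_ru5p: float = 1.0
) -> RubiscoRouteDeltas:
    """Net deltas of the PRK/Rubisco route per ``v_rubisco`` mmol Ru5P.

    Ru5P + CO2 -> 2 x 3-phosphoglycerate -> 2 ethanol + 2 CO2, with net
    oxidation of 2 NADH; one CO2 is fixed and two are re-emitted, so the
    route is a net CO2 source of +1 per Ru5P.  The net ATP yield defaults
    to +1 (two pyruvate-kinase ATP minus one PRK ATP).
    """
    if v_rubisco < 0:
        raise RubifluxError("v_rubisco must be non-negative")
    return RubiscoRouteDeltas(
        ethanol=2.0 * v_rubisco,
        nadh=-2.0 * v_rubisco,
        co2_fixed=1.0 * v_rubisco,
        co2_emitted=2.0 * v_rubisco,
        atp=atp_per_ru5p * v_rubisco,
    )


def allocate_ru5p(
    ru5p_demand: float, nadph_demand: float, allow_recycle: bool = False
) -> tuple[float, float]:
    """Split Ru5P sourcing between the oxidative and non-oxidative PPP.

    Ru5P is preferentially drawn from the oxidative branch (2 NADPH per
    Ru5P) until the NADPH output matches ``nadph_demand``; the remainder
    comes from the non-oxidative rearrangements:

    ``v_oxppp = min(ru5p_demand, nadph_demand / 2)``.

    With ``allow_recycle=True`` (reference-scenario convention, where the
    oxidative branch is the sole NADPH source and must run regardless of
    Ru5P demand) the oxidative flux is pinned at ``nadph_demand / 2`` and
    the non-oxidative flux is signed -- negative values return surplus
    Ru5P to glycolysis.
    """
    if ru5p_demand < 0 or nadph_demand < 0:
        raise RubifluxError("ru5p_demand and nadph_demand must be >= 0")
    if allow_recycle:
        v_oxppp = nadph_demand / 2.0
    else:
        v_oxppp = min(ru5p_demand, nadph_demand / 2.0)
    return v_oxppp, ru5p_demand - v_oxppp


def co2_saturation_factor(c_dissolved: Saturating, K_co2: float) -> float:
    """Michaelis fraction c/(K + c) of Rubisco capacity at dissolved CO2 ``c`` (mM).

    Used only to cap ``rubisco_capacity``; balances are never rescaled.
    """
    if K_co2 <= 0:
        raise RubifluxError("K_co2 must be positive")
    if _is_saturating(c_dissolved):
        return 1.0
    c = float(c_dissolved)
    if c < 0:
        raise RubifluxError("dissolved CO2 must be non-negative")
    return c / (K_co2 + c)


def _effective_capacity(params: StoichParameters, spec: ScenarioSpec) -> float:
    if spec.mode == REFERENCE:
        return 0.0
    factor = co2_saturation_factor(spec.co2_dissolved, params.K_co2)
    if factor == 0.0:
        return 0.0
    if _is_unlimited(spec.rubisco_capacity):
        return math.inf
    return float(spec.rubisco_capacity) * factor


def solve_scenario(params: StoichParameters, spec: ScenarioSpec) -> FluxDistribution:
    """Solve the scenario's carbon/NADH/NADPH/ATP balances exactly.

    Piecewise-linear strategy: first assume glycerol formation is fully
    replaced (``v_rubisco = n_nadh * v_biomass / 2``); if the required
    carboxylation flux exceeds the effective Rubisco capacity, pin
    ``v_rubisco`` at the capacity and let glycerol close the remaining
    NADH balance.  Each branch is a 2x2 linear solve in
    ``(v_ferment, v_biomass)``; the reference scenario is the capacity-0
    limit of the second branch.
    """
    cap = _effective_capacity(params, spec)
    a = params.atp_coeffs
    n_co2b = params.n_co2_biomass
    maint = params.maintenance_atp * params.biomass_carbon_content / spec.dilution_rate

    branches = []
    if cap > 0:
        branches.append("replace")  # glycerol fully replaced
    branches.append("capped")  # v_rubisco pinned at capacity (0 in reference)

    last_failure = "carbon"
    for branch in branches:
        if branch == "replace":
            rub = (0.0, params.n_nadh / 2.0)  # (const, per v_biomass)
            gly = (0.0, 0.0)
        else:
            rub_cap = cap if math.isfinite(cap) else 0.0
            rub = (rub_cap, 0.0)
            gly = (-2.0 * rub_cap, params.n_nadh)
        ox = (0.0, params.n_nadph / 2.0)  # NADPH closure: 2*v_ox = n_nadph*v_b
        non = (rub[0] - ox[0], rub[1] - ox[1])  # Ru5P closure

        # hexose balance: v_f + 1/2 gly + ox + 5/6 non + (1+n_co2b)/6 v_b = 100
        h1 = 0.5 * gly[1] + ox[1] + 5.0 / 6.0 * non[1] + (1.0 + n_co2b) / 6.0
        h0 = 0.5 * gly[0] + ox[0] + 5.0 / 6.0 * non[0]
        # ATP coupling: v_b = y_atp * (net ATP - maint * v_b)
        p1 = a.glycerol * gly[1] + a.rubisco * rub[1] + a.oxppp * ox[1] + a.nonoxppp * non[1]
        p0 = a.glycerol * gly[0] + a.rubisco * rub[0] + a.oxppp * ox[0] + a.nonoxppp * non[0]

        matrix = np.array(
            [
                [1.0, h1],
                [-a.fermentation * params.y_atp, 1.0 - params.y_atp * (p1 - maint)],
            ]
        )
        rhs = np.array([HEXOSE_BASIS - h0, params.y_atp * p0])
        try:
            solution = np.linalg.solve(matrix, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate params
            raise InfeasibleScenarioError("ATP", str(exc)) from None
        v_f, v_b = float(solution[0]), float(solution[1])

        v_rub = rub[0] + rub[1] * v_b
        v_gly = gly[0] + gly[1] * v_b
        tol = BALANCE_RTOL * HEXOSE_BASIS
        if v_b < -tol:
            last_failure = "ATP"
            continue
        if v_f < -tol:
            last_failure = "carbon"
            continue
        if branch == "replace" and v_rub > cap * (1.0 + BALANCE_RTOL):
            continue  # capacity exceeded -> try capped branch
        if v_gly < -tol:
            last_failure = "NADH"
            continue
        return _assemble(params, v_f, max(v_b, 0.0), v_rub, max(v_gly, 0.0), maint)

    raise InfeasibleScenarioError(last_failure)


def _assemble(
    params: StoichParameters,
    v_f: float,
    v_b: float,
    v_rub: float,
    v_gly: float,
    maint: float = 0.0,
) -> FluxDistribution:
    a = params.atp_coeffs
    n_co2b = params.n_co2_biomass
    v_ox = params.n_nadph * v_b / 2.0
    v_non = v_rub - v_ox

    ethanol = 2.0 * v_f + 2.0 * v_rub
    co2_emitted = 2.0 * v_f + v_ox + 2.0 * v_rub + n_co2b * v_b
    co2_fixed = v_rub

    hexose_used = (
        v_f + 0.5 * v_gly + v_ox + 5.0 / 6.0 * v_non + (1.0 + n_co2b) / 6.0 * v_b
    )
    residuals = {
        "carbon": hexose_used - HEXOSE_BASIS,
        "nadh": params.n_nadh * v_b - v_gly - 2.0 * v_rub,
        "nadph": 2.0 * v_ox - params.n_nadph * v_b,
        "atp": params.y_atp
        * (
            a.fermentation * v_f
            + a.glycerol * v_gly
            + a.rubisco * v_rub
            + a.oxppp * v_ox
            + a.nonoxppp * v_non
            - maint * v_b
        )
        - v_b,
    }
    return FluxDistribution(
        v_ferment=v_f,
        v_glycerol=v_gly,
        v_oxppp=v_ox,
        v_nonoxppp=v_non,
        v_rubisco=v_rub,
        v_biomass=v_b,
        ethanol_out=ethanol,
        glycerol_out=v_gly,
        co2_fixed=co2_fixed,
        co2_emitted=co2_emitted,
        co2_net=co2_emitted - co2_fixed,
        residuals=residuals,
    )


def electron_balance_residual(
    flux: FluxDistribution, params: StoichParameters, gamma: float | None = None
) -> float:
    """Degree-of-reduction residual (mmol electrons per 100 mmol hexose).

    Hexose carries 24 e-/mol, ethanol 12, glycerol 14, CO2 none and
    biomass ``gamma`` e-/Cmol.  By default ``gamma`` is the value implied
    by the lumped biosynthesis coefficients (``params.implied_gamma``),
    with which closure is an exact consequence of the C/NADH/NADPH
    balances -- a redundancy check on the implementation.
    """
    g = params.implied_gamma if gamma is None else gamma
    electrons_out = (
        12.0 * flux.ethanol_out + 14.0 * flux.glycerol_out + g * flux.v_biomass
    )
    return electrons_out - 24.0 * HEXOSE_BASIS


def predict_yields(flux: FluxDistribution, params: StoichParameters) -> YieldSet:
    """Convert a flux distribution to yield units.

    Ethanol and glycerol in mol per mol hexose; biomass in gram per gram
    hexose via the biomass carbon content and the 180 g/mol hexose mass.
    """
    return YieldSet(
        y_biomass=flux.v_biomass * params.biomass_carbon_content / (HEXOSE_BASIS * MM_HEXOSE),
        y_ethanol=flux.ethanol_out / HEXOSE_BASIS,
        y_glycerol=flux.glycerol_out / HEXOSE_BASIS,
        evaporation_corrected=False,
    )


def calibrate(
    params0: StoichParameters,
    reference_yields: YieldSet,
    recovery_band: tuple[float, float] = (0.95, 1.05),
) -> StoichParameters:
    """Recover ``n_nadh``, ``n_nadph`` and ``y_atp`` from reference yields.

    Inverts the linear balance equations of the reference scenario so that
    ``solve_scenario(reference)`` reproduces ``reference_yields`` exactly:
    the glycerol yield pins the biosynthetic NADH excess, carbon closure
    pins the oxidative-PPP flux (hence the NADPH demand), and the ATP
    balance pins the biomass yield on ATP.  Other fields are taken from
    ``params0``.

    Raises
    ------
    CalibrationError
        If the target yields are internally inconsistent: carbon recovery
        (before assigning the residual to the oxidative PPP) outside
        ``recovery_band``, or above 1 (which would require a negative
        oxidative-PPP flux).
    """
    y = reference_yields
    if min(y.y_biomass, y.y_ethanol, y.y_glycerol) < 0:
        raise CalibrationError("target yields must be non-negative")
    v_b = y.y_biomass * HEXOSE_BASIS * MM_HEXOSE / params0.biomass_carbon_content
    v_f = HEXOSE_BASIS * y.y_ethanol / 2.0
    v_gly = HEXOSE_BASIS * y.y_glycerol

    carbon_products = (
        2.0 * HEXOSE_BASIS * y.y_ethanol  # ethanol C
        + 3.0 * HEXOSE_BASIS * y.y_glycerol  # glycerol C
        + v_b  # biomass C
        + 2.0 * v_f  # fermentative CO2
        + params0.n_co2_biomass * v_b  # biosynthetic CO2
    )
    recovery = carbon_products / (6.0 * HEXOSE_BASIS)
    if not (recovery_band[0] <= recovery <= recovery_band[1]):
        raise CalibrationError(
            f"carbon recovery of target yields is {recovery:.3f}, outside "
            f"[{recovery_band[0]}, {recovery_band[1]}]"
        )
    v_ox = 6.0 * HEXOSE_BASIS - carbon_products
    if v_ox < -BALANCE_RTOL * HEXOSE_BASIS:
        raise CalibrationError(
            f"carbon recovery {recovery:.3f} > 1 would require a negative "
            "oxidative-PPP flux"
        )
    v_ox = max(v_ox, 0.0)

    a = params0.atp_coeffs
    if v_b == 0.0:
        # Pure-fermentation limit: biosynthetic coefficients are unused.
        return params0.with_(y_atp=0.0)
    n_nadh = v_gly / v_b
    n_nadph = 2.0 * v_ox / v_b
    net_atp = (
        a.fermentation * v_f
        + a.glycerol * v_gly
        + a.oxppp * v_ox
        + a.nonoxppp * (-v_ox)
    )
    if net_atp <= 0:
        raise CalibrationError("net catabolic ATP of target yields is not positive")
    y_atp = v_b / net_atp
    if n_nadh <= 0 or n_nadph <= 0:
        raise CalibrationError(
            "target yields imply non-positive biosynthetic cofactor coefficients"
        )
    return params0.with_(n_nadh=n_nadh, n_nadph=n_nadph, y_atp=y_atp)


def calibrate_engineered(
    params0: StoichParameters, yields: YieldSet
) -> tuple[StoichParameters, float]:
    """Encode measured yields of a PRK/Rubisco strain as an exact scenario.

    For an engineered strain with residual glycerol formation, the
    observables (biomass, ethanol, glycerol yields) pin ``n_nadh`` and
    ``y_atp`` once the carboxylation flux is known; the carboxylation flux
    itself is recovered from exact carbon closure, since CO2 fixed into
    ethanol is the only way product carbon can exceed the hexose supply.
    The NADPH demand per Cmol biomass is strain-independent biology and is
    inherited from ``params0`` (normally the reference-strain calibration).

    Returns the effective parameter set and the Rubisco capacity
    (mmol Ru5P per 100 mmol hexose) at which
    ``solve_scenario(prk_rubisco, capacity)`` reproduces ``yields`` exactly.
    """
    y = yields
    if min(y.y_biomass, y.y_ethanol, y.y_glycerol) < 0:
        raise CalibrationError("target yields must be non-negative")
    v_b = y.y_biomass * HEXOSE_BASIS * MM_HEXOSE / params0.biomass_carbon_content
    v_gly = HEXOSE_BASIS * y.y_glycerol
    ethanol = HEXOSE_BASIS * y.y_ethanol
    if v_b == 0.0:
        raise CalibrationError("engineered calibration needs a positive biomass yield")
    v_ox = params0.n_nadph * v_b / 2.0
    n_co2b = params0.n_co2_biomass
    # carbon: v_f + 5/6 v_rub = HEXOSE_BASIS - v_gly/2 - v_ox/6 - (1+n_co2b)/6 v_b
    # ethanol: v_f + v_rub = ethanol / 2
    carbon_rhs = (
        HEXOSE_BASIS - v_gly / 2.0 - v_ox / 6.0 - (1.0 + n_co2b) / 6.0 * v_b
    )
    v_rub = 6.0 * (ethanol / 2.0 - carbon_rhs)
    v_f = ethanol / 2.0 - v_rub
    if v_rub < -BALANCE_RTOL * HEXOSE_BASIS:
        raise CalibrationError(
            "target yields imply a negative carboxylation flux; "
            "use the reference-mode calibration instead"
        )
    v_rub = max(v_rub, 0.0)
    if v_f < 0:
        raise CalibrationError("target yields imply a negative fermentative flux")
    n_nadh = (v_gly + 2.0 * v_rub) / v_b
    a = params0.atp_coeffs
    net_atp = (
        a.fermentation * v_f
        + a.glycerol * v_gly
        + a.rubisco * v_rub
        + a.oxppp * v_ox
        + a.nonoxppp * (v_rub - v_ox)
    )
    if net_atp <= 0:
        raise CalibrationError("net catabolic ATP of target yields is not positive")
    if n_nadh <= 0:
        raise CalibrationError("target yields imply no biosynthetic NADH excess")
    return params0.with_(n_nadh=n_nadh, y_atp=v_b / net_atp), v_rub


def scenario_gain(params: StoichParameters) -> float:
    """Relative ethanol-yield increase of the engineered over the reference scenario.

    Both scenarios are solved with the same parameters (equal biomass
    yield on ATP); the engineered scenario runs at unlimited Rubisco
    capacity under saturating CO2.
    """
    ref = solve_scenario(params, ScenarioSpec(mode=REFERENCE))
    eng = solve_scenario(params, ScenarioSpec(mode=PRK_RUBISCO))
    if ref.ethanol_out <= 0:
        raise RubifluxError("reference scenario produces no ethanol")
    return (eng.ethanol_out - ref.ethanol_out) / ref.ethanol_out


class GlobalProjection(NamedTuple):
    additional_volume: float
    rounded: float


def _round_one_sig(x: float) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent)


def project_global_gain(total_volume: float, sugar_loss_fraction: float) -> GlobalProjection:
    """Extra product volume if sugar lost to glycerol were redirected to ethanol.

    With a fraction ``f`` of consumed sugar lost to the by-product, current
    production corresponds to ``1 - f`` of the sugar; redirecting the loss
    at the prevailing yield adds ``total_volume * f / (1 - f)``.  Returned
    raw and rounded to one significant figure.
    """
    if total_volume <= 0:
        raise RubifluxError("total_volume must be positive")
    if not 0.0 <= sugar_loss_fraction < 1.0:
        raise RubifluxError("sugar_loss_fraction must be in [0, 1)")
    extra = total_volume * sugar_loss_fraction / (1.0 - sugar_loss_fraction)
    return GlobalProjection(extra, _round_one_sig(extra))
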