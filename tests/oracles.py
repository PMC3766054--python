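"""Independent brute-force oracles used to cross-check the solver.

The linear-programming oracle maximizes ethanol over the same carbon /
NADH / NADPH / Ru5P / ATP balances the scenario solver enforces, using
scipy's HiGHS backend -- a completely separate solution path from the
package's exact per-branch linear solve.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog

from rubiflux import StoichParameters
from rubiflux.constants import HEXOSE_BASIS


def lp_max_ethanol(params: StoichParameters, capacity: float = math.inf) -> dict:
    """Maximize ethanol output subject to the scenario balances.

    Variables: v_ferment, v_glycerol, v_oxppp, v_nonoxppp (free sign),
    v_rubisco (bounded by ``capacity``), v_biomass.  Returns the optimal
    fluxes and the ethanol maximum in mmol per 100 mmol hexose.
    """
    a = params.atp_coeffs
    n_co2b = params.n_co2_biomass
    A_eq = [
        # hexose balance
        [1.0, 0.5, 1.0, 5.0 / 6.0, 0.0, (1.0 + n_co2b) / 6.0],
        # NADH balance
        [0.0, -1.0, 0.0, 0.0, -2.0, params.n_nadh],
        # NADPH balance
        [0.0, 0.0, 2.0, 0.0, 0.0, -params.n_nadph],
        # Ru5P balance
        [0.0, 0.0, 1.0, 1.0, -1.0, 0.0],
        # ATP-coupled biomass
        [
            a.fermentation * params.y_atp,
            a.glycerol * params.y_atp,
            a.oxppp * params.y_atp,
            a.nonoxppp * params.y_atp,
            a.rubisco * params.y_atp,
            -1.0,
        ],
    ]
    b_eq = [HEXOSE_BASIS, 0.0, 0.0, 0.0, 0.0]
    cost = [-2.0, 0.0, 0.0, 0.0, -2.0, 0.0]  # maximize 2 v_f + 2 v_rub
    cap = None if math.isinf(capacity) else capacity
    bounds = [(0, None), (0, None), (0, None), (None, None), (0, cap), (0, None)]
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    assert res.status == 0, f"LP oracle failed: {res.message}"
    names = ["v_ferment", "v_glycerol", "v_oxppp", "v_nonoxppp", "v_rubisco", "v_biomass"]
    out = dict(zip(names, res.x))
    out["ethanol_out"] = -res.fun
    return out


def random_valid_params(rng: np.random.Generator) -> StoichParameters:
    """Draw a parameter set from physiologically plausible ranges."""
    return StoichParameters(
        n_nadh=rng.uniform(0.10, 0.35),
        n_nadph=rng.uniform(0.20, 0.90),
        n_co2_biomass=rng.uniform(0.05, 0.20),
        y_atp=rng.uniform(0.30, 0.55),
    )
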