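"""Exception hierarchy."""


class RubifluxError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleScenarioError(RubifluxError):
    """The balance equations admit no non-negative flux distribution.

    The message names the violated balance (carbon, NADH, NADPH, ATP) or
    non-negativity constraint instead of silently clipping fluxes.
    """

    def __init__(self, balance: str, detail: str = ""):
        self.balance = balance
        msg = f"scenario infeasible: {balance} balance cannot be closed"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class CalibrationError(RubifluxError):
    """Target yields are internally inconsistent (carbon recovery off)."""


class SchemaError(RubifluxError):
    """A delimited input table violates the documented schema."""


class GrowthFitError(RubifluxError):
    """No contiguous log-linear window meets the fit criterion."""
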