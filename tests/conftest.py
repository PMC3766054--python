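import pytest
from hypothesis import HealthCheck, settings

from rubiflux import StoichParameters, YieldSet, calibrate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> StoichParameters:
    return StoichParameters()


@pytest.fixture(scope="session")
def reference_yields() -> YieldSet:
    """Benchmark reference-strain chemostat yields (N2-sparged)."""
    return YieldSet(y_biomass=0.083, y_ethanol=1.56, y_glycerol=0.14)


@pytest.fixture(scope="session")
def calibrated_params(reference_yields) -> StoichParameters:
    """Parameters calibrated at run time to the reference steady state."""
    return calibrate(StoichParameters(), reference_yields)
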