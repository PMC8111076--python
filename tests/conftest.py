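import numpy as np
import pytest

from nsclc_cea.synthetic import (
    ArmSpec,
    CostInputs,
    GeneratorSpec,
    calibrate_drug_price,
    simulate_trial,
)


@pytest.fixture(scope="session")
def exp_trial():
    """Synthetic trial with exponential PFS (rate 0.10/month), n=200, 24-month cut-off."""
    spec = GeneratorSpec(
        arms=(ArmSpec("arm_a", 200, "exponential", {"rate": 0.10}),),
        admin_censor=24.0,
        seed=42,
    )
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def calibrated_inputs():
    """Synthetic cost config with the treatment drug price solved so that the
    high-PD-L1 base-case incremental cost equals the published $112,744.35."""
    return calibrate_drug_price(CostInputs(), "high", 112744.35)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
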