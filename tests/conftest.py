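import numpy as np
import pytest

from marzic.core import ModelParams, OutcomeParams, ZIBParams
from marzic.simulate import Setting1Config, simulate_setting1, table1_params


@pytest.fixture(scope="session")
def low_ra_params() -> ModelParams:
    """Generating truth of the rare-taxon scenario (printed parameter set)."""
    return table1_params("low")


@pytest.fixture(scope="session")
def high_ra_params() -> ModelParams:
    return table1_params("high")


@pytest.fixture(scope="session")
def uniform_zib_params() -> ModelParams:
    """All outcome coefficients zero; mediator Beta(1,1) with 20% zero mass."""
    return ModelParams(
        outcome=OutcomeParams(0, 0, 0, 0, 0, 0, delta=1.0),
        mediator=ZIBParams(alpha0=0.0, alpha1=0.0, phi=2.0,
                           gamma0=float(np.log(0.25)), gamma1=0.0),
    )


@pytest.fixture(scope="session")
def small_low_ra_dataset(low_ra_params):
    """One simulated rare-taxon dataset (n=200) with LOD false zeros."""
    data, truth, true_effects = simulate_setting1(
        Setting1Config(n=200, seed=7, params=low_ra_params))
    return data, truth, true_effects
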