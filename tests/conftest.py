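import numpy as np
import pytest

from sbmcircuit.synth import SBMSpec, generate_sbm_strengths

from _util import planted_block_probabilities


@pytest.fixture(scope="session")
def two_block_dataset():
    """Well-separated 2-block SBM, n=400."""
    spec = SBMSpec(
        n=400,
        kappa=2,
        rho=(0.5, 0.5),
        P=planted_block_probabilities(2, 0.3, 0.02),
        strength_mean=5.0,
        seed=11,
    )
    return generate_sbm_strengths(spec)


@pytest.fixture(scope="session")
def three_block_dataset():
    """Clean 3-block SBM, n=300, used for fast end-to-end runs."""
    spec = SBMSpec(
        n=300,
        kappa=3,
        rho=(1 / 3, 1 / 3, 1 / 3),
        P=planted_block_probabilities(3, 0.4, 0.03),
        strength_mean=6.0,
        seed=5,
    )
    return generate_sbm_strengths(spec)
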