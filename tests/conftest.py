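import numpy as np
import pytest

from patchbleed.phantom import PhantomParams, generate_case, generate_cohort


@pytest.fixture(scope="session")
def case():
    """Default phantom subject: 5 microbleeds, 3 vessels, noise on."""
    return generate_case(PhantomParams(seed=7), subject_id="sub-fix")


@pytest.fixture(scope="session")
def noiseless_case():
    """Noise-free, vessel-free subject for exactness checks."""
    return generate_case(
        PhantomParams(seed=11, noise_sd=0.0, n_vessels=0, partial_volume_mm=0.0),
        subject_id="sub-clean",
    )


@pytest.fixture(scope="session")
def cohort():
    """Small cohort for split/sampling tests."""
    return generate_cohort(6, seed=5)
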