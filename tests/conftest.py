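import numpy as np
import pytest

from fundusquant.synthetic import CohortSpec, GroundTruthFundus, generate_cohort, render_fundus


@pytest.fixture(scope="session")
def default_render():
    """One rendered synthetic fundus with landmarks and expected features."""
    truth = GroundTruthFundus(seed=11)
    image, landmarks, expected = render_fundus(truth)
    return truth, image, landmarks, expected


@pytest.fixture(scope="session")
def small_cohort():
    """A small labelled synthetic cohort for fast end-to-end runs."""
    return generate_cohort(CohortSpec(n=60, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
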