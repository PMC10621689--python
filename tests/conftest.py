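import numpy as np
import pytest

import tirtsim as ts


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def small_design(rng):
    """5-trait equally keyed questionnaire with the standard 9 blocks/trait."""
    return ts.make_design(5, "equal", "high_uniform", rng)


@pytest.fixture
def mixed_design(rng):
    return ts.make_design(5, "mixed", "realistic_truncnorm", rng)


@pytest.fixture
def pair_micro_model():
    """1-person, 2-trait micro model with pair blocks and known item
    parameters — small enough for exact grid-quadrature integration."""
    design = ts.QuestionnaireDesign(
        n_traits=2,
        trait_of_item=np.array([0, 1, 0, 1, 0, 1]),
        loadings=np.array([0.8, 0.7, 0.6, 0.75, 0.85, 0.65]),
        item_means=np.array([0.2, -0.1, 0.0, 0.3, -0.25, 0.1]),
        blocks=np.array([[0, 1], [2, 3], [4, 5]]),
        keying="equal",
    )
    phi = np.array([[1.0, 0.3], [0.3, 1.0]])
    eta = np.array([[1.2, -0.6]])
    rng = np.random.default_rng(99)
    responses = ts.simulate_responses(design, ts.PersonSample(eta), rng)
    return design, phi, responses
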