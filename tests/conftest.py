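import numpy as np
import pytest

from cvdcea.risk import STATES, TransitionMatrix, validate_matrix

#: the published annual counterfactual matrix for males without diabetes,
#: exactly as printed (healthy and stroke rows do not sum to 1)
PRINTED_MATRIX = np.array(
    [
        [0.9057, 0.0070, 0.0090, 0.0100, 0.0198],
        [0.0000, 0.4053, 0.0392, 0.0488, 0.1813],
        [0.0000, 0.0000, 0.5078, 0.1230, 0.3691],
        [0.0000, 0.0000, 0.0000, 0.4873, 0.5127],
        [0.0000, 0.0000, 0.0000, 0.0000, 1.0000],
    ]
)


@pytest.fixture
def printed_matrix() -> TransitionMatrix:
    return TransitionMatrix(PRINTED_MATRIX.copy())


def random_valid_matrix(rng: np.random.Generator) -> TransitionMatrix:
    """A random validated 5-state matrix respecting the structural mask."""
    probs = np.zeros((5, 5))
    # healthy row: Dirichlet over stay + 4 events
    probs[0] = rng.dirichlet(np.ones(5) * rng.uniform(0.5, 5.0))
    # stroke row: stay, -> mi, chf, death
    s = rng.dirichlet(np.ones(4))
    probs[1, 1:5] = s
    # mi row: stay, chf, death
    m = rng.dirichlet(np.ones(3))
    probs[2, 2:5] = m
    # chf row: stay, death
    c = rng.dirichlet(np.ones(2))
    probs[3, 3:5] = c
    probs[4, 4] = 1.0
    validated, _ = validate_matrix(TransitionMatrix(probs), policy="error")
    return validated


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
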