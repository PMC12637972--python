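import numpy as np
import pytest

from stemcomp import CostMatrix

# The benchmark matrices exercised throughout: neutral, the two
# frequency-independent dominance cases, and the frequency-dependent sets.
NEUTRAL = CostMatrix(1.0, 1.0, 1.0, 1.0)
DAMAGED_DOMINANT = CostMatrix(1.0, 1.0, 0.8, 0.8)
INTACT_DOMINANT = CostMatrix(1.0, 1.0, 1.25, 1.25)
GREEN = CostMatrix(1.0, 1.5, 1.16, 0.8)          # positive frequency dependence
HAWK_DOVE = CostMatrix(1.0, 0.25, 0.5, 0.75)     # negative frequency dependence
CONVEX_E = CostMatrix(1.0, 1.5, 1.2, 0.5)
LATTICE_E = CostMatrix(1.0, 1.75, 1.25, 0.5)


@pytest.fixture
def neutral_cm():
    return NEUTRAL


@pytest.fixture
def green_cm():
    return GREEN


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_cost_matrix(rng: np.random.Generator, low: float = 0.05, high: float = 3.0) -> CostMatrix:
    return CostMatrix(*np.exp(rng.uniform(np.log(low), np.log(high), size=4)))
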