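import numpy as np
import pytest

from farmsustain.ahp import PairwiseMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def dimension_matrix():
    """The three-dimension comparison matrix used in the worked example."""
    return PairwiseMatrix(
        np.array([[1.0, 2.0, 2.0], [0.5, 1.0, 2.0], [0.5, 0.5, 1.0]]),
        labels=("economic", "environmental", "social"),
    )


def random_dea_instance(rng, n_farms, n_inputs):
    """Small random DEA instance with positive inputs and outputs."""
    x = np.exp(rng.normal(0.0, 0.6, size=(n_farms, n_inputs)))
    y = np.exp(rng.normal(0.0, 0.5, size=n_farms))
    return x, y
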