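import numpy as np
import pytest

import matplotlib

matplotlib.use("Agg")

from ggminfer import DataMatrix, PrecisionModel, fig2_model, sample_gaussian


@pytest.fixture(scope="session")
def fig2():
    return fig2_model()


@pytest.fixture(scope="session")
def fig2_data(fig2):
    """One n=500 draw from the nine-edge model."""
    return sample_gaussian(fig2, n=500, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pd_precision(p, rng, density=0.4):
    """Random sparse PD precision matrix via diagonal dominance."""
    upper = np.triu((rng.random((p, p)) < density) * rng.uniform(-0.6, 0.6, (p, p)), 1)
    theta = upper + upper.T
    theta += np.eye(p) * (np.abs(theta).sum(axis=1).max() + 0.5)
    return theta


@pytest.fixture()
def small_data(rng):
    """Well-conditioned 60 x 5 Gaussian data."""
    theta = random_pd_precision(5, rng)
    model = PrecisionModel(theta)
    return model, sample_gaussian(model, 60, seed=rng)
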