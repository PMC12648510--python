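import numpy as np
import pytest

from expvol.filter_core import GaussianBelief


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_spd(rng, d, scale=1.0):
    """Random well-conditioned SPD matrix."""
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))


def random_belief(rng, d, scale=1.0):
    return GaussianBelief.from_moments(rng.standard_normal(d), random_spd(rng, d, scale))
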