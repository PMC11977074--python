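import numpy as np
import pytest

from likertcomp import ScaleSystem, enumerate_possible_means


@pytest.fixture(scope="session")
def k5p05():
    """The worked-example scale system: K=5 categories, LOQ p=0.05."""
    return ScaleSystem.create(5, 0.05)


@pytest.fixture(scope="session")
def k5p05_spms(k5p05):
    """Possible-means sets for I=2 items on the ilr and star scales."""
    return (
        enumerate_possible_means(k5p05.ilr_values, 2, scale_tag="ILR"),
        enumerate_possible_means(k5p05.star.values, 2, scale_tag="RS*"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
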