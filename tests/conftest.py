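import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(rng, n_pops=4, n_per_pop=6, n_loci=20, two_regions=True):
    """Random binary matrix with a 2-regions x pops x individuals design."""
    from isopop import AFLPMatrix

    X = rng.integers(0, 2, (n_pops * n_per_pop, n_loci)).astype(np.int8)
    pops = [f"P{i + 1}" for i in range(n_pops) for _ in range(n_per_pop)]
    half = n_pops // 2 if two_regions else n_pops
    region_of = {
        f"P{i + 1}": ("R1" if i < half else "R2") if two_regions else "R1"
        for i in range(n_pops)
    }
    return AFLPMatrix(
        X,
        [f"s{i}" for i in range(X.shape[0])],
        pops,
        region_of,
        [f"L{j + 1}" for j in range(n_loci)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng)


@pytest.fixture(scope="session")
def survey_traits():
    from isopop.datasets import load_cheddar_pink_traits

    return load_cheddar_pink_traits()
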