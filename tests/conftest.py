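import numpy as np
import pytest

from asclust import FamilySpec, default_distance_matrix, generate_family


@pytest.fixture(scope="session")
def dmat():
    return default_distance_matrix()


@pytest.fixture(scope="session")
def small_family():
    """A compact planted family: 3 groups x 12 members, site length 8."""
    return generate_family(
        FamilySpec(seed=7, n_groups=3, members_per_group=12, site_length=8,
                   full_sequence_length=60, p_noise=0.05, p_gap=0.02)
    )


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free family: extracted sites must equal the group signatures."""
    return generate_family(
        FamilySpec(seed=3, n_groups=3, members_per_group=6, site_length=8,
                   full_sequence_length=48, p_noise=0.0, p_gap=0.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


def random_score_matrix(rng, n):
    """A valid random precomputed-distance matrix in [0,1]."""
    from asclust import ScoreMatrix

    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return ScoreMatrix(tuple(f"m{i}" for i in range(n)), v)
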