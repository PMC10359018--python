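import numpy as np
import pytest

from seqmut import MutationPath, fitness_profile


@pytest.fixture
def fig1_path():
    """Three-type path with a deleterious then strongly advantageous step
    (net growth rates 0.3, 0.1, 0.6)."""
    return MutationPath(alpha=(1.1, 1.0, 1.1), beta=(0.8, 0.9, 0.5),
                        nu=(0.01, 0.01, 0.0))


@pytest.fixture
def mixed_path():
    """Down-up fitness sequence (0.7, 1.1, -0.5) with nu = 0.01: the
    arrival-law validation setting."""
    return MutationPath(alpha=(1.0, 1.4, 1.0), beta=(0.3, 0.3, 1.5),
                        nu=(0.01, 0.01, 0.0))


def two_type_sim(alpha2: float) -> MutationPath:
    """Two-type family used for the amplitude-law simulations: common
    alpha_1=1.2, beta_1=0.2, nu_1=0.01, beta_2=0.3 and a varying alpha_2."""
    return MutationPath(alpha=(1.2, alpha2), beta=(0.2, 0.3), nu=(0.01, 0.0))


@pytest.fixture
def sim3_path():
    """alpha_2 = 1.0 (tail parameter 1.0; observation time 12)."""
    return two_type_sim(1.0)


@pytest.fixture
def sim2_path():
    """alpha_2 = 2.3 (tail parameter 0.5; observation time 7)."""
    return two_type_sim(2.3)


def neutral_assay_path(nu: float, n_types: int = 3) -> MutationPath:
    """Neutral no-death path for fluctuation assays (alpha_i = 1)."""
    return MutationPath([1.0] * n_types, [0.0] * n_types,
                        [nu] * (n_types - 1) + [0.0])


def random_valid_path(rng: np.random.Generator, max_types: int = 5):
    """A random valid path: supercritical type 1, arbitrary later fitness
    (ties forced with probability 0.3), small mutation rates."""
    n = int(rng.integers(2, max_types + 1))
    lam = rng.uniform(-1.0, 2.0, n)
    lam[0] = rng.uniform(0.2, 2.0)
    for i in range(1, n):
        if rng.random() < 0.3:
            lam[i] = max(lam[:i])
    alpha = np.abs(lam) + rng.uniform(0.1, 2.0, n)
    beta = alpha - lam
    nu = 10.0 ** rng.uniform(-6.0, -1.5, n)
    return MutationPath(alpha, beta, nu)
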