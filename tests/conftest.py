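import numpy as np
import pytest

from algsst import ALGParams, ExGParams, SSTConfig

# Group-mean cluster Ex-Gaussian components of the motivating dataset
THETA_A = ExGParams(478.8, 109.9, 104.2)
THETA_B = ExGParams(532.8, 133.1, 142.4)
ALG_GROUP = ALGParams(104.2, 142.4, 53.9, 172.6)


@pytest.fixture
def theta_a():
    return THETA_A


@pytest.fixture
def theta_b():
    return THETA_B


@pytest.fixture
def alg_group():
    return ALG_GROUP


@pytest.fixture
def default_config():
    return SSTConfig()


def random_alg_params(rng: np.random.Generator, n: int,
                      tail_safe: bool = False) -> list[ALGParams]:
    """Random RT-scale ALG parameter sets.

    ``tail_safe`` restricts sigma/alpha2 so the exponential tail already
    dominates by mean + 6 sd, which the tail-slope check requires.
    """
    out = []
    for _ in range(n):
        if tail_safe:
            a1 = rng.uniform(60, 200)
            a2 = rng.uniform(60, 200)
            sigma = rng.uniform(40, 250)
        else:
            a1 = rng.uniform(20, 300)
            a2 = rng.uniform(20, 300)
            sigma = rng.uniform(20, 300)
        out.append(ALGParams(a1, a2, rng.uniform(-100, 100), sigma))
    return out


def random_exg_params(rng: np.random.Generator, n: int) -> list[ExGParams]:
    return [ExGParams(rng.uniform(300, 700), rng.uniform(40, 200),
                      rng.uniform(40, 250)) for _ in range(n)]
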