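import numpy as np
import pytest

from effcomm import inverse_planner as ip
from effcomm import path_space as ps


@pytest.fixture(scope="session")
def study1():
    return ps.build_study1_set(seed=11)


@pytest.fixture(scope="session")
def study2():
    return ps.build_study2_set()


@pytest.fixture(scope="session")
def model_config():
    return ip.ModelConfig()


def random_spec(rng: np.random.Generator, n_min: int = 1, n_max: int = 6) -> ps.PathSpec:
    n = int(rng.integers(n_min, n_max + 1))
    return ps.PathSpec(tuple(int(i) for i in rng.integers(0, 16, size=n)))
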