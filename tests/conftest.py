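import numpy as np
import pytest

from virotime import synth


def coupled_logistic(seed: int, n: int = 400, coupling: float = 0.32,
                     r_x: float = 3.8, r_y: float = 3.5):
    """Unidirectionally coupled logistic maps: x drives y."""
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(0.2, 0.8, 2)
    xs, ys = [], []
    for _ in range(n + 100):
        x = x * (r_x - r_x * x)
        y = y * (r_y - r_y * y - coupling * x)
        xs.append(x)
        ys.append(y)
    return np.array(xs[100:]), np.array(ys[100:])


@pytest.fixture(scope="session")
def quiet_env():
    """Noise-free four-year monthly environment."""
    cfg = synth.EnvironmentConfig().scale_noise(0.0)
    return synth.gen_environment(48, 30.5, seed=0, config=cfg)


@pytest.fixture(scope="session")
def env48():
    return synth.gen_environment(48, 30.5, seed=3)


@pytest.fixture(scope="session")
def community(env48):
    """Default 4-guild community at the study's size (40 hosts, 120 viruses)."""
    return synth.gen_community(env48, 40, 120, 4, seed=4)


@pytest.fixture(scope="session")
def observed(community):
    """(coverage table, marker table, per-sample Gbp) for the community."""
    return synth.gen_coverage(community, seed=5)
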