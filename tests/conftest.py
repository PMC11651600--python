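import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ergmselect import Graph, generate_bernoulli

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_graph(rng, n_min=3, n_max=10, p=None):
    """A random Bernoulli graph with size and density drawn from rng."""
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.1, 0.9)) if p is None else p
    return generate_bernoulli(n, p, seed=int(rng.integers(1 << 30)))


def attrs_for(g, rng):
    """A numeric node-attribute table matching g's labels."""
    return pd.DataFrame(
        {"w": rng.normal(size=g.n_nodes), "z": rng.uniform(size=g.n_nodes)},
        index=[str(lab) for lab in g.node_labels],
    )


@pytest.fixture
def triangle_graph():
    return Graph(3, {(0, 1), (0, 2), (1, 2)})


@pytest.fixture
def florentine():
    from ergmselect import load_classic

    return load_classic("florentine_marriage")
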