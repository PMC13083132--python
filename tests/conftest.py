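import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cereconn as cc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_atlas() -> cc.AtlasMap:
    """Six-network atlas with 19 ROIs, small enough for hand checks."""
    return cc.make_atlas({"DMN": 4, "FP": 2, "CO": 3, "SM": 3, "OCC": 2, "CER": 5})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_graph(
    n: int, rng: np.random.Generator, density: float = 0.4
) -> cc.ConnectomeGraph:
    """Random sparse symmetric graph with signed weights and zero diagonal."""
    w = rng.standard_normal((n, n))
    w = (w + w.T) / 2
    mask = rng.random((n, n)) < density
    mask = np.triu(mask, 1)
    w = np.where(mask | mask.T, w, 0.0)
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices(n, 1)
    retained = np.count_nonzero(w[iu]) / iu[0].size
    return cc.ConnectomeGraph("s", "CON", "1-back", w, retained)
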