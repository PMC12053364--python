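import numpy as np
import pytest

from rhizoflow.architecture import RootSystem
from rhizoflow.hydraulics import HydraulicParams, PiecewiseLinearFunction


def random_tree(rng: np.random.Generator, n_segments: int = 30) -> RootSystem:
    """Random topologically ordered segment tree for solver tests."""
    parent = np.empty(n_segments, dtype=np.int64)
    root_id = np.zeros(n_segments, dtype=np.int64)
    type_code = rng.integers(0, 3, n_segments)
    length = rng.uniform(0.005, 0.05, n_segments)
    radius = rng.uniform(1e-4, 4e-4, n_segments)
    creation = np.sort(rng.uniform(0.0, 30.0, n_segments))
    for i in range(n_segments):
        if i == 0 or rng.uniform() < 0.1:
            parent[i] = -1
        else:
            parent[i] = rng.integers(0, i)
    return RootSystem(parent, root_id, type_code, length, radius, creation,
                      simulation_time=40.0)


def random_hydraulics(rng: np.random.Generator) -> HydraulicParams:
    P = PiecewiseLinearFunction.from_knots

    def pl(scale):
        ages = np.sort(rng.uniform(0, 50, 3))
        ages[0] = 0.0
        vals = rng.uniform(0.3, 3.0, 3) * scale
        return P(zip(ages, vals))

    return HydraulicParams(
        kr_by_type={t: pl(1e-7) for t in ("seminal", "crown", "lateral")},
        kx_by_type={t: pl(2e-12) for t in ("seminal", "crown", "lateral")},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
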