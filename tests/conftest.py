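import numpy as np
import pytest

import tissuegraph as tg


@pytest.fixture(scope="session")
def small_cohort():
    """A small arrangement-signal cohort shared by read-only tests."""
    cfg = tg.SimConfig(n_patients=10, images_per_patient=2, cells_per_image=150,
                       signal=tg.SignalConfig(channel="arrangement", strength=1.0))
    return tg.simulate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def tiny_graph():
    """A deterministic 10-node spatial graph with one-hot type features."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 100, size=(10, 2))
    A = tg.build_radius_graph(coords, 45.0)
    types = np.array(["a", "b", "a", "c", "b", "a", "c", "b", "a", "c"], dtype=object)
    X = np.zeros((10, 3))
    X[np.arange(10), [{"a": 0, "b": 1, "c": 2}[t] for t in types]] = 1.0
    return tg.SpatialGraph(A, X, cell_type=types,
                           immune_flag=np.array([t == "a" for t in types]))
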