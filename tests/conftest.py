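import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netimg.graph_io import PPIGraph
from netimg.synth import SynthConfig, make_cohort, make_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    """P3: A - B - C."""
    g = PPIGraph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def random_connected_graph(rng):
    """30-node connected Erdos-Renyi graph with string labels."""
    while True:
        g = nx.gnp_random_graph(30, 0.15, seed=4242)
        if nx.is_connected(g):
            break
    out = PPIGraph()
    out.add_edges_from((f"n{u:02d}", f"n{v:02d}") for u, v in g.edges)
    return out


@pytest.fixture(scope="session")
def toy_cohort():
    """Small 3-class synthetic cohort with planted signatures."""
    cfg = SynthConfig(seed=7)
    return cfg, make_graph(cfg), make_cohort(cfg)


@pytest.fixture
def toy_metadata():
    """Two cancers with enough samples for the 3:1 split rule."""
    rows = []
    for cancer, n_norm, n_tum in (("CA", 4, 20), ("CB", 5, 30)):
        for i in range(n_norm):
            rows.append({"sample_id": f"{cancer}_n{i}", "cancer": cancer, "status": "normal"})
        for i in range(n_tum):
            rows.append({"sample_id": f"{cancer}_t{i}", "cancer": cancer, "status": "tumor"})
    return pd.DataFrame(rows)
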