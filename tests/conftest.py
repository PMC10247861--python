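import networkx as nx
import numpy as np
import pytest


def random_connected_graph(rng: np.random.Generator, n_min: int = 3, n_max: int = 15) -> nx.Graph:
    """Uniform-ish random connected graph via G(n, p) rejection sampling."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.25, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


def simulate_meeting_times(g: nx.Graph, i: int, j: int, replicates: int, seed: int) -> np.ndarray:
    """Monte-Carlo coalescing random walk: per step one of the two walkers moves
    (chosen with probability 1/2) to a uniform neighbor; returns meeting times.

    Independent simulation oracle for the coalescence linear system.
    """
    rng = np.random.default_rng(seed)
    nbrs = {v: list(g.neighbors(v)) for v in g.nodes()}
    times = np.empty(replicates)
    for rep in range(replicates):
        a, b, t = i, j, 0
        while a != b:
            t += 1
            if rng.random() < 0.5:
                a = nbrs[a][rng.integers(len(nbrs[a]))]
            else:
                b = nbrs[b][rng.integers(len(nbrs[b]))]
        times[rep] = t
    return times


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
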