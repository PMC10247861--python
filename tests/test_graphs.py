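import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transamp.bellgraphs import BellFamilySpec, make_bell
from transamp.graphs import (
    canonical_key,
    complement,
    cospectral_key,
    cycle_partitions,
    degrees,
    enumerate_regular_graphs,
    is_connected,
    read_graph6,
    regulars_from_cycle_partitions,
    remove_edge,
    write_graph6,
)


def _random_graph(seed: int) -> nx.Graph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 10))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)), seed=seed)
    return g


class TestDegrees:
    @pytest.mark.parametrize(
        "g, expect, mean",
        [
            (nx.complete_graph(4), (3, 3, 3, 3), 3.0),
            (nx.path_graph(3), (1, 2, 1), 4 / 3),
        ],
    )
    def test_small_graphs(self, g, expect, mean):
        d = degrees(g)
        assert d.degrees == expect
        assert d.mean == pytest.approx(mean)

    def test_barbell_extremes(self):
        d = degrees(make_bell(BellFamilySpec("barbell", 8, 3)))
        assert (d.max, d.min) == (8, 2)
        assert sum(d.degrees) == 2 * make_bell(BellFamilySpec("barbell", 8, 3)).number_of_edges()


def test_is_connected():
    assert is_connected(nx.complete_graph(4))
    assert not is_connected(nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3)))
    g = remove_edge(nx.complete_graph(4), 0, 1)
    assert is_connected(g)


def test_remove_edge():
    p3 = remove_edge(nx.complete_graph(3), 0, 1)
    assert sorted(d for _, d in p3.degree()) == [1, 1, 2]
    c4 = remove_edge(nx.cycle_graph(4), 0, 1)
    assert nx.is_isomorphic(c4, nx.path_graph(4))
    assert sorted(d for _, d in remove_edge(nx.complete_graph(4), 0, 1).degree()) == [2, 2, 3, 3]
    with pytest.raises(ValueError, match="not present"):
        remove_edge(nx.path_graph(3), 0, 2)


class TestComplement:
    def test_known_complements(self):
        assert complement(nx.complete_graph(5)).number_of_edges() == 0
        c5 = nx.cycle_graph(5)
        assert nx.is_isomorphic(complement(c5), c5)  # self-complementary
        two_reg = nx.cycle_graph(11)
        assert all(d == 8 for _, d in complement(two_reg).degree())

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_involution(self, seed):
        g = _random_graph(seed)
        gg = complement(complement(g))
        assert set(gg.nodes()) == set(g.nodes())
        assert set(map(frozenset, gg.edges())) == set(map(frozenset, g.edges()))


class TestCyclePartitionComplements:
    @pytest.mark.parametrize("n, count", [(11, 6), (12, 9), (14, 13)])
    def test_counts(self, n, count):
        graphs = regulars_from_cycle_partitions(n)
        assert len(graphs) == count

    def test_partitions_of_11(self):
        assert sorted(cycle_partitions(11)) == [
            (3, 3, 5), (3, 4, 4), (3, 8), (4, 7), (5, 6), (11,)
        ]

    def test_regular_connected_nonisomorphic(self):
        graphs = regulars_from_cycle_partitions(12)
        keys = set()
        for g in graphs:
            assert all(d == 9 for _, d in g.degree())
            assert nx.is_connected(g)
            keys.add(canonical_key(g))
        assert len(keys) == len(graphs)

    def test_too_small(self):
        with pytest.raises(ValueError):
            regulars_from_cycle_partitions(5)


def test_enumerate_cubic_counts():
    # connected cubic graphs: 1 on 4 vertices, 2 on 6, 5 on 8
    assert [len(enumerate_regular_graphs(n, 3)) for n in (4, 6, 8)] == [1, 2, 5]


class TestKeys:
    def test_canonical_detects_isomorphism(self, rng):
        c5 = nx.cycle_graph(5)
        relabeled = nx.relabel_nodes(c5, dict(zip(range(5), rng.permutation(5).tolist())))
        assert canonical_key(c5) == canonical_key(relabeled)
        assert canonical_key(nx.cycle_graph(6)) != canonical_key(
            nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        )

    def test_cospectral_key(self, rng):
        b = make_bell(BellFamilySpec("barbell", 4, 5))
        relabeled = nx.relabel_nodes(
            b, dict(zip(sorted(b.nodes()), rng.permutation(b.number_of_nodes()).tolist()))
        )
        assert cospectral_key(b) == cospectral_key(relabeled)
        assert cospectral_key(nx.complete_graph(4)) != cospectral_key(nx.cycle_graph(4))
        assert cospectral_key(b) == cospectral_key(b)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_isomorphic_implies_cospectral(self, seed):
        g = _random_graph(seed)
        if any(d == 0 for _, d in g.degree()):
            return
        perm = np.random.default_rng(seed).permutation(g.number_of_nodes()).tolist()
        h = nx.relabel_nodes(g, dict(zip(sorted(g.nodes()), perm)))
        assert canonical_key(g) == canonical_key(h)
        assert cospectral_key(g) == cospectral_key(h)


class TestGraph6IO:
    def test_roundtrip(self, tmp_path):
        graphs = [nx.complete_graph(5), nx.petersen_graph(), nx.path_graph(2)]
        path = tmp_path / "set.g6"
        write_graph6(graphs, path)
        back = read_graph6(path)
        assert len(back) == 3
        for g, h in zip(graphs, back):
            assert nx.to_numpy_array(g).tolist() == nx.to_numpy_array(h).tolist()

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.g6"
        path.write_bytes(b"")
        assert read_graph6(path) == []

    def test_corrupt_line_reported(self, tmp_path):
        path = tmp_path / "bad.g6"
        path.write_bytes(nx.to_graph6_bytes(nx.complete_graph(3), header=False) + b"\x01\xff\n")
        with pytest.raises(ValueError, match="line 2"):
            read_graph6(path)
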