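import networkx as nx
import numpy as np
import pytest

from conftest import random_connected_graph
from transamp.spectral import (
    default_sigma,
    density_distance,
    ensemble_density,
    interlacing_check,
    laplacians,
    spectral_density,
    spectral_distance,
    spectral_summary,
)


class TestSpectra:
    def test_k2_closed_form(self):
        s = spectral_summary(nx.complete_graph(2))
        assert s.mu.tolist() == pytest.approx([0.0, 2.0], abs=1e-12)
        assert s.lam.tolist() == pytest.approx([0.0, 2.0], abs=1e-12)

    def test_c4_circulant_closed_form(self):
        s = spectral_summary(nx.cycle_graph(4))
        assert sorted(s.mu.tolist()) == pytest.approx([0, 2, 2, 4], abs=1e-9)

    def test_c12_lambda2(self):
        s = spectral_summary(nx.cycle_graph(12))
        assert s.lam2 == pytest.approx(1 - np.cos(2 * np.pi / 12), abs=1e-9)

    def test_complete_graph_mu2(self):
        assert spectral_summary(nx.complete_graph(7)).mu2 == pytest.approx(7.0, abs=1e-9)

    def test_regular_spectra_scale(self, rng):
        # for k-regular graphs Lambda = I - A/k, hence mu_i = k * lambda_i
        for g in (nx.cycle_graph(9), nx.petersen_graph(), nx.circulant_graph(11, [1, 2])):
            k = g.degree(0)
            s = spectral_summary(g)
            assert np.max(np.abs(s.mu - k * s.lam)) < 1e-9

    def test_trace_identities(self, rng):
        for _ in range(20):
            g = random_connected_graph(rng, n_max=12)
            s = spectral_summary(g)
            assert s.mu.sum() == pytest.approx(2 * g.number_of_edges(), abs=1e-9)
            assert s.lam.sum() == pytest.approx(g.number_of_nodes(), abs=1e-9)
            assert s.lam[-1] <= 2 + 1e-9
            assert s.lam2 > 0  # connected

    def test_disconnected_has_zero_lambda2(self):
        g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(4))
        assert spectral_summary(g).lam2 == pytest.approx(0.0, abs=1e-9)

    def test_isolated_vertex_rejected(self):
        g = nx.path_graph(3)
        g.add_node(7)
        with pytest.raises(ValueError):
            laplacians(g)


class TestInterlacing:
    def test_random_edge_removals(self, rng):
        for _ in range(40):
            g = random_connected_graph(rng, n_min=4, n_max=8)
            edges = list(g.edges())
            e = edges[rng.integers(len(edges))]
            h = g.copy()
            h.remove_edge(*e)
            if any(d == 0 for _, d in h.degree()):
                continue
            std_ok, norm_ok = interlacing_check(g, e)
            assert std_ok and norm_ok

    def test_k3_example(self):
        # mu(K3) = {0,3,3}, mu(P3) = {0,1,3}
        s = spectral_summary(nx.path_graph(3))
        assert sorted(s.mu.tolist()) == pytest.approx([0, 1, 3], abs=1e-9)
        assert interlacing_check(nx.complete_graph(3), (0, 1)) == (True, True)

    def test_missing_edge_rejected(self):
        with pytest.raises(ValueError):
            interlacing_check(nx.path_graph(3), (0, 2))


class TestDensity:
    def test_unit_mass(self):
        wide = np.linspace(-30, 30, 40001)
        d = spectral_density([1.0], sigma=0.1, grid=wide)
        assert np.trapezoid(d.values, d.grid) == pytest.approx(1.0, abs=1e-9)
        d5 = spectral_density([0.0, 0.5, 1.0, 1.5, 2.0], sigma=0.05, grid=wide)
        assert np.trapezoid(d5.values, d5.grid) == pytest.approx(1.0, abs=1e-9)

    def test_default_sigma(self):
        d = spectral_density(np.zeros(10))
        assert d.sigma == pytest.approx(default_sigma(10))

    def test_multiplicity_peak_ratio(self):
        # at an eigenvalue of multiplicity m the peak approaches m / (single peak)
        for sigma in (0.05, 0.01, 0.002):
            x = np.array([0.5, 1.5])
            single = spectral_density([0.5, 1.5], sigma=sigma, grid=x)
            double = spectral_density([0.5, 0.5, 0.5, 1.5], sigma=sigma, grid=x)
            # densities are normalized by N; compare per-eigenvalue peak mass
            ratio = (4 * double.values[0]) / (2 * single.values[0])
            assert ratio == pytest.approx(3.0, abs=0.05 if sigma < 0.01 else 0.5)

    def test_pseudometric_axioms(self, rng):
        graphs = [random_connected_graph(rng, n_max=9) for _ in range(3)]
        for g in graphs:
            assert spectral_distance(g, g) == pytest.approx(0.0, abs=1e-12)
        d01 = spectral_distance(graphs[0], graphs[1])
        d10 = spectral_distance(graphs[1], graphs[0])
        d02 = spectral_distance(graphs[0], graphs[2])
        d12 = spectral_distance(graphs[1], graphs[2])
        assert d01 == pytest.approx(d10, abs=1e-12)
        assert d01 >= 0
        assert d02 <= d01 + d12 + 1e-9

    def test_k4_c4_distinct(self):
        assert spectral_distance(nx.complete_graph(4), nx.cycle_graph(4)) > 0.1

    def test_standard_variant_grid(self):
        d = spectral_distance(nx.complete_graph(4), nx.cycle_graph(4), which="standard")
        assert d > 0


class TestEnsemble:
    def test_singleton_equals_density(self):
        g = nx.complete_graph(4)
        ens = ensemble_density([g])
        single = spectral_density(spectral_summary(g).lam)
        assert np.allclose(ens.values, single.values)

    def test_duplicates_no_effect(self):
        g = nx.cycle_graph(5)
        assert np.allclose(ensemble_density([g, g]).values, ensemble_density([g]).values)

    def test_pair_is_pointwise_mean(self):
        g1, g2 = nx.complete_graph(4), nx.cycle_graph(4)
        ens = ensemble_density([g1, g2])
        mean = 0.5 * (ensemble_density([g1]).values + ensemble_density([g2]).values)
        assert np.allclose(ens.values, mean)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_density([])
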