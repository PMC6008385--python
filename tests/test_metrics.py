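"""Graph-metric unit and property tests against independent oracles."""

import warnings

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from dmnet import (BinaryGraph, auc, binarize_at_sparsity,
                   clustering_coefficient, generate_benchmark_graph,
                   global_efficiency, largest_component_size,
                   local_efficiency, metric_curves, nodal_metrics,
                   path_length_harmonic, rewire_preserving_degree,
                   small_world_parameters)
from dmnet.metrics import (DEFAULT_GRID, edge_count_at_sparsity,
                           shortest_path_lengths, _rewire_ensemble)

import _bruteforce as bf


def random_graph(rng, n=None, p=None):
    n = n or int(rng.integers(4, 12))
    p = p or rng.uniform(0.15, 0.8)
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_edge_count_rounds_half_away_from_zero(self):
        # N=20: 0.05 * 190 = 9.5 -> 10 edges
        assert edge_count_at_sparsity(20, 0.05) == 10

    def test_sparsity_one_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        C = np.corrcoef(rng.standard_normal((30, 6)), rowvar=False)
        G = binarize_at_sparsity(C, 1.0)
        assert G.n_edges == 15
        assert (G.degrees() == 5).all()

    def test_keeps_strongest_edges(self):
        C = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3,
                (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            C[i, j] = C[j, i] = v
        G = binarize_at_sparsity(C, 1 / 3)  # K = round(2) = 2 edges
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4)
                if G.adjacency[i, j]}
        assert kept == {(0, 1), (0, 2)}

    def test_signed_ranking_prefers_positive_over_large_negative(self):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 0.1
        C[0, 2] = C[2, 0] = -0.9
        C[1, 2] = C[2, 1] = 0.05
        G = binarize_at_sparsity(C, 1 / 3)  # K = 1
        assert G.adjacency[0, 1] == 1 and G.adjacency[0, 2] == 0
        G_abs = binarize_at_sparsity(C, 1 / 3, rank="abs")
        assert G_abs.adjacency[0, 2] == 1

    def test_tie_break_is_lexicographic_and_deterministic(self):
        C = np.full((5, 5), 0.5)
        np.fill_diagonal(C, 0)
        G1 = binarize_at_sparsity(C, 0.3)
        G2 = binarize_at_sparsity(C, 0.3)
        assert np.array_equal(G1.adjacency, G2.adjacency)
        iu, ju = np.nonzero(np.triu(G1.adjacency, 1))
        pairs = sorted(zip(iu, ju))
        # K = round(0.3*10) = 3: first three pairs in (i, j) order
        assert pairs == [(0, 1), (0, 2), (0, 3)]

    def test_zero_edges_is_an_error(self):
        C = np.eye(3) * 0
        with pytest.raises(ValueError, match="zero edges"):
            binarize_at_sparsity(C, 0.01)


# ---------------------------------------------------------------------------
# closed-form fixtures
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_complete_graph_unit_metrics(self, complete4):
        A = complete4.adjacency
        _, cp = clustering_coefficient(A)
        assert cp == 1.0
        assert path_length_harmonic(A) == 1.0
        assert global_efficiency(A) == 1.0
        assert local_efficiency(A) == 1.0
        nm = nodal_metrics(complete4)
        assert (nm["betweenness"] == 0).all()
        assert (nm["efficiency"] == 1).all()

    def test_star_metrics(self, star4):
        A = star4.adjacency
        _, cp = clustering_coefficient(A)
        assert cp == 0.0
        assert path_length_harmonic(A) == pytest.approx(4 / 3, abs=1e-12)
        assert global_efficiency(A) == pytest.approx(0.75, abs=1e-12)
        assert local_efficiency(A) == 0.0
        nm = nodal_metrics(star4)
        assert nm.loc["0", "degree"] == 3
        assert nm.loc["0", "betweenness"] == pytest.approx(3.0)
        assert nm.loc["0", "efficiency"] == 1.0
        assert nm.loc["1", "efficiency"] == pytest.approx(2 / 3)

    def test_triangle_plus_pendant(self, triangle_pendant):
        Ci, cp = clustering_coefficient(triangle_pendant)
        assert np.allclose(Ci, [1 / 3, 1, 1, 0])
        assert cp == pytest.approx(7 / 12, abs=1e-12)
        assert local_efficiency(triangle_pendant) == pytest.approx(
            7 / 12, abs=1e-12)

    def test_two_disjoint_edges_handle_disconnection(self):
        G = generate_benchmark_graph("two_disjoint_edges")
        assert path_length_harmonic(G.adjacency) == pytest.approx(3.0)
        assert global_efficiency(G.adjacency) == pytest.approx(1 / 3)
        assert largest_component_size(G.adjacency) == 2

    def test_path_graph_betweenness(self):
        G = generate_benchmark_graph("path", n=4)
        nm = nodal_metrics(G)
        assert list(nm["betweenness"]) == [0, 2, 2, 0]

    def test_empty_graph_conventions(self):
        A = np.zeros((5, 5))
        assert global_efficiency(A) == 0.0
        assert largest_component_size(A) == 1
        with pytest.raises(ValueError):
            path_length_harmonic(A)


# ---------------------------------------------------------------------------
# oracle equivalence and invariants on random graphs
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_metrics_match_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 40:
            A = random_graph(rng)
            if A.sum() == 0:
                continue
            checked += 1
            D = shortest_path_lengths(A)
            assert np.array_equal(D, bf.floyd_warshall(A))
            Ci, cp = clustering_coefficient(A)
            ci_ref, cp_ref = bf.clustering(A)
            assert np.allclose(Ci, ci_ref, atol=1e-12)
            assert abs(cp - cp_ref) < 1e-12
            assert abs(global_efficiency(A) - bf.global_eff(A)) < 1e-12
            assert abs(local_efficiency(A) - bf.local_eff(A)) < 1e-12
            nm = nodal_metrics(A)
            assert np.allclose(nm["betweenness"], bf.betweenness(A),
                               atol=1e-10)
            assert np.allclose(nm["efficiency"], bf.nodal_efficiency(A),
                               atol=1e-12)
            assert list(nm["degree"]) == bf.degrees(A)

    def test_lp_eglob_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            A = random_graph(rng)
            if A.sum() == 0:
                continue
            assert path_length_harmonic(A) * global_efficiency(A) == \
                pytest.approx(1.0, abs=1e-12)

    def test_adding_edge_never_increases_distances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = random_graph(rng, n=8, p=0.3)
            D0 = shortest_path_lengths(A)
            free = np.argwhere(np.triu(A == 0, 1))
            if len(free) == 0:
                continue
            i, j = free[rng.integers(len(free))]
            A2 = A.copy()
            A2[i, j] = A2[j, i] = 1
            D1 = shortest_path_lengths(A2)
            finite = np.isfinite(D0)
            assert (D1[finite] <= D0[finite]).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_metric_ranges_hold_on_arbitrary_graphs(self, seed):
        rng = np.random.default_rng(seed)
        A = random_graph(rng)
        Ci, cp = clustering_coefficient(A)
        assert np.all((Ci >= 0) & (Ci <= 1))
        assert 0 <= global_efficiency(A) <= 1
        assert 0 <= local_efficiency(A) <= 1
        nm = nodal_metrics(A)
        assert (nm["betweenness"] >= 0).all()
        assert nm["degree"].sum() == A.sum()


# ---------------------------------------------------------------------------
# degree-preserving rewiring
# ---------------------------------------------------------------------------

class TestRewiring:
    def test_preserves_degree_sequence_and_edge_count(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            A = random_graph(rng, n=12, p=0.4)
            if A.sum() < 4:
                continue
            G = BinaryGraph(A.astype(np.uint8))
            R = rewire_preserving_degree(G, swaps_per_edge=20, seed=trial)
            assert np.array_equal(R.degrees(), G.degrees())
            assert R.n_edges == G.n_edges

    def test_seed_reproducibility(self):
        G = generate_benchmark_graph("erdos_renyi", n=30, p=0.3, seed=2)
        R1 = rewire_preserving_degree(G, swaps_per_edge=10, seed=99)
        R2 = rewire_preserving_degree(G, swaps_per_edge=10, seed=99)
        assert np.array_equal(R1.adjacency, R2.adjacency)

    def test_rewiring_destroys_lattice_clustering(self):
        G = generate_benchmark_graph("ring_lattice", n=100, k=6)
        _, cp0 = clustering_coefficient(G.adjacency.astype(float))
        hits = 0
        for s in range(100):
            R = rewire_preserving_degree(G, swaps_per_edge=10, seed=s)
            _, cp = clustering_coefficient(R.adjacency.astype(float))
            hits += cp < cp0
        assert hits >= 95

    def test_ensemble_matches_networkx_double_edge_swap_statistics(self):
        # cross-check: blocked ensemble and networkx's sequential swap
        # agree on the mean clustering of the randomized lattice
        G = generate_benchmark_graph("ring_lattice", n=60, k=6)
        ens = _rewire_ensemble(G.adjacency.astype(bool), 30, 20,
                               np.random.default_rng(0))
        cps = [clustering_coefficient(a.astype(float))[1] for a in ens]
        nx_cps = []
        for s in range(30):
            H = nx.from_numpy_array(G.adjacency)
            nx.double_edge_swap(H, nswap=20 * G.n_edges,
                                max_tries=10_000 * G.n_edges, seed=s)
            nx_cps.append(nx.average_clustering(H))
        assert abs(np.mean(cps) - np.mean(nx_cps)) < 0.02

    def test_unswappable_graph_warns_and_returns_input(self):
        G = generate_benchmark_graph("star", n=5)  # no valid double swap
        with pytest.warns(RuntimeWarning, match="no valid"):
            R = rewire_preserving_degree(G, swaps_per_edge=5, seed=0)
        assert np.array_equal(R.adjacency, G.adjacency)


class TestSmallWorld:
    def test_self_ensemble_is_unity(self, complete4):
        G = generate_benchmark_graph("ring_lattice", n=20, k=4)
        sw = small_world_parameters(G, n_random=1, swaps_per_edge=0, seed=0)
        assert sw["gamma"] == pytest.approx(1.0)
        assert sw["lambda"] == pytest.approx(1.0)
        assert sw["sigma"] == pytest.approx(1.0)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            small_world_parameters(np.zeros((4, 4)), n_random=1, seed=0)


# ---------------------------------------------------------------------------
# curves and AUC
# ---------------------------------------------------------------------------

class TestCurvesAndAUC:
    def test_default_grid_has_46_levels(self):
        assert len(DEFAULT_GRID) == 46
        assert DEFAULT_GRID[0] == 0.05 and DEFAULT_GRID[-1] == 0.50

    def test_curves_on_constant_matrix_are_reproducible(self):
        C = np.full((10, 10), 0.5)
        np.fill_diagonal(C, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = metric_curves(C, n_random=2, swaps_per_edge=2, seed=4)
            m2 = metric_curves(C, n_random=2, swaps_per_edge=2, seed=4)
        assert m1.global_metrics.equals(m2.global_metrics)
        assert len(m1.global_metrics) == 46

    def test_curve_values_match_single_graph_metrics(self):
        rng = np.random.default_rng(8)
        C = np.corrcoef(rng.standard_normal((200, 12)), rowvar=False)
        np.fill_diagonal(C, 0)
        grid = np.array([0.2, 0.4, 0.6])
        curves = metric_curves(C, grid, n_random=0)
        for idx, sp in enumerate(grid):
            G = binarize_at_sparsity(C, sp)
            A = G.adjacency.astype(float)
            row = curves.global_metrics.iloc[idx]
            assert row["cp"] == pytest.approx(
                clustering_coefficient(A)[1], abs=1e-12)
            assert row["eglob"] == pytest.approx(global_efficiency(A),
                                                 abs=1e-12)
            assert row["eloc"] == pytest.approx(local_efficiency(A),
                                                abs=1e-12)
            nm = nodal_metrics(G)
            assert np.allclose(curves.nodal["betweenness"].iloc[idx],
                               nm["betweenness"], atol=1e-10)

    def test_auc_constant_and_linear_closed_forms(self):
        grid = DEFAULT_GRID
        assert auc(np.full(46, 3.0), grid) == pytest.approx(0.45 * 3.0)
        assert auc(grid.copy(), grid) == pytest.approx(
            (0.50 ** 2 - 0.05 ** 2) / 2)
        assert auc(np.array([1.0, 3.0]), np.array([0.1, 0.2])) == \
            pytest.approx(0.2)

    def test_auc_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0]), np.array([0.1]))
        with pytest.raises(ValueError):
            auc(np.array([np.nan, np.nan, 1.0]), np.array([0.1, 0.2, 0.3]))

    def test_auc_drops_missing_points_with_warning(self):
        y = np.array([1.0, np.nan, 1.0, 1.0])
        x = np.array([0.1, 0.2, 0.3, 0.4])
        with pytest.warns(RuntimeWarning, match="missing"):
            val = auc(y, x)
        assert val == pytest.approx(1.0 * 0.3)
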