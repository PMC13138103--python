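"""Path homology core: Betti numbers, curves and persistence pairing."""

import numpy as np
import networkx as nx
import pytest

import oracle
from pathpersist import betti_curve, betti_numbers, filtration_grid, persistence_pairs
from pathpersist.homology import GRID_TOL, allowed_two_paths

from conftest import make_filtered, random_filtered


def weak_components(nodes, edges):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.number_weakly_connected_components(g)


class TestBettiNumbers:
    def test_toy_network_full(self, toy):
        assert betti_numbers(toy) == (3, 2)

    def test_toy_network_edgeless(self, toy):
        assert betti_numbers((toy.nodes, [])) == (10, 0)

    def test_toy_network_single_edge(self, toy):
        b0, b1 = betti_numbers((toy.nodes, [("g9", "g7")]))
        assert (b0, b1) == (9, 0)

    @pytest.mark.parametrize(
        "edges,expected_b1",
        [
            # transitive triangle: the 2-path a->b->c fills the cycle
            ([("a", "b"), ("b", "c"), ("a", "c")], 0),
            # diamond: the two 2-paths a->b->d and a->c->d bound the square
            ([("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")], 0),
            # consistently oriented square: no allowed 2-path combination fills it
            ([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")], 1),
            # bi-fan ("directional cross-talk")
            ([("g6", "g7"), ("g6", "g8"), ("g9", "g7"), ("g9", "g8")], 1),
            # directed 5-cycle
            ([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")], 1),
        ],
        ids=["transitive-triangle", "diamond", "cyclic-square", "bi-fan", "5-cycle"],
    )
    def test_closed_forms(self, edges, expected_b1):
        nodes = sorted({v for e in edges for v in e})
        b0, b1 = betti_numbers((nodes, edges))
        assert b0 == 1
        assert b1 == expected_b1

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            betti_numbers((["a", "b"], [("a", "a"), ("a", "b")]))

    @pytest.mark.parametrize("backend", ["fraction", "gf"])
    def test_backends_agree_on_random_graphs(self, backend):
        rng = np.random.default_rng(3)
        for _ in range(25):
            nodes, edges = oracle.random_digraph(rng, int(rng.integers(2, 7)))
            assert betti_numbers((nodes, edges), backend=backend) == \
                oracle.betti_numbers(nodes, edges)

    def test_oracle_equivalence_on_100_random_digraphs(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            nodes, edges = oracle.random_digraph(rng, int(rng.integers(2, 7)), 0.3)
            ours = betti_numbers((nodes, edges))
            theirs = oracle.betti_numbers(nodes, edges)
            assert ours == theirs, (nodes, edges)

    def test_beta0_matches_weak_components(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            nodes, edges = oracle.random_digraph(rng, int(rng.integers(2, 8)), 0.25)
            assert betti_numbers((nodes, edges))[0] == weak_components(nodes, edges)

    def test_adding_an_edge_changes_beta0_by_at_most_one(self):
        rng = np.random.default_rng(21)
        nodes, edges = oracle.random_digraph(rng, 6, 0.3)
        candidates = [
            (a, b) for a in nodes for b in nodes
            if a != b and (a, b) not in edges
        ]
        current = edges[:]
        b0_prev = betti_numbers((nodes, current))[0]
        for e in candidates[:8]:
            current.append(e)
            b0 = betti_numbers((nodes, current))[0]
            assert b0 in (b0_prev, b0_prev - 1)
            b0_prev = b0


def test_boundary_composition_vanishes_on_omega2():
    """d1 ∘ d2 = 0 on Omega_2: boundary columns are themselves cycles."""
    from pathpersist._linalg import rank_of_columns
    from pathpersist.homology import _boundary_1, _omega2_and_boundary

    rng = np.random.default_rng(5)
    for _ in range(20):
        nodes, edges = oracle.random_digraph(rng, int(rng.integers(3, 7)), 0.4)
        if not edges:
            continue
        d2_cols, _ = _omega2_and_boundary(edges, "fraction")
        d1 = _boundary_1(nodes, edges)
        for col in d2_cols:
            image = [
                sum(d1[i][j] * col[j] for j in range(len(edges)))
                for i in range(len(nodes))
            ]
            assert all(v == 0 for v in image)


class TestBettiCurve:
    def test_toy_milestones(self, toy_fg):
        curve = betti_curve(toy_fg)
        at = {f: i for i, f in enumerate(round(float(x), 2) for x in curve.grid)}
        assert curve.values[0][at[0.0]] == 10 and curve.values[1][at[0.0]] == 0
        assert curve.values[0][at[0.2]] == 9 and curve.values[1][at[0.2]] == 0
        assert curve.values[0][at[0.4]] == 7 and curve.values[1][at[0.4]] == 1
        assert curve.values[0][at[0.95]] == 3 and curve.values[1][at[0.95]] == 2
        assert curve.values[0][at[1.0]] == 3 and curve.values[1][at[1.0]] == 2

    def test_all_zero_weights_constant_curve(self, toy):
        fg = make_filtered(
            {e: 0.0 for e in toy.edge_pairs()}, extra_nodes=toy.nodes
        )
        curve = betti_curve(fg)
        assert set(curve.values[0]) == {3} and set(curve.values[1]) == {2}

    def test_pointwise_recomputation_on_random_graphs(self):
        rng = np.random.default_rng(77)
        grid = filtration_grid()
        for _ in range(5):
            fg = random_filtered(rng, n_nodes=5)
            curve = betti_curve(fg, grid)
            for t in rng.choice(len(grid), size=12, replace=False):
                edges = [
                    e for e, w in fg.edge_weights.items()
                    if w <= grid[t] + GRID_TOL
                ]
                b0, b1 = betti_numbers((fg.network.nodes, edges))
                assert curve.values[0][t] == b0
                assert curve.values[1][t] == b1

    def test_beta0_non_increasing(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            curve = betti_curve(random_filtered(rng, n_nodes=6))
            assert np.all(np.diff(curve.values[0]) <= 0)


class TestPersistencePairs:
    def test_toy_has_exactly_two_dimension1_bars(self, toy_fg):
        bc = persistence_pairs(toy_fg, dimension=1)
        assert len(bc.bars) == 2
        assert all(bc.essential)

    def test_toy_dimension1_births_at_cycle_completion(self, toy_fg):
        # bi-fan completes at 0.3775 -> grid 0.38; square at 0.725 -> 0.73
        bc = persistence_pairs(toy_fg, dimension=1)
        assert sorted(b for b, _ in bc.bars) == [0.38, 0.73]

    def test_empty_graph_all_bars_essential(self):
        fg = make_filtered({}, extra_nodes=[f"n{i}" for i in range(4)])
        bc = persistence_pairs(fg, dimension=0)
        assert bc.bars == [(0.0, 1.0)] * 4
        assert all(bc.essential)

    @pytest.mark.parametrize("dimension", [0, 1])
    @pytest.mark.parametrize("method", ["rank", "curve"])
    def test_alive_bars_match_betti_curve_everywhere(self, dimension, method):
        rng = np.random.default_rng(31)
        grid = filtration_grid()
        for _ in range(6):
            fg = random_filtered(rng, n_nodes=5)
            curve = betti_curve(fg, grid)
            bc = persistence_pairs(fg, grid, dimension, method=method)
            for t, f in enumerate(grid):
                assert bc.alive_at(float(f)) == curve.values[dimension][t], (
                    fg.edge_weights, dimension, method, float(f)
                )

    def test_rank_invariant_against_oracle(self):
        """Persistent beta_1(i, j) from the barcode equals the brute-force
        Z∩B computation for nested subgraphs of random digraphs."""
        rng = np.random.default_rng(99)
        grid = filtration_grid()
        for _ in range(4):
            fg = random_filtered(rng, n_nodes=5, p_edge=0.45)
            bc = persistence_pairs(fg, grid, 1)
            for f_i, f_j in [(0.25, 0.5), (0.5, 0.75), (0.3, 0.9), (0.7, 0.7)]:
                small = [e for e, w in fg.edge_weights.items() if w <= f_i + GRID_TOL]
                big = [e for e, w in fg.edge_weights.items() if w <= f_j + GRID_TOL]
                expected = oracle.persistent_beta1(fg.network.nodes, small, big)
                from_bars = sum(
                    1
                    for (b, d), ess in zip(bc.bars, bc.essential)
                    if b <= f_i + GRID_TOL and (ess or d > f_j + GRID_TOL)
                )
                assert from_bars == expected

    def test_gf_backend_matches_fraction(self, toy_fg):
        for dim in (0, 1):
            a = persistence_pairs(toy_fg, dimension=dim, backend="fraction")
            b = persistence_pairs(toy_fg, dimension=dim, backend="gf")
            assert sorted(a.bars) == sorted(b.bars)


def test_allowed_two_paths_enumeration():
    edges = [("a", "b"), ("b", "c"), ("b", "a")]
    paths = set(allowed_two_paths(edges))
    assert paths == {("a", "b", "c"), ("a", "b", "a"), ("b", "a", "b")}


def test_grid_requires_step_dividing_one():
    with pytest.raises(ValueError, match="divide"):
        filtration_grid(0.03)
    assert len(filtration_grid(0.01)) == 101
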