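"""The gravity-model family: kernels, variants, the α factor and radius search."""

import math

import networkx as nx
import pytest

from spreadrank import (
    degree_centrality,
    eigenvector_centrality,
    estimate_r_star,
    gc,
    gc_plus,
    gravity_sum,
    k_shell,
    lgm,
    mcgm,
    mcgm_alpha,
    neighborhood_within,
    search_optimal_radius,
    ugm,
)

from conftest import floyd_warshall_distances


def brute_force_gravity(g, mass_focal, mass_neighbor, radius):
    nodes, dmat = floyd_warshall_distances(g)
    idx = {u: i for i, u in enumerate(nodes)}
    out = {}
    for i in nodes:
        total = 0.0
        for j in nodes:
            d = dmat[idx[i], idx[j]]
            if 1 <= d <= radius and not math.isinf(d):
                total += mass_focal[i] * mass_neighbor[j] / d**2
        out[i] = total
    return out


class TestNeighborhood:
    def test_toy_node3_radius2(self, toy_graph):
        assert neighborhood_within(toy_graph, "3", 2) == {
            ("2", 1), ("4", 1), ("7", 1), ("1", 2), ("5", 2), ("6", 2),
        }

    def test_toy_leaf_radius1(self, toy_graph):
        assert neighborhood_within(toy_graph, "1", 1) == {("2", 1)}

    def test_radius_beyond_diameter_reaches_all(self, toy_graph):
        pairs = neighborhood_within(toy_graph, "1", 10)
        assert {n for n, _ in pairs} == set(toy_graph) - {"1"}

    def test_invalid_radius(self, toy_graph):
        with pytest.raises(ValueError):
            neighborhood_within(toy_graph, "1", 0)


class TestGravitySum:
    def test_two_unit_masses(self):
        g = nx.Graph([("a", "b")])
        ones = {"a": 1.0, "b": 1.0}
        assert gravity_sum(g, ones, ones, 1) == {"a": 1.0, "b": 1.0}

    def test_path_radius2(self):
        g = nx.path_graph(["a", "b", "c"])
        ones = dict.fromkeys(g, 1.0)
        assert gravity_sum(g, ones, ones, 2)["a"] == pytest.approx(1.25)

    def test_missing_mass_raises(self, toy_graph):
        with pytest.raises(KeyError):
            gravity_sum(toy_graph, {"1": 1.0}, {"1": 1.0}, 2)

    def test_matches_brute_force(self, random_graphs):
        for g in random_graphs[:6]:
            deg = {n: float(d) for n, d in g.degree()}
            for radius in (1, 2, 3):
                got = gravity_sum(g, deg, deg, radius)
                expected = brute_force_gravity(g, deg, deg, radius)
                assert got == pytest.approx(expected)

    def test_nondecreasing_in_radius(self, random_graphs):
        for g in random_graphs[:6]:
            deg = {n: float(d) for n, d in g.degree()}
            prev = None
            for radius in (1, 2, 3, 4):
                cur = gravity_sum(g, deg, deg, radius)
                if prev is not None:
                    assert all(cur[n] >= prev[n] - 1e-12 for n in g)
                prev = cur


class TestGCFamily:
    def test_triangle_gc_and_igc(self):
        g = nx.cycle_graph(3)
        assert set(gc(g, "gc").scores.values()) == {8.0}
        assert set(gc(g, "igc").scores.values()) == {8.0}

    def test_toy_hub_gc(self, toy_graph):
        # ks(7)=3; 1-hop ks sum 2+2+3+3+3=13; 2-hop nodes 1,8,9 each ks 1
        assert gc(toy_graph, "gc")["7"] == pytest.approx(3 * 13 + 3 * 3 / 4)

    def test_gc_matches_brute_force(self, random_graphs):
        for g in random_graphs[:4]:
            ks = {n: float(v) for n, v in k_shell(g).scores.items()}
            deg = {n: float(d) for n, d in g.degree()}
            assert gc(g, "gc").scores == pytest.approx(
                brute_force_gravity(g, ks, ks, 3))
            assert gc(g, "igc").scores == pytest.approx(
                brute_force_gravity(g, ks, deg, 3))

    def test_triangle_gc_plus(self):
        assert set(gc_plus(nx.cycle_graph(3), "gc+").scores.values()) == {16.0}

    def test_plus_sums_neighbors_excluding_self(self, toy_graph):
        base = gc(toy_graph, "gc").scores
        plus = gc_plus(toy_graph, "gc+")
        assert plus["1"] == pytest.approx(base["2"])
        assert plus["7"] == pytest.approx(sum(base[j] for j in "23456"))

    def test_unknown_variant(self, toy_graph):
        with pytest.raises(ValueError):
            gc(toy_graph, "xxx")


class TestLGM:
    def test_two_nodes(self):
        g = nx.Graph([("a", "b")])
        assert lgm(g, 1).scores == {"a": 1.0, "b": 1.0}

    def test_toy_leaf_radius2(self, toy_graph):
        # k(1)=1; 1-hop: node 2 (k=3); 2-hop: nodes 3,7 (k=3,5)
        assert lgm(toy_graph, 2)["1"] == pytest.approx(3 + 8 / 4)

    def test_auto_radius_resolves(self, toy_graph):
        table = lgm(toy_graph, "auto")
        assert table.params["radius"] == 1  # <d> = 1.972 -> R* = 1


class TestRStar:
    @pytest.mark.parametrize(
        "avg_d, expected", [(2.2350, 1), (3.6925, 2), (1.0, 1), (3.0, 2), (2.9, 1)]
    )
    def test_half_average_distance(self, avg_d, expected):
        assert estimate_r_star(avg_d) == expected

    def test_positive_required(self):
        with pytest.raises(ValueError):
            estimate_r_star(0.0)


class TestAlpha:
    def test_toy_value(self, toy_graph, toy):
        stats = mcgm_alpha(
            degree_centrality(toy_graph), k_shell(toy_graph),
            eigenvector_centrality(toy_graph),
        )
        assert stats.k_max == 5 and stats.ks_max == 3
        assert stats.k_mid == 3 and stats.ks_mid == 2
        assert stats.x_max == pytest.approx(0.1917, abs=5e-4)
        assert stats.x_mid == pytest.approx(0.1256, abs=5e-4)
        assert stats.alpha == pytest.approx(toy.expected_alpha, abs=1e-4)

    def test_regular_graph_alpha_one(self):
        g = nx.random_regular_graph(4, 10, seed=2)
        stats = mcgm_alpha(
            degree_centrality(g), k_shell(g), eigenvector_centrality(g))
        assert stats.alpha == pytest.approx(1.0)

    def test_mismatched_nodes_raise(self, toy_graph):
        dc = degree_centrality(toy_graph)
        ks = k_shell(toy_graph)
        ec = eigenvector_centrality(toy_graph)
        del ec.scores["1"]
        with pytest.raises(ValueError):
            mcgm_alpha(dc, ks, ec)


class TestMCGM:
    def test_toy_all_printed_values(self, toy):
        table = mcgm(toy.network, radius=2)
        for node, expected in toy.expected_mcgm.items():
            assert table[node] == pytest.approx(expected, abs=0.01)

    def test_single_edge_symmetric(self):
        g = nx.Graph([("a", "b")])
        for norm in ("none", "plain", "alpha"):
            table = mcgm(g, radius=1, normalization=norm)
            assert table["a"] == pytest.approx(table["b"])

    def test_alpha_one_reduces_to_plain(self, random_graphs, monkeypatch):
        import spreadrank.gravity as grav
        for g in random_graphs[:3]:
            plain = mcgm(g, radius=2, normalization="plain")
            monkeypatch.setattr(
                grav, "mcgm_alpha",
                lambda dc, ks, ec: grav.AlphaStats(1, 1, 1, 1, 1, 1, 1.0),
            )
            forced = mcgm(g, radius=2, normalization="alpha")
            monkeypatch.undo()
            assert forced.scores == pytest.approx(plain.scores, abs=1e-12)

    def test_symmetric_toy_nodes_tie(self, toy_graph):
        table = mcgm(toy_graph, radius=2)
        assert table["5"] == pytest.approx(table["6"], abs=1e-12)
        assert table["8"] == pytest.approx(table["9"], abs=1e-12)

    def test_bad_normalization(self, toy_graph):
        with pytest.raises(ValueError):
            mcgm(toy_graph, radius=2, normalization="bogus")


class TestUGM:
    def test_degenerates_to_lgm(self, random_graphs):
        for g in random_graphs:
            u = ugm(g, 2, a=1.0, b=1.0).scores
            l = lgm(g, 2).scores
            assert all(abs(u[n] - l[n]) < 1e-12 for n in g)

    def test_degenerates_to_gc(self, random_graphs):
        for g in random_graphs:
            u = ugm(g, 3, a=0.0, b=0.0).scores
            c = gc(g, "gc").scores
            assert all(abs(u[n] - c[n]) < 1e-12 for n in g)

    def test_degenerates_to_igc(self, random_graphs):
        for g in random_graphs:
            u = ugm(g, 3, a=0.0, b=1.0).scores
            c = gc(g, "igc").scores
            assert all(abs(u[n] - c[n]) < 1e-12 for n in g)


class TestRadiusSearch:
    def test_self_consistency_returns_r2(self, toy_graph):
        truth_scores = mcgm(toy_graph, radius=2).scores

        class Truth:
            scores = truth_scores

        radius, tau = search_optimal_radius(
            toy_graph, lambda g, r: mcgm(g, radius=r), Truth())
        # perfect rank agreement up to the toy's two tied pairs, which the
        # tie-aware statistic keeps in the denominator
        assert tau == pytest.approx(1.0 - 2 * 2 / (9 * 8))
        assert radius <= 2  # ties break toward the smallest radius

    def test_diameter_one_graph(self):
        g = nx.complete_graph(4)
        truth_scores = {n: float(n) for n in g}

        class Truth:
            scores = truth_scores

        radius, _ = search_optimal_radius(
            g, lambda gg, r: lgm(gg, r), Truth())
        assert radius == 1
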