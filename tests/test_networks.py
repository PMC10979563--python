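import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_signed_graph
from omuecol.networks import (
    build_network,
    cpn_properties,
    detect_core_periphery,
    extract_skeleton,
    link_salience,
    nodf,
)
from omuecol.omu_table import OmuTable
from omuecol.simulate import plant_core_periphery


# -- independent oracles ------------------------------------------------


def brute_force_core_strength(G: nx.Graph):
    """Exhaustive scan of all non-trivial core assignments, scoring each by
    the Pearson correlation between observed and ideal off-diagonal
    adjacency, computed from first principles."""
    nodes = sorted(G.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    best_val, best_delta = -np.inf, None
    for bits in itertools.product((0, 1), repeat=n):
        if sum(bits) in (0, n):
            continue
        P = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j and (bits[i] or bits[j]):
                    P[i, j] = 1.0
        iu = np.triu_indices(n, k=1)
        a, p = A[iu], P[iu]
        if a.std() == 0 or p.std() == 0:
            continue
        val = float(np.corrcoef(a, p)[0, 1])
        if val > best_val:
            best_val, best_delta = val, np.array(bits)
    return best_val, best_delta


def brute_force_salience(G: nx.Graph, weight="weight"):
    """Edge salience via explicit enumeration of every simple path: an edge
    belongs to root x's tree iff it lies on some minimum-weight path from
    x to any other node."""
    sal = {tuple(sorted(e)): 0 for e in G.edges}
    comp_of = {}
    for comp in nx.connected_components(G):
        for node in comp:
            comp_of[node] = frozenset(comp)
    for x in G.nodes:
        comp = comp_of[x]
        in_tree = set()
        for y in comp:
            if y == x:
                continue
            paths = list(nx.all_simple_paths(G, x, y))
            costs = [
                sum(G.edges[u, v][weight] for u, v in zip(p, p[1:]))
                for p in paths
            ]
            best = min(costs)
            for p, c in zip(paths, costs):
                if np.isclose(c, best, rtol=1e-9):
                    for u, v in zip(p, p[1:]):
                        in_tree.add(tuple(sorted((u, v))))
        for e in in_tree:
            sal[e] += 1
    return {e: sal[e] / len(comp_of[e[0]]) for e in sal}


# -- construction -------------------------------------------------------


class TestBuildNetwork:
    def _table(self, rows, ids):
        return OmuTable(pd.DataFrame(
            np.asarray(rows, dtype=float), index=ids,
            columns=[f"s{j}" for j in range(len(rows[0]))]))

    def test_perfectly_rank_correlated_pair(self):
        base = np.arange(1.0, 11.0)
        table = self._table([base, base * 2 + 3, base[::-1]], list("abc"))
        net = build_network(table, alpha=0.05)
        assert net.edges["a", "b"]["rho"] == pytest.approx(1.0)
        assert net.edges["a", "b"]["sign"] == "+"
        assert net.edges["a", "c"]["rho"] == pytest.approx(-1.0)
        assert net.edges["a", "c"]["sign"] == "-"

    def test_constant_rows_excluded_with_warning(self):
        base = np.arange(1.0, 11.0)
        table = self._table([base, np.full(10, 7.0), base * 2], list("abc"))
        with pytest.warns(UserWarning):
            net = build_network(table)
        assert "b" not in net

    def test_false_edge_rate_controlled_on_noise(self):
        rates = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            table = self._table(rng.normal(10, 1, size=(50, 20)) ** 2,
                                [f"o{i}" for i in range(50)])
            net = build_network(table, alpha=0.05)
            rates.append(net.number_of_edges() / (50 * 49 / 2))
        assert float(np.mean(rates)) <= 0.05


# -- core/periphery ------------------------------------------------------


class TestCorePeriphery:
    def _ideal(self, nc=4, npr=8):
        G = nx.Graph()
        core = [f"c{i}" for i in range(nc)]
        peri = [f"p{i}" for i in range(npr)]
        G.add_edges_from(itertools.combinations(core, 2))
        G.add_edges_from((p, c) for p in peri for c in core)
        return G, core, peri

    def test_planted_ideal_recovered_exactly(self):
        G, core, peri = self._ideal()
        res = detect_core_periphery(G)
        assert sorted(res.core) == sorted(core)
        assert res.core_strength == pytest.approx(1.0)
        # raw match score: every edge coincides with the ideal pattern
        assert res.rho_score == 2 * G.number_of_edges()

    @pytest.mark.parametrize("seed", range(6))
    def test_annealing_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        G = nx.gnp_random_graph(n, 0.4, seed=seed)
        if G.number_of_edges() == 0:
            G.add_edge(0, 1)
        oracle_val, _ = brute_force_core_strength(G)
        annealed = detect_core_periphery(G, seed=3, exhaustive_max=0)
        assert annealed.core_strength == pytest.approx(oracle_val, abs=1e-9)

    def test_random_graph_weaker_than_planted(self):
        G, _, _ = self._ideal()
        planted = detect_core_periphery(G).core_strength
        vals = []
        for seed in range(10):
            R = nx.gnp_random_graph(12, 0.5, seed=seed)
            if R.number_of_edges() < 2:
                continue
            vals.append(detect_core_periphery(R).core_strength)
        assert max(vals) < planted

    def test_complement_never_scores_higher(self):
        G = nx.gnp_random_graph(10, 0.45, seed=5)
        res = detect_core_periphery(G)
        from omuecol.networks import _score

        A = nx.to_numpy_array(G, nodelist=res.nodes, weight=None)
        _, flipped = _score(A, 1 - res.delta)
        assert not flipped > res.core_strength

    def test_pipeline_recovers_planted_core(self):
        table, truth = plant_core_periphery(8, 24, 100, loading=0.9,
                                            noise=1.0, seed=5)
        net = build_network(table, alpha=0.05)
        cpn = detect_core_periphery(net, seed=1)
        true_core = {i for i, s in truth.structure.items() if s == "core"}
        acc = np.mean([
            (node in set(cpn.core)) == (node in true_core)
            for node in cpn.nodes
        ])
        assert acc >= 0.95


class TestCpnProperties:
    def test_ideal_block_densities(self):
        G = nx.Graph()
        core = [f"c{i}" for i in range(4)]
        peri = [f"p{i}" for i in range(6)]
        G.add_edges_from((u, v, {"sign": "+"})
                         for u, v in itertools.combinations(core, 2))
        G.add_edges_from((p, c, {"sign": "-"}) for p in peri for c in core)
        cpn = detect_core_periphery(G)
        props = cpn_properties(G, cpn)
        assert props["block_density"]["core_core"] == 1.0
        assert props["block_density"]["core_periphery"] == 1.0
        assert props["block_density"]["periphery_periphery"] == 0.0
        assert props["cp_ratio"] == pytest.approx(0.4)
        assert props["block_pn"]["core_core"] == (6, 0)
        assert props["block_pn"]["core_periphery"] == (0, 24)

    def test_nodf_perfectly_nested_matrix(self):
        # strictly nested with distinct fills: every pair overlaps fully
        M = np.array([
            [1, 1, 1, 1],
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 0],
        ])
        assert nodf(M) == pytest.approx(100.0)

    def test_nodf_checkerboard_is_zero(self):
        M = np.array([[1, 0], [0, 1]])
        assert nodf(M) == 0.0


# -- salience / skeleton -------------------------------------------------


class TestLinkSalience:
    def test_path_graph_all_edges_salient(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("b", "c", weight=1.0)
        sal = link_salience(G).salience
        assert sal[("a", "b")] == 1.0
        assert sal[("b", "c")] == 1.0

    def test_hand_worked_triangle(self):
        G = nx.Graph()
        G.add_edge("x", "y", weight=1.0)
        G.add_edge("y", "z", weight=1.0)
        G.add_edge("x", "z", weight=3.0)
        sal = link_salience(G).salience
        assert sal[("x", "y")] == 1.0
        assert sal[("y", "z")] == 1.0
        assert sal[("x", "z")] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = random_signed_graph(rng, int(rng.integers(4, 9)))
        if G.number_of_edges() == 0:
            return
        got = link_salience(G).salience
        expected = brute_force_salience(G)
        for e in expected:
            assert got[e] == pytest.approx(expected[e], abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        G = random_signed_graph(rng, 7)
        ref = link_salience(G).salience
        scaled = G.copy()
        for u, v in scaled.edges:
            scaled.edges[u, v]["weight"] *= 17.0
        assert link_salience(scaled).salience == ref

    def test_nonpositive_weight_rejected(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=0.0)
        with pytest.raises(ValueError):
            link_salience(G)


class TestSkeleton:
    def _path(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        G.add_edge("b", "c", weight=1.0)
        return G

    def test_threshold_one_keeps_fully_salient_edges(self):
        G = self._path()
        hsn = extract_skeleton(G, link_salience(G), s_star=1.0)
        assert sorted(hsn.skeleton) == [("a", "b"), ("b", "c")]
        assert hsn.fraction == 1.0

    def test_threshold_above_max_empties_skeleton(self):
        G = nx.Graph()
        G.add_edge("x", "y", weight=1.0)
        G.add_edge("y", "z", weight=1.0)
        G.add_edge("x", "z", weight=1.0)  # symmetric triangle: s = 2/3
        hsn = extract_skeleton(G, link_salience(G), s_star=0.9)
        assert hsn.skeleton == []
        assert hsn.fraction == 0.0

    def test_moments_match_direct_formulas(self):
        rng = np.random.default_rng(8)
        G = random_signed_graph(rng, 8)
        hsn = extract_skeleton(G, link_salience(G), s_star=0.5)
        v = np.array(list(hsn.salience.values()))
        m = v.mean()
        sd = v.std()
        skew = ((v - m) ** 3).mean() / sd**3
        kurt = ((v - m) ** 4).mean() / sd**4 - 3
        assert hsn.moments["mean"] == pytest.approx(m, abs=1e-10)
        assert hsn.moments["max"] == v.max()
        assert hsn.moments["skewness"] == pytest.approx(skew, abs=1e-10)
        assert hsn.moments["kurtosis"] == pytest.approx(kurt, abs=1e-10)

    def test_invalid_threshold_rejected(self):
        G = self._path()
        with pytest.raises(ValueError):
            extract_skeleton(G, link_salience(G), s_star=0.0)
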