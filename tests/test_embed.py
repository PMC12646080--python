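"""Walk graphs, biased walks, skip-gram embedding, WED and betweenness."""

from collections import Counter, defaultdict, deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pleionet import embed
from pleionet.types import ConfigurationError, TermIncidence, TopKCurve, WalkConfig, WeightedAdjacency


def _adj(W: np.ndarray, ids=None) -> WeightedAdjacency:
    n = W.shape[0]
    ids = ids or [f"g{i}" for i in range(n)]
    return WeightedAdjacency(weights=pd.DataFrame(W, index=ids, columns=ids))


def betweenness_bruteforce(G: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration oracle (n <= 12)."""

    def bfs_dist(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in G.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        return dist

    score = dict.fromkeys(G.nodes, 0.0)
    nodes = list(G.nodes)
    for i, s in enumerate(nodes):
        dist_t = {t: bfs_dist(t) for t in nodes}
        for t in nodes[i + 1:]:
            if t not in dist_t[s] or s == t:
                continue
            # enumerate all shortest s-t paths by DFS down the distance gradient
            paths = []
            stack = [[s]]
            while stack:
                path = stack.pop()
                u = path[-1]
                if u == t:
                    paths.append(path)
                    continue
                for v in G.neighbors(u):
                    if dist_t[t].get(v, -1) == dist_t[t][u] - 1:
                        stack.append(path + [v])
            if not paths:
                continue
            through = Counter(v for p in paths for v in p[1:-1])
            for v, cnt in through.items():
                score[v] += cnt / len(paths)
    return score


class TestWalkGraph:
    def test_incidence_expands_to_bipartite_path(self):
        inc = TermIncidence(
            matrix=pd.DataFrame({"T1": [1, 1]}, index=["gA", "gB"]),
            qvalues=pd.Series({"T1": 0.01}),
        )
        G = embed.build_walk_graph(inc)
        assert nx.shortest_path(G, "gA", "gB") == ["gA", "T1", "gB"]

    def test_diagonal_ignored_weights_preserved(self):
        W = np.array([[0.7, 0.3], [0.3, 0.9]])
        G = embed.build_walk_graph(_adj(W))
        assert not G.has_edge("g0", "g0")
        assert G["g0"]["g1"]["weight"] == pytest.approx(0.3)

    def test_isolated_nodes_retained(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        G = embed.build_walk_graph(_adj(W))
        assert G.number_of_nodes() == 3


class TestWalks:
    def test_isolated_node_dead_end_policy(self):
        G = nx.Graph()
        G.add_node("lonely")
        walks = embed.biased_random_walks(G, WalkConfig(n_walks=3, seed=0))
        assert walks == [["lonely"]] * 3

    def test_walk_counts_and_lengths(self):
        G = nx.cycle_graph(6)
        cfg = WalkConfig(seed=1)
        walks = embed.biased_random_walks(G, cfg)
        assert len(walks) == 6 * cfg.n_walks
        assert all(len(w) <= cfg.walk_length for w in walks)
        starts = Counter(w[0] for w in walks)
        assert all(starts[v] == cfg.n_walks for v in G.nodes)

    def test_triangle_transition_frequencies_match_analytic(self):
        G = nx.complete_graph(3)
        cfg = WalkConfig(n_walks=140, walk_length=250, seed=2)
        walks = embed.biased_random_walks(G, cfg)
        counts: dict = defaultdict(Counter)
        total_steps = 0
        for w in walks:
            for i in range(2, len(w)):
                counts[(w[i - 2], w[i - 1])][w[i]] += 1
                total_steps += 1
        assert total_steps > 100_000
        for (u, v), nxt in counts.items():
            expected = embed.walk_transition_probs(G, u, v, cfg)
            n = sum(nxt.values())
            for x, p_exp in expected.items():
                assert abs(nxt[x] / n - p_exp) < 0.01

    def test_deterministic_given_seed(self):
        G = nx.karate_club_graph()
        cfg = WalkConfig(n_walks=2, walk_length=20, seed=5)
        assert embed.biased_random_walks(G, cfg) == embed.biased_random_walks(G, cfg)


def two_cliques_with_bridge(k: int = 20) -> nx.Graph:
    G = nx.Graph()
    for base in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                G.add_edge(base + i, base + j, weight=1.0)
    G.add_edge(0, k, weight=1.0)
    return G


class TestSkipgram:
    def test_dimensionality_and_determinism(self):
        G = nx.cycle_graph(8)
        walks = embed.biased_random_walks(G, WalkConfig(n_walks=3, walk_length=20, seed=3))
        a = embed.skipgram_embed(walks, nodes=list(G.nodes), epochs=2, seed=3)
        b = embed.skipgram_embed(walks, nodes=list(G.nodes), epochs=2, seed=3)
        assert a.dims == 32
        assert a.vectors.shape == (8, 32)
        pd.testing.assert_frame_equal(a.vectors, b.vectors)

    def test_unwalked_node_gets_zero_vector(self):
        walks = [["a", "b", "a", "b"]]
        emb = embed.skipgram_embed(walks, nodes=["a", "b", "c"], epochs=1, seed=0)
        assert np.allclose(emb.vectors.loc["c"], 0.0)
        assert not np.allclose(emb.vectors.loc["a"], 0.0)

    def test_clique_structure_separates(self):
        G = two_cliques_with_bridge()
        walks = embed.biased_random_walks(G, WalkConfig(seed=1))
        emb = embed.skipgram_embed(walks, nodes=list(G.nodes), epochs=10, seed=1)
        V = emb.vectors.to_numpy()
        Vn = V / np.linalg.norm(V, axis=1, keepdims=True)
        S = Vn @ Vn.T
        within = np.mean(
            [S[i, j] for i in range(20) for j in range(i + 1, 20)]
            + [S[i, j] for i in range(20, 40) for j in range(i + 1, 40)]
        )
        cross = float(np.mean(S[:20, 20:]))
        assert within > cross


class TestWED:
    def test_complete_unit_graph_all_ones(self):
        n = 12
        W = np.ones((n, n)) - np.eye(n)
        curve = embed.wed_topk(_adj(W), [f"g{i}" for i in range(n)], k_grid=[2, 5, 12])
        np.testing.assert_allclose(curve.values, 1.0)

    def test_no_edges_zero(self):
        W = np.zeros((5, 5))
        curve = embed.wed_topk(_adj(W), [f"g{i}" for i in range(5)], k_grid=[3, 5])
        np.testing.assert_allclose(curve.values, 0.0)

    def test_hand_computed_k3(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.25
        W[1, 2] = W[2, 1] = 0.25
        curve = embed.wed_topk(_adj(W), ["g0", "g1", "g2"], k_grid=[3])
        assert curve.values[0] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_pairwise_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        W = rng.uniform(0, 1, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        ids = [f"g{i}" for i in range(n)]
        ranking = list(rng.permutation(ids))
        grid = [k for k in (2, 3, n // 2, n) if k >= 2]
        curve = embed.wed_topk(_adj(W), ranking, k_grid=grid)
        adj = pd.DataFrame(W, index=ids, columns=ids)
        for K, val in zip(curve.K, curve.values):
            top = ranking[:K]
            direct = sum(
                adj.loc[top[i], top[j]]
                for i in range(K) for j in range(i + 1, K)
            ) / (K * (K - 1) / 2)
            assert val == pytest.approx(direct, rel=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        W = rng.uniform(0, 1, (8, 8)); W = (W + W.T) / 2; np.fill_diagonal(W, 0)
        ids = [f"g{i}" for i in range(8)]
        other = [f"x{i}" for i in range(8)]
        ranking = ids[::-1]
        c1 = embed.wed_topk(_adj(W, ids), ranking, k_grid=[4, 8])
        c2 = embed.wed_topk(_adj(W, other), [o for o in other[::-1]], k_grid=[4, 8])
        np.testing.assert_allclose(c1.values, c2.values)


class TestBetweenness:
    def test_star_closed_form(self):
        G = nx.star_graph(4)  # center 0, four leaves
        scores = embed.betweenness(G)
        assert scores[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        for leaf in range(1, 5):
            assert scores[leaf] == pytest.approx(0.0)

    def test_path_middle(self):
        G = nx.path_graph(3)
        assert embed.betweenness(G)[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        p = float(rng.uniform(0.2, 0.7))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        got = embed.betweenness(G)
        want = betweenness_bruteforce(G)
        for v in G.nodes:
            assert got[v] == pytest.approx(want[v], abs=1e-9)


class TestMeanBetweennessTopK:
    def test_k_equals_all_gives_global_mean(self):
        scores = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0, "T": 99.0})
        curve = embed.mean_betweenness_topk(scores, ["a", "b", "c"], k_grid=[3])
        assert curve.values[0] == pytest.approx(2.0)

    def test_flat_scores_flat_curve(self):
        scores = pd.Series({f"g{i}": 1.5 for i in range(10)})
        curve = embed.mean_betweenness_topk(
            scores, [f"g{i}" for i in range(10)], k_grid=[2, 5, 10]
        )
        np.testing.assert_allclose(curve.values, 1.5)

    def test_hub_fixture_decreasing_curve(self):
        # low-p genes are term hubs: mean betweenness decays with K
        G = nx.Graph()
        genes = [f"g{i}" for i in range(12)]
        for t in range(4):
            members = genes[: 3 + t * 3]  # earlier genes join more terms
            for g in members:
                G.add_edge(g, f"T{t}")
        scores = embed.betweenness(G)
        curve = embed.mean_betweenness_topk(scores, genes, k_grid=[3, 6, 9, 12])
        assert (np.diff(curve.values) <= 1e-12).all()

    def test_terms_excluded_from_mean(self):
        scores = pd.Series({"g1": 2.0, "T1": 50.0})
        curve = embed.mean_betweenness_topk(scores, ["g1"], k_grid=[1])
        assert curve.values[0] == pytest.approx(2.0)


def test_k_grid_caps_and_errors():
    grid = embed.default_k_grid(350)
    np.testing.assert_array_equal(grid, [100, 200, 300])
    assert list(embed.default_k_grid(50)) == [50]
    with pytest.raises(ConfigurationError):
        embed.wed_topk(_adj(np.zeros((3, 3))), ["g0", "g1", "g2"], k_grid=[])
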