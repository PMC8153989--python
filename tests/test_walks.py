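"""Biased walk transition law, walk corpus, and skip-gram embedding."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mgrl.walks import (
    Node2Vec,
    WalkConfig,
    generate_walks,
    step_distribution,
    train_skipgram,
    transition_bias,
)


class TestTransitionBias:
    def test_return_bias(self):
        assert transition_bias(0, p=4, q=1) == 0.25

    def test_common_neighbor_bias_is_unit(self):
        assert transition_bias(1, p=9, q=9) == 1.0

    def test_outward_bias(self):
        assert transition_bias(2, p=1, q=2) == 0.5

    def test_uniform_when_p_q_one(self):
        assert [transition_bias(d, 1, 1) for d in (0, 1, 2)] == [1, 1, 1]

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            transition_bias(3, 1, 1)


class TestStepDistribution:
    def test_triangle_uniform(self):
        g = nx.Graph([("t", "v"), ("v", "x"), ("t", "x")])
        neighbors, probs = step_distribution(g, "t", "v", p=1, q=1)
        assert sorted(neighbors) == ["t", "x"]
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_path_graph_outward_discounted(self):
        # t - v - x with no t-x edge: alpha(t) = 1/p = 1, alpha(x) = 1/q
        g = nx.Graph([("t", "v"), ("v", "x")])
        neighbors, probs = step_distribution(g, "t", "v", p=1, q=2)
        d = dict(zip(neighbors, probs))
        assert d["t"] == pytest.approx(2 / 3)
        assert d["x"] == pytest.approx(1 / 3)

    def test_star_center(self):
        g = nx.Graph([("v", "t"), ("v", "a"), ("v", "b")])
        neighbors, probs = step_distribution(g, "t", "v", p=2, q=3)
        d = dict(zip(neighbors, probs))
        assert d["t"] == pytest.approx(3 / 7)
        assert d["a"] == pytest.approx(2 / 7)
        assert d["b"] == pytest.approx(2 / 7)

    def test_first_step_weight_proportional(self):
        g = nx.Graph()
        g.add_edge("v", "a", weight=3.0)
        g.add_edge("v", "b", weight=1.0)
        neighbors, probs = step_distribution(g, None, "v", p=5, q=5)
        d = dict(zip(neighbors, probs))
        assert d["a"] == pytest.approx(0.75)

    def test_isolated_vertex_rejected(self):
        g = nx.Graph()
        g.add_node("v")
        with pytest.raises(ValueError, match="isolated"):
            step_distribution(g, None, "v", 1, 1)

    def test_sums_to_one_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 16)))
            p, q = rng.uniform(0.25, 4, size=2)
            for v in g.nodes:
                if g.degree(v) == 0:
                    continue
                t = next(iter(g.neighbors(v)))
                neighbors, probs = step_distribution(g, t, v, p, q)
                assert probs.sum() == pytest.approx(1.0)
                assert set(neighbors) == set(g.neighbors(v))

    def test_p_q_one_reduces_to_weight_proportional(self):
        g = nx.Graph()
        g.add_edge("v", "a", weight=2.0)
        g.add_edge("v", "b", weight=6.0)
        g.add_edge("v", "t", weight=2.0)
        neighbors, probs = step_distribution(g, "t", "v", 1, 1)
        w = {"a": 2.0, "b": 6.0, "t": 2.0}
        total = sum(w.values())
        for x, pr in zip(neighbors, probs):
            assert pr == pytest.approx(w[x] / total)


class TestGenerateWalks:
    def cfg(self, **kw):
        base = dict(walk_length=5, num_walks=2, dim=8, window=2, epochs=1, seed=0)
        base.update(kw)
        return WalkConfig(**base)

    def test_single_edge_alternates(self):
        g = nx.Graph([("a", "b")])
        walks = generate_walks(g, self.cfg(walk_length=4))
        for walk in walks:
            assert walk in (["a", "b", "a", "b"], ["b", "a", "b", "a"])

    def test_walk_invariants(self):
        g = nx.gnp_random_graph(10, 0.4, seed=4)
        walks = generate_walks(g, self.cfg())
        non_isolated = [u for u in g.nodes if g.degree(u) > 0]
        assert len(walks) == 2 * len(non_isolated)
        starts = [w[0] for w in walks]
        for u in non_isolated:
            assert starts.count(u) == 2
        for walk in walks:
            assert len(walk) <= 5
            for a, b in zip(walk, walk[1:]):
                assert g.has_edge(a, b)

    def test_seed_reproducibility(self):
        g = nx.gnp_random_graph(12, 0.3, seed=9)
        assert generate_walks(g, self.cfg(seed=5)) == generate_walks(g, self.cfg(seed=5))
        assert generate_walks(g, self.cfg(seed=5)) != generate_walks(g, self.cfg(seed=6))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            generate_walks(nx.empty_graph(3), self.cfg())

    def test_empirical_first_transition_matches_exact_law(self):
        # all second-step transitions from state (t, v) are draws from
        # the exact step distribution; chi-square over pooled states
        g = nx.Graph([("t", "v"), ("v", "x"), ("v", "y"), ("t", "x")])
        config = self.cfg(walk_length=40, num_walks=150, seed=12, p=2.0, q=0.5)
        walks = generate_walks(g, config)
        counts: dict[tuple, dict] = {}
        for walk in walks:
            for t, v, x in zip(walk, walk[1:], walk[2:]):
                counts.setdefault((t, v), {}).setdefault(x, 0)
                counts[(t, v)][x] += 1
        chi2 = 0.0
        dof = 0
        for (t, v), obs in counts.items():
            neighbors, probs = step_distribution(g, t, v, config.p, config.q)
            n = sum(obs.values())
            if n < 50:
                continue
            for x, pr in zip(neighbors, probs):
                expect = n * pr
                chi2 += (obs.get(x, 0) - expect) ** 2 / expect
                dof += 1
            dof -= 1
        assert stats.chi2.sf(chi2, dof) > 0.01


class TestSkipgram:
    def test_vector_dimension_and_coverage(self):
        walks = [["a", "b", "c", "a"], ["b", "a", "b", "c"]]
        ids, vecs = train_skipgram(walks, dim=8, window=2, epochs=2, seed=0)
        assert ids == ["a", "b", "c"]
        assert vecs.shape == (3, 8)
        assert np.isfinite(vecs).all()

    def test_determinism(self):
        g = nx.gnp_random_graph(10, 0.5, seed=1)
        cfg = WalkConfig(walk_length=10, num_walks=3, dim=8, window=3, epochs=2, seed=4)
        walks = generate_walks(g, cfg)
        _, v1 = train_skipgram(walks, dim=8, window=3, epochs=2, seed=4)
        _, v2 = train_skipgram(walks, dim=8, window=3, epochs=2, seed=4)
        np.testing.assert_array_equal(v1, v2)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_skipgram([])

    def test_structural_neighbors_embed_closer(self):
        # two 4-cliques joined by one bridge: nodes inside a clique should
        # be more similar to each other than to nodes across the bridge
        g = nx.Graph()
        for base in (0, 10):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(base + i, base + j)
        g.add_edge(0, 10)
        n2v = Node2Vec(
            n_components=16, walk_length=20, num_walks=20, window=4,
            epochs=5, random_state=2,
        ).fit(g)
        emb = n2v.embedding_

        def cos(a, b):
            return float(np.dot(emb[a], emb[b]) / (np.linalg.norm(emb[a]) * np.linalg.norm(emb[b])))

        assert cos(1, 2) > cos(1, 12)
        assert cos(11, 13) > cos(11, 3)

    def test_transform_zero_fills_missing(self):
        g = nx.Graph([("a", "b")])
        n2v = Node2Vec(n_components=4, walk_length=5, num_walks=2, epochs=1,
                       random_state=0).fit(g)
        out = n2v.transform(["a", "ghost"])
        assert out.shape == (2, 4)
        assert out[0].any()
        assert not out[1].any()
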