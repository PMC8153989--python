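"""node2vec: second-order biased random walks plus skip-gram embedding.

A walk currently at vertex ``v``, having arrived from ``t``, steps to a
neighbor ``x`` with unnormalized probability ``alpha_pq(t, x) * w_vx``,
where the search bias depends on the hop distance d(t, x):

    alpha = 1/p  if x == t          (return)
            1    if x neighbors t   (stay close)
            1/q  otherwise          (move outward)

``p`` is the return parameter, ``q`` the in-out parameter; p = q = 1
recovers the plain weight-proportional first-order walk.  The walk
corpus is embedded with skip-gram and negative sampling (SGNS); the
trainer is a seeded, single-threaded numba kernel so identical
configurations produce identical vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
from numba import njit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "WalkConfig",
    "transition_bias",
    "step_distribution",
    "generate_walks",
    "train_skipgram",
    "Node2Vec",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Hyperparameters of the biased walk and the skip-gram trainer.

    Defaults follow the published node2vec conventions: 10 walks of
    length 80 per node, window 10, p = q = 1; the 64-dimensional
    output mirrors the graph-convolution feature width so the two
    representations contribute equally after fusion.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    num_walks: int = 10
    dim: int = 64
    window: int = 10
    epochs: int = 5
    negative: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be > 0")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if min(self.num_walks, self.dim, self.window, self.epochs) < 1:
            raise ValueError("num_walks, dim, window and epochs must be >= 1")


def transition_bias(d_tx: int, p: float, q: float) -> float:
    """Search bias alpha for hop distance d(t, x) in {0, 1, 2}."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ValueError(f"hop distance must be 0, 1 or 2, got {d_tx}")


def step_distribution(
    graph: nx.Graph,
    prev: Hashable | None,
    cur: Hashable,
    p: float,
    q: float,
) -> tuple[list, np.ndarray]:
    """Exact next-step distribution over the neighbors of ``cur``.

    ``prev`` is the walk's previous vertex, or None at the first step
    (no predecessor: alpha is 1 for every neighbor, i.e. the step is
    weight-proportional).  Probabilities sum to 1 and are zero off the
    neighbor set by construction.
    """
    neighbors = sorted(graph.neighbors(cur))
    if not neighbors:
        raise ValueError(f"vertex {cur!r} is isolated; cannot step from it")
    weights = np.array(
        [graph[cur][x].get("weight", 1.0) for x in neighbors], dtype=np.float64
    )
    if prev is None:
        unnorm = weights
    else:
        alphas = np.empty(len(neighbors))
        for i, x in enumerate(neighbors):
            if x == prev:
                d = 0
            elif graph.has_edge(prev, x):
                d = 1
            else:
                d = 2
            alphas[i] = transition_bias(d, p, q)
        unnorm = alphas * weights
    return neighbors, unnorm / unnorm.sum()


def generate_walks(graph: nx.Graph, config: WalkConfig) -> list[list]:
    """Biased walk corpus: ``num_walks`` walks of ``walk_length`` vertices
    from every non-isolated node, reproducible for a fixed seed.

    Second-order transition distributions are cached per (prev, cur)
    state, so each distinct state is normalized once per run.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges; nothing to walk")
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, tuple[list, np.ndarray]] = {}

    def distribution(prev, cur):
        # cumulative form so each step is one uniform draw + searchsorted
        key = (prev, cur)
        if key not in cache:
            neighbors, probs = step_distribution(graph, prev, cur, config.p, config.q)
            cache[key] = (neighbors, np.cumsum(probs))
        return cache[key]

    walks: list[list] = []
    nodes = sorted(graph.nodes())
    skipped = [u for u in nodes if graph.degree(u) == 0]
    if skipped:
        logger.warning("skipping %d isolated node(s) in walk generation", len(skipped))
    for _ in range(config.num_walks):
        for u in nodes:
            if graph.degree(u) == 0:
                continue
            walk = [u]
            prev = None
            while len(walk) < config.walk_length:
                cur = walk[-1]
                neighbors, cdf = distribution(prev, cur)
                idx = int(np.searchsorted(cdf, rng.random(), side="right"))
                nxt = neighbors[min(idx, len(neighbors) - 1)]
                walk.append(nxt)
                prev = cur
            walks.append(walk)
    return walks


@njit(cache=True)
def _xorshift(state):
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _sgns_kernel(
    tokens, offsets, emb_in, emb_out, noise_cdf, window, epochs, negative, lr0, seed
):
    """Classic word2vec SGNS: reduced windows, unigram^0.75 negatives,
    linearly decaying learning rate.  Fully deterministic for a seed."""
    dim = emb_in.shape[1]
    state = np.uint64(seed * 2654435761 + 1)
    total = np.float64(epochs * tokens.shape[0])
    processed = 0.0
    neu1e = np.empty(dim)
    for _ in range(epochs):
        for w in range(offsets.shape[0] - 1):
            start, end = offsets[w], offsets[w + 1]
            for i in range(start, end):
                center = tokens[i]
                lr = lr0 * (1.0 - processed / total)
                if lr < lr0 * 1e-4:
                    lr = lr0 * 1e-4
                processed += 1.0
                state = _xorshift(state)
                b = int(state % np.uint64(window))
                lo = i - (window - b)
                hi = i + (window - b)
                if lo < start:
                    lo = start
                if hi > end - 1:
                    hi = end - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    context = tokens[j]
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = context
                            label = 1.0
                        else:
                            state = _xorshift(state)
                            u = np.float64(state >> np.uint64(11)) / 9007199254740992.0
                            target = np.searchsorted(noise_cdf, u)
                            if target == context:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += emb_in[center, d] * emb_out[target, d]
                        if f > 6.0:
                            s = 1.0
                        elif f < -6.0:
                            s = 0.0
                        else:
                            s = 1.0 / (1.0 + math.exp(-f))
                        g = (label - s) * lr
                        for d in range(dim):
                            neu1e[d] += g * emb_out[target, d]
                            emb_out[target, d] += g * emb_in[center, d]
                    for d in range(dim):
                        emb_in[center, d] += neu1e[d]


def train_skipgram(
    walks: Sequence[Sequence[Hashable]],
    dim: int = 64,
    window: int = 10,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
    learning_rate: float = 0.025,
) -> tuple[list, np.ndarray]:
    """Embed a walk corpus with skip-gram and negative sampling.

    Returns the walked node ids (sorted) and one d-dimensional vector
    per node.  Nodes absent from every walk are absent from the output.
    """
    if not walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({node for walk in walks for node in walk})
    index = {node: i for i, node in enumerate(vocab)}
    tokens = np.empty(sum(len(w) for w in walks), dtype=np.int64)
    offsets = np.zeros(len(walks) + 1, dtype=np.int64)
    pos = 0
    for wi, walk in enumerate(walks):
        for node in walk:
            tokens[pos] = index[node]
            pos += 1
        offsets[wi + 1] = pos
    counts = np.bincount(tokens, minlength=len(vocab)).astype(np.float64)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    rng = np.random.default_rng(seed)
    emb_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    emb_out = np.zeros((len(vocab), dim))
    _sgns_kernel(
        tokens,
        offsets,
        emb_in,
        emb_out,
        noise_cdf,
        window,
        epochs,
        negative,
        learning_rate,
        seed,
    )
    return vocab, emb_in


class Node2Vec(BaseEstimator):
    """node2vec graph embedder with the sklearn estimator surface.

    Parameters mirror :class:`WalkConfig`; ``random_state`` seeds both
    the walk generator and the skip-gram trainer.

    Attributes
    ----------
    node_ids_ : list
        Walked nodes, sorted; isolated nodes never appear.
    vectors_ : ndarray of shape (n_walked, n_components)
    embedding_ : dict
        node id -> vector view, for keyed lookup.
    """

    def __init__(
        self,
        n_components: int = 64,
        p: float = 1.0,
        q: float = 1.0,
        walk_length: int = 80,
        num_walks: int = 10,
        window: int = 10,
        epochs: int = 5,
        negative: int = 5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.p = p
        self.q = q
        self.walk_length = walk_length
        self.num_walks = num_walks
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.random_state = random_state

    def _config(self) -> WalkConfig:
        return WalkConfig(
            p=self.p,
            q=self.q,
            walk_length=self.walk_length,
            num_walks=self.num_walks,
            dim=self.n_components,
            window=self.window,
            epochs=self.epochs,
            negative=self.negative,
            seed=self.random_state,
        )

    def fit(self, graph: nx.Graph, y=None):
        config = self._config()
        walks = generate_walks(graph, config)
        self.node_ids_, self.vectors_ = train_skipgram(
            walks,
            dim=config.dim,
            window=config.window,
            epochs=config.epochs,
            negative=config.negative,
            seed=config.seed,
        )
        self.embedding_ = {n: self.vectors_[i] for i, n in enumerate(self.node_ids_)}
        return self

    def transform(self, node_ids: Sequence[Hashable]) -> np.ndarray:
        """Vectors for the requested nodes; unwalked nodes get zero rows."""
        check_is_fitted(self, "embedding_")
        out = np.zeros((len(node_ids), self.n_components))
        missing = 0
        for i, node in enumerate(node_ids):
            vec = self.embedding_.get(node)
            if vec is None:
                missing += 1
            else:
                out[i] = vec
        if missing:
            logger.warning("%d node(s) missing from embedding; zero-filled", missing)
        return out

    def fit_transform(self, graph: nx.Graph, y=None) -> np.ndarray:
        self.fit(graph)
        return self.transform(self.node_ids_)
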