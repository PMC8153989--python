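"""One-layer graph-convolution feature propagation.

The association graph is encoded as a unified n x n adjacency A over
all drugs and diseases (bipartite: nonzero only between a drug and a
disease).  With a self-loop added, Ã = A + I, node attributes X are
propagated through a single randomly-initialized linear projection W
and a nonlinearity:

    simplified (default):  H = σ(Ã X W)
    normalized:            H = σ(D̃^{-1/2} Ã D̃^{-1/2} X W)

where D̃ is the degree matrix of Ã.  The projection is untrained: no
loss is defined for this stage, so it acts as a fixed, seeded random
graph filter that mixes each node's attributes with its neighbors'.
The seed is mandatory state and recorded alongside the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import AssociationTable

__all__ = [
    "UnifiedAdjacency",
    "build_adjacency",
    "init_weights",
    "gcn_propagate",
    "GraphConvolution",
]

_ACTIVATIONS = {
    "relu": lambda h: np.maximum(h, 0.0),
    "identity": lambda h: h,
    "tanh": np.tanh,
}
_MODES = ("simplified", "normalized")
_SCHEMES = ("glorot-uniform", "normal")


@dataclass(frozen=True)
class UnifiedAdjacency:
    """Unified bipartite adjacency with self-loops and degrees.

    ``A`` is symmetric with zero diagonal and zero within-type blocks;
    ``A_tilde = A + I``; ``degrees`` holds the diagonal of D̃ (row sums
    of Ã, all >= 1).
    """

    A: np.ndarray
    n_drugs: int
    n_diseases: int

    @property
    def A_tilde(self) -> np.ndarray:
        return self.A + np.eye(self.A.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        return self.A_tilde.sum(axis=1)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def build_adjacency(table: AssociationTable) -> UnifiedAdjacency:
    """Unified adjacency over drugs then diseases in canonical order."""
    n_d, n_z = table.n_drugs, table.n_diseases
    idx = table.node_index()
    A = np.zeros((n_d + n_z, n_d + n_z))
    for drug, disease in table.pairs:
        i, j = idx[drug], idx[disease]
        A[i, j] = A[j, i] = 1.0
    return UnifiedAdjacency(A, n_d, n_z)


def init_weights(
    k: int, m: int, seed: int, scheme: str = "glorot-uniform"
) -> np.ndarray:
    """Seeded random k x m projection matrix.

    ``glorot-uniform`` draws uniformly within +/- sqrt(6 / (k + m));
    ``normal`` draws standard normal entries scaled by 1/sqrt(k).
    """
    if k < 1 or m < 1:
        raise ValueError("weight dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    if scheme == "glorot-uniform":
        limit = np.sqrt(6.0 / (k + m))
        return rng.uniform(-limit, limit, size=(k, m))
    if scheme == "normal":
        return rng.standard_normal((k, m)) / np.sqrt(k)
    raise ValueError(f"unknown weight scheme {scheme!r}; options: {_SCHEMES}")


def gcn_propagate(
    adj: UnifiedAdjacency,
    X: np.ndarray,
    W: np.ndarray,
    mode: str = "simplified",
    activation: str = "relu",
) -> np.ndarray:
    """Propagate attributes X through one graph-convolution layer."""
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; options: {_MODES}")
    if activation not in _ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; options: {tuple(_ACTIVATIONS)}"
        )
    if X.shape[0] != adj.n_nodes:
        raise ValueError(f"X has {X.shape[0]} rows, graph has {adj.n_nodes} nodes")
    if W.shape[0] != X.shape[1]:
        raise ValueError(f"W rows ({W.shape[0]}) must equal X columns ({X.shape[1]})")
    a_tilde = adj.A_tilde
    if mode == "normalized":
        d_inv_sqrt = 1.0 / np.sqrt(adj.degrees)
        a_tilde = d_inv_sqrt[:, None] * a_tilde * d_inv_sqrt[None, :]
    return _ACTIVATIONS[activation](a_tilde @ X @ W)


class GraphConvolution(BaseEstimator, TransformerMixin):
    """Seeded one-layer graph-convolution featurizer.

    Parameters
    ----------
    n_components : int, default 64
        Output feature dimension m.
    mode : {"simplified", "normalized"}, default "simplified"
        Whether to symmetrically degree-normalize Ã before propagation.
    activation : {"relu", "identity", "tanh"}, default "relu"
    weight_init : {"glorot-uniform", "normal"}, default "glorot-uniform"
    random_state : int
        Seed for the random projection; required for reproducibility.

    Attributes
    ----------
    weights_ : ndarray of shape (k, n_components)
        The realized random projection.
    adjacency_ : UnifiedAdjacency
        Graph captured at fit time and reused by :meth:`transform`.
    """

    def __init__(
        self,
        n_components: int = 64,
        mode: str = "simplified",
        activation: str = "relu",
        weight_init: str = "glorot-uniform",
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.mode = mode
        self.activation = activation
        self.weight_init = weight_init
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, *, adjacency: UnifiedAdjacency):
        X = np.asarray(X, dtype=np.float64)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if X.ndim != 2 or X.shape[0] != adjacency.n_nodes:
            raise ValueError("X must be 2-D with one row per graph node")
        self.adjacency_ = adjacency
        self.n_features_in_ = X.shape[1]
        self.weights_ = init_weights(
            X.shape[1], self.n_components, self.random_state, self.weight_init
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return gcn_propagate(
            self.adjacency_, X, self.weights_, self.mode, self.activation
        )

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform(X)
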