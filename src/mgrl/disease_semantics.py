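"""Disease semantic similarity from MeSH-style tree numbers.

A disease annotated with tree numbers such as ``C04.557.337`` induces a
directed acyclic graph: every dot-prefix of every code is an ancestor
node, and edges connect each prefix to its one-component extension.
Each ancestor ``t`` contributes to the disease's semantics with a value
decayed by a factor ``mu`` per edge on the best downward path to one of
the disease's own codes:

    D_a(a) = 1
    D_a(t) = max { mu * D_a(t') : t' a child of t in the DAG }

The semantic value DV(a) is the sum of all contributions, and the
similarity of two diseases is the Wang-style overlap ratio

    Sim(a, b) = sum_{t in T_a ∩ T_b} (D_a(t) + D_b(t)) / (DV(a) + DV(b)),

which is 1 for identical annotation sets, 0 for disjoint ones, and
symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "DiseaseDAG",
    "build_dag",
    "semantic_contribution",
    "semantic_value",
    "disease_similarity",
    "similarity_matrix",
    "DiseaseSemanticSimilarity",
]

DEFAULT_MU = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor DAG of one disease.

    ``nodes`` holds every dot-prefix of every tree number (ancestors
    including the codes themselves); ``edges`` are (parent, child)
    prefix extensions; ``own`` are the disease's own full codes, which
    anchor the contribution recursion at 1.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    own: frozenset[str]


def build_dag(tree_numbers: Sequence[str], disease_id: str = "") -> DiseaseDAG:
    """Expand tree numbers into the disease's ancestor DAG.

    ``C04.557.337`` contributes nodes ``C04``, ``C04.557`` and
    ``C04.557.337`` and the two chained edges between them; shared
    prefixes across codes are deduplicated.
    """
    if not tree_numbers:
        raise ValueError(f"disease {disease_id!r}: no tree numbers given")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for code in tree_numbers:
        parts = code.split(".")
        prefix = parts[0]
        nodes.add(prefix)
        for part in parts[1:]:
            child = prefix + "." + part
            nodes.add(child)
            edges.add((prefix, child))
            prefix = child
    return DiseaseDAG(disease_id, frozenset(nodes), frozenset(edges), frozenset(tree_numbers))


def semantic_contribution(dag: DiseaseDAG, mu: float = DEFAULT_MU) -> dict[str, float]:
    """Contribution of every DAG node, by reverse-topological dynamic programming.

    The disease's own codes are pinned at 1; every other node takes the
    max over its children of ``mu`` times the child's contribution.
    """
    if not 0 < mu < 1:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError(f"disease {dag.disease_id!r}: DAG contains a cycle") from exc
    contrib: dict[str, float] = {}
    for node in reversed(order):
        if node in dag.own:
            contrib[node] = 1.0
            continue
        children = [contrib[c] for c in g.successors(node)]
        if not children:
            raise ValueError(
                f"disease {dag.disease_id!r}: node {node!r} has no path to an own code"
            )
        contrib[node] = mu * max(children)
    return contrib


def semantic_value(contributions: Mapping[str, float]) -> float:
    """DV(a): the sum of all ancestor contributions (>= 1)."""
    if not contributions:
        raise ValueError("empty contribution map")
    return float(sum(contributions.values()))


def disease_similarity(
    contrib_a: Mapping[str, float], contrib_b: Mapping[str, float]
) -> float:
    """Overlap-ratio similarity of two contribution maps, in [0, 1]."""
    if not contrib_a or not contrib_b:
        raise ValueError("empty contribution map")
    shared = contrib_a.keys() & contrib_b.keys()
    if not shared:
        return 0.0
    num = sum(contrib_a[t] + contrib_b[t] for t in shared)
    return float(num / (semantic_value(contrib_a) + semantic_value(contrib_b)))


def similarity_matrix(
    tree_numbers: Mapping[str, Sequence[str]], mu: float = DEFAULT_MU
) -> tuple[list[str], np.ndarray]:
    """Pairwise similarity over all diseases, in canonical (sorted) order.

    Returns the sorted disease ids and the symmetric matrix with unit
    diagonal.  DAG construction errors are re-raised with the disease
    id attached.
    """
    if not tree_numbers:
        raise ValueError("no diseases given")
    disease_ids = sorted(tree_numbers)
    contribs = []
    for disease_id in disease_ids:
        try:
            dag = build_dag(tree_numbers[disease_id], disease_id)
            contribs.append(semantic_contribution(dag, mu))
        except ValueError as exc:
            raise ValueError(f"disease {disease_id!r}: {exc}") from exc
    n = len(disease_ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = disease_similarity(contribs[i], contribs[j])
    return disease_ids, sim


class DiseaseSemanticSimilarity(BaseEstimator):
    """Estimator wrapper computing the disease-similarity matrix.

    Parameters
    ----------
    mu : float, default 0.5
        Semantic contribution decay per DAG edge; the Wang-measure
        convention.

    Attributes
    ----------
    disease_ids_ : list of str
        Sorted disease identifiers (canonical order).
    similarity_ : ndarray of shape (n_diseases, n_diseases)
        Symmetric similarity matrix with unit diagonal.
    """

    def __init__(self, mu: float = DEFAULT_MU):
        self.mu = mu

    def fit(self, tree_numbers: Mapping[str, Sequence[str]], y=None):
        self.disease_ids_, self.similarity_ = similarity_matrix(tree_numbers, self.mu)
        return self

    def fit_transform(self, tree_numbers: Mapping[str, Sequence[str]], y=None) -> np.ndarray:
        return self.fit(tree_numbers).similarity_
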