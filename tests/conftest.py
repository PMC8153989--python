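"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by the most direct
method available (path enumeration, O(n^2) pair counting, explicit
dense products) so they share no code path with the implementation
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mgrl.disease_semantics import similarity_matrix
from mgrl.drug_features import build_attribute_matrix
from mgrl.synthetic import CANONICAL_SPEC, simulate_attributes, simulate_network


# ---------------------------------------------------------------- oracles


def oracle_contribution(nodes, edges, own, mu):
    """Contribution by exhaustive downward path enumeration.

    D(t) = max over all directed paths from t to one of the disease's
    own codes of mu^(path length); own codes themselves give 1.
    """
    children = {}
    for parent, child in edges:
        children.setdefault(parent, []).append(child)

    def best(t, visited):
        value = 1.0 if t in own else -np.inf
        for c in children.get(t, []):
            if c in visited:
                continue
            sub = best(c, visited | {c})
            if sub > -np.inf:
                value = max(value, mu * sub)
        return value

    return {t: best(t, {t}) for t in nodes}


def oracle_similarity(contrib_a, contrib_b):
    shared = set(contrib_a) & set(contrib_b)
    if not shared:
        return 0.0
    num = sum(contrib_a[t] + contrib_b[t] for t in shared)
    return num / (sum(contrib_a.values()) + sum(contrib_b.values()))


def oracle_auc(labels, scores):
    """O(P*N) pairwise count with half credit for score ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_average_precision(labels, scores):
    """Step integration of the precision-recall curve, ties grouped."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    scores = scores[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        block_tp = int(labels[i:j].sum())
        prev_recall = tp / n_pos
        tp += block_tp
        fp += (j - i) - block_tp
        precision = tp / (tp + fp)
        ap += (tp / n_pos - prev_recall) * precision
        i = j
    return ap


def oracle_confusion_metrics(labels, scores, threshold=0.5):
    """Direct confusion-table arithmetic for the thresholded rates."""
    labels = np.asarray(labels).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "acc": (tp + tn) / (tp + tn + fp + fn),
        "sen": tp / (tp + fn) if tp + fn else 0.0,
        "spec": tn / (tn + fp) if tn + fp else 0.0,
        "prec": tp / (tp + fp) if tp + fp else 0.0,
        "mcc": (tp * tn - fp * fn) / den if den else 0.0,
    }


def random_tree_numbers(rng, max_codes=3, max_depth=3, roots=("A1", "B2", "C3")):
    """Random tree-number set producing a small ancestor DAG (<= ~8 nodes)."""
    n_codes = int(rng.integers(1, max_codes + 1))
    codes = set()
    for _ in range(n_codes):
        root = roots[int(rng.integers(len(roots)))]
        depth = int(rng.integers(0, max_depth + 1))
        parts = [root] + [str(int(rng.integers(10, 13))) for _ in range(depth)]
        codes.add(".".join(parts))
    return sorted(codes)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def canonical_benchmark():
    """Canonical planted-block fixture: table, attributes X, blocks."""
    table, drug_blocks, disease_blocks = simulate_network(CANONICAL_SPEC)
    (drug_ids, bits), trees = simulate_attributes(
        CANONICAL_SPEC, drug_blocks, disease_blocks
    )
    disease_ids, sim = similarity_matrix(trees)
    X, layout = build_attribute_matrix(drug_ids, bits, disease_ids, sim)
    return {
        "table": table,
        "X": X,
        "layout": layout,
        "drug_blocks": drug_blocks,
        "disease_blocks": disease_blocks,
        "tree_numbers": trees,
        "similarity": sim,
        "fingerprints": (drug_ids, bits),
    }
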