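"""End-to-end orchestration: attributes -> representations -> evaluation.

Two evaluation regimes are available and always labeled in reports:

* transductive (default): graph-convolution features and walk
  embeddings are computed once on the full association graph, then the
  labeled pairs are cross-validated.  Test edges participate in
  representation learning, which inflates scores; this matches the
  single-pass workflow the method describes.
* leakage-safe: representations are recomputed inside every fold from
  the training positives only, so no test edge influences any feature.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .disease_semantics import similarity_matrix
from .drug_features import build_attribute_matrix, fingerprint_matrix
from .evaluate import (
    METRIC_NAMES,
    compute_metrics,
    cross_validate,
    fuse_features,
    make_classifier,
    rank_candidates,
    sample_negatives,
)
from .gcn import GraphConvolution, UnifiedAdjacency, build_adjacency
from .io import (
    AssociationTable,
    read_associations,
    read_fingerprint_table,
    read_smiles_table,
    read_tree_numbers,
    write_embeddings,
    write_similarity_matrix,
)
from .walks import Node2Vec

__all__ = [
    "RunConfig",
    "adjacency_from_pairs",
    "association_graph",
    "compute_representations",
    "evaluate_associations",
    "run_pipeline",
]


def adjacency_from_pairs(
    pairs: Sequence[tuple[str, str]],
    drug_ids: Sequence[str],
    disease_ids: Sequence[str],
) -> UnifiedAdjacency:
    """Unified adjacency over a fixed node universe from a pair subset.

    Unlike :func:`mgrl.gcn.build_adjacency` the node sets are given, so
    nodes with no pair in ``pairs`` keep an (isolated) row — needed for
    per-fold recomputation where train edges may not cover every node.
    """
    n_d, n_z = len(drug_ids), len(disease_ids)
    idx = {d: i for i, d in enumerate(drug_ids)}
    idx.update({z: n_d + j for j, z in enumerate(disease_ids)})
    A = np.zeros((n_d + n_z, n_d + n_z))
    for drug, disease in pairs:
        i, j = idx[drug], idx[disease]
        A[i, j] = A[j, i] = 1.0
    return UnifiedAdjacency(A, n_d, n_z)


def association_graph(
    pairs: Sequence[tuple[str, str]],
    drug_ids: Sequence[str],
    disease_ids: Sequence[str],
) -> nx.Graph:
    """networkx view of the bipartite graph, all nodes present."""
    g = nx.Graph()
    g.add_nodes_from(drug_ids)
    g.add_nodes_from(disease_ids)
    g.add_edges_from(pairs)
    return g


def compute_representations(
    pairs: Sequence[tuple[str, str]],
    drug_ids: Sequence[str],
    disease_ids: Sequence[str],
    X: np.ndarray,
    gcn_dim: int = 64,
    gcn_mode: str = "simplified",
    walk_params: Mapping | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Both node representations (H, E) from an edge set.

    H: one-layer graph-convolution features, seeded random projection.
    E: node2vec embedding rows aligned to canonical node order; nodes
    untouched by any walk (isolated under ``pairs``) get zero rows.
    """
    adj = adjacency_from_pairs(pairs, drug_ids, disease_ids)
    gc = GraphConvolution(
        n_components=gcn_dim, mode=gcn_mode, random_state=seed
    )
    H = gc.fit_transform(X, adjacency=adj)
    graph = association_graph(pairs, drug_ids, disease_ids)
    n2v = Node2Vec(random_state=seed, **dict(walk_params or {}))
    n2v.fit(graph)
    E = n2v.transform(list(drug_ids) + list(disease_ids))
    return H, E


def evaluate_associations(
    table: AssociationTable,
    X: np.ndarray,
    mode: str = "fused",
    leakage_safe: bool = False,
    negative_ratio: float = 1.0,
    n_folds: int = 5,
    classifier: str = "rf",
    gcn_dim: int = 64,
    gcn_mode: str = "simplified",
    walk_params: Mapping | None = None,
    seed: int = 0,
    classifier_params: Mapping | None = None,
    representations: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Cross-validated link-prediction report for one feature mode.

    Stage seeds are derived from the single run seed (negatives:
    seed; representations: seed + 1; folds and classifier: seed).
    ``representations`` may carry precomputed transductive (H, E) to
    avoid recomputation; it is ignored in leakage-safe mode, which
    must rebuild per fold.
    """
    node_index = table.node_index()
    drug_ids, disease_ids = table.drug_ids, table.disease_ids
    labeled = sample_negatives(table, negative_ratio, seed)
    rep_seed = seed + 1

    if not leakage_safe:
        if representations is not None:
            H, E = representations
        else:
            H, E = compute_representations(
                table.pairs, drug_ids, disease_ids, X,
                gcn_dim, gcn_mode, walk_params, rep_seed,
            )
        F = fuse_features(labeled.pairs, node_index, H, E, mode)
        report = cross_validate(
            F, labeled.labels, n_folds, classifier, seed,
            classifier_params=classifier_params,
        )
    else:
        labels = labeled.labels.astype(int)
        pairs = list(labeled.pairs)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = []
        dummy = np.zeros(len(pairs))
        for fold_id, (train_idx, test_idx) in enumerate(skf.split(dummy, labels)):
            train_pos = [pairs[i] for i in train_idx if labels[i] == 1]
            H, E = compute_representations(
                train_pos, drug_ids, disease_ids, X,
                gcn_dim, gcn_mode, walk_params, rep_seed,
            )
            F_train = fuse_features(
                [pairs[i] for i in train_idx], node_index, H, E, mode
            )
            F_test = fuse_features(
                [pairs[i] for i in test_idx], node_index, H, E, mode
            )
            model = make_classifier(classifier, seed, **dict(classifier_params or {}))
            model.fit(F_train, labels[train_idx])
            scores = model.predict_proba(F_test)[:, 1]
            metrics = compute_metrics(labels[test_idx], scores)
            folds.append({"fold": fold_id, "n_test": int(len(test_idx)), **metrics})
        mean = {m: float(np.mean([f[m] for f in folds])) for m in METRIC_NAMES}
        std = {m: float(np.std([f[m] for f in folds])) for m in METRIC_NAMES}
        report = {
            "config": {
                "classifier": classifier,
                "classifier_params": dict(classifier_params or {}),
                "n_folds": n_folds,
                "seed": seed,
                "threshold": 0.5,
            },
            "folds": folds,
            "mean": mean,
            "std": std,
        }
    report["config"].update(
        {
            "feature_mode": mode,
            "leakage_safe": leakage_safe,
            "negative_ratio": negative_ratio,
            "representation_seed": rep_seed,
            "gcn_dim": gcn_dim,
            "gcn_mode": gcn_mode,
            "walk_params": dict(walk_params or {}),
            "n_drugs": table.n_drugs,
            "n_diseases": table.n_diseases,
            "n_positives": len(table.pairs),
        }
    )
    return report


_KNOWN_KEYS = {
    "associations", "smiles", "fingerprints", "tree_numbers", "outdir",
    "mu", "radius", "n_bits", "gcn_dim", "gcn_mode", "walk_params",
    "feature_mode", "leakage_safe", "negative_ratio", "n_folds",
    "classifier", "classifier_params", "seed", "rank_drug", "top_k",
}


@dataclass
class RunConfig:
    """Resolved configuration of one full pipeline run."""

    associations: str
    tree_numbers: str
    outdir: str
    smiles: str | None = None
    fingerprints: str | None = None
    mu: float = 0.5
    radius: int = 2
    n_bits: int = 1024
    gcn_dim: int = 64
    gcn_mode: str = "simplified"
    walk_params: dict = field(default_factory=dict)
    feature_mode: str = "fused"
    leakage_safe: bool = False
    negative_ratio: float = 1.0
    n_folds: int = 5
    classifier: str = "rf"
    classifier_params: dict = field(default_factory=dict)
    seed: int = 0
    rank_drug: str | None = None
    top_k: int = 10

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for path_key in ("associations", "tree_numbers"):
            p = getattr(self, path_key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config {path_key!r}: missing file {p!r}")
        if self.smiles is None and self.fingerprints is None:
            raise ValueError("config needs either 'smiles' or 'fingerprints'")
        src = self.smiles if self.smiles is not None else self.fingerprints
        if not Path(src).exists():
            raise FileNotFoundError(f"drug attribute file missing: {src!r}")


def _load_attribute_matrix(config: RunConfig, table: AssociationTable):
    """Attributes X restricted and aligned to the association node order."""
    if config.smiles is not None:
        smiles = read_smiles_table(config.smiles)
        missing = [d for d in table.drug_ids if d not in smiles]
        if missing:
            raise ValueError(f"drugs without SMILES: {missing[:5]}")
        drug_ids, fps = fingerprint_matrix(
            {d: smiles[d] for d in table.drug_ids}, config.radius, config.n_bits
        )
    else:
        all_ids, all_fps = read_fingerprint_table(config.fingerprints)
        pos = {d: i for i, d in enumerate(all_ids)}
        missing = [d for d in table.drug_ids if d not in pos]
        if missing:
            raise ValueError(f"drugs without fingerprints: {missing[:5]}")
        drug_ids = list(table.drug_ids)
        fps = all_fps[[pos[d] for d in drug_ids]]
    trees = read_tree_numbers(config.tree_numbers)
    missing = [z for z in table.disease_ids if z not in trees]
    if missing:
        raise ValueError(f"diseases without tree numbers: {missing[:5]}")
    disease_ids, sim = similarity_matrix(
        {z: trees[z] for z in table.disease_ids}, config.mu
    )
    X, layout = build_attribute_matrix(drug_ids, fps, disease_ids, sim)
    return X, layout, (disease_ids, sim)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and persist every intermediate.

    Writes into ``config.outdir``: the resolved config snapshot, the
    disease-similarity matrix, the walk embedding, the evaluation
    report (JSON) and, when ``rank_drug`` is set, the top-k candidate
    ranking.  Reruns with an identical config produce byte-identical
    outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    table = read_associations(config.associations)
    X, layout, (disease_ids, sim) = _load_attribute_matrix(config, table)
    write_similarity_matrix(disease_ids, sim, outdir / "disease_similarity.tsv")

    H, E = compute_representations(
        table.pairs, table.drug_ids, table.disease_ids, X,
        config.gcn_dim, config.gcn_mode, config.walk_params, config.seed + 1,
    )
    node_ids = list(table.drug_ids) + list(table.disease_ids)
    write_embeddings(node_ids, E, outdir / "embeddings.txt")
    write_embeddings(node_ids, H, outdir / "gcn_features.tsv")

    report = evaluate_associations(
        table, X,
        mode=config.feature_mode,
        leakage_safe=config.leakage_safe,
        negative_ratio=config.negative_ratio,
        n_folds=config.n_folds,
        classifier=config.classifier,
        gcn_dim=config.gcn_dim,
        gcn_mode=config.gcn_mode,
        walk_params=config.walk_params,
        seed=config.seed,
        classifier_params=config.classifier_params,
        representations=None if config.leakage_safe else (H, E),
    )
    report["config"]["attribute_layout"] = dataclasses.asdict(layout)

    if config.rank_drug is not None:
        labeled = sample_negatives(table, config.negative_ratio, config.seed)
        F = fuse_features(
            labeled.pairs, table.node_index(), H, E, config.feature_mode
        )
        model = make_classifier(
            config.classifier, config.seed, **config.classifier_params
        )
        model.fit(F, labeled.labels.astype(int))
        ranking = rank_candidates(
            config.rank_drug, model, table, table.node_index(),
            H, E, config.feature_mode, config.top_k,
        )
        with open(outdir / "ranking.tsv", "w") as fh:
            fh.write("# disease_id\tscore\n")
            for z, s in ranking:
                fh.write(f"{z}\t{s:.12g}\n")
        report["ranking"] = {"drug": config.rank_drug, "top": ranking}

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
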