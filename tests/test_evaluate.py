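"""Negative sampling, feature fusion, metrics and cross-validation."""

import numpy as np
import pytest

from mgrl.evaluate import (
    MGRLClassifier,
    compute_metrics,
    cross_validate,
    fuse_features,
    make_classifier,
    rank_candidates,
    sample_negatives,
)
from mgrl.io import AssociationTable

from conftest import oracle_auc, oracle_average_precision, oracle_confusion_metrics


def table(*pairs):
    return AssociationTable.from_pairs(list(pairs))


class TestSampleNegatives:
    def test_forced_complement(self):
        t = table(("d1", "z1"), ("d2", "z2"))
        labeled = sample_negatives(t, ratio=1.0, seed=0)
        negatives = {p for p, y in zip(labeled.pairs, labeled.labels) if y == 0}
        assert negatives == {("d1", "z2"), ("d2", "z1")}

    def test_negatives_disjoint_from_positives(self):
        t = table(*[(f"d{i}", f"z{j}") for i in range(5) for j in range(8) if (i + j) % 3 == 0])
        labeled = sample_negatives(t, ratio=1.0, seed=3)
        pos = {p for p, y in zip(labeled.pairs, labeled.labels) if y == 1}
        neg = {p for p, y in zip(labeled.pairs, labeled.labels) if y == 0}
        assert pos == set(t.pairs)
        assert not pos & neg
        assert len(neg) == len(pos)

    def test_seed_determinism(self):
        t = table(*[(f"d{i}", f"z{j}") for i in range(4) for j in range(6) if (i + 2 * j) % 5 == 0])
        a = sample_negatives(t, 1.0, 9)
        b = sample_negatives(t, 1.0, 9)
        assert a.pairs == b.pairs

    def test_oversampling_rejected(self):
        t = table(("d1", "z1"), ("d1", "z2"), ("d2", "z1"))
        with pytest.raises(ValueError, match="unobserved"):
            sample_negatives(t, ratio=10.0, seed=0)


class TestFuseFeatures:
    def setup_method(self):
        self.t = table(("d1", "z1"), ("d2", "z2"))
        self.idx = self.t.node_index()
        rng = np.random.default_rng(0)
        self.H = rng.standard_normal((4, 3))
        self.E = rng.standard_normal((4, 5))

    def test_fused_width(self):
        F = fuse_features(self.t.pairs, self.idx, self.H, self.E, "fused")
        assert F.shape == (2, 2 * 3 + 2 * 5)

    def test_embedding_only_width_and_layout(self):
        F = fuse_features([("d1", "z1")], self.idx, self.H, self.E, "embedding")
        np.testing.assert_array_equal(
            F[0], np.concatenate([self.E[self.idx["d1"]], self.E[self.idx["z1"]]])
        )

    def test_fused_layout_order(self):
        F = fuse_features([("d2", "z1")], self.idx, self.H, self.E, "fused")
        i, j = self.idx["d2"], self.idx["z1"]
        np.testing.assert_array_equal(
            F[0], np.concatenate([self.H[i], self.H[j], self.E[i], self.E[j]])
        )

    def test_duplicate_pair_identical_rows(self):
        F = fuse_features([("d1", "z2"), ("d1", "z2")], self.idx, self.H, self.E)
        np.testing.assert_array_equal(F[0], F[1])

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            fuse_features([("dX", "z1")], self.idx, self.H, self.E)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="feature mode"):
            fuse_features(self.t.pairs, self.idx, self.H, self.E, "everything")


class TestComputeMetrics:
    def test_worked_confusion_example(self):
        # TP=3, TN=2, FP=1, FN=0
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.6, 0.2, 0.1]
        m = compute_metrics(labels, scores, threshold=0.5)
        assert m["acc"] == pytest.approx(5 / 6, abs=1e-4)
        assert m["sen"] == 1.0
        assert m["spec"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["prec"] == 0.75
        assert m["mcc"] == pytest.approx(0.7071, abs=1e-4)

    def test_perfect_separation(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m["auc"] == 1.0 and m["mcc"] == 1.0 and m["aupr"] == 1.0

    def test_constant_scores_auc_half(self):
        m = compute_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert m["auc"] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([1, 1, 1], [0.1, 0.5, 0.9])

    def test_inverted_predictions_mcc_minus_one(self):
        m = compute_metrics([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert m["mcc"] == -1.0 and m["auc"] == 0.0

    def test_flip_symmetry(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        m = compute_metrics(labels, scores)
        m_flip = compute_metrics(1 - labels, 1.0 - scores + 1e-12)
        assert m_flip["mcc"] == pytest.approx(m["mcc"], abs=1e-9)

    def test_matches_brute_force_oracle(self):
        # moderate sweep here; the full 1,000-vector sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            labels = rng.integers(0, 2, n)
            labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), int(rng.integers(1, 4)))
            m = compute_metrics(labels, scores)
            assert m["auc"] == pytest.approx(oracle_auc(labels, scores), abs=1e-10)
            assert m["aupr"] == pytest.approx(
                oracle_average_precision(labels, scores), abs=1e-10
            )
            for key, val in oracle_confusion_metrics(labels, scores).items():
                assert m[key] == pytest.approx(val, abs=1e-10)


class TestCrossValidate:
    def test_leaky_feature_gives_perfect_auc(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        F = np.column_stack([rng.standard_normal((200, 3)), y])
        report = cross_validate(F, y, n_folds=5, seed=0)
        assert report["mean"]["auc"] == 1.0

    def test_noise_features_near_chance(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 150)
        F = rng.standard_normal((300, 8))
        report = cross_validate(F, y, n_folds=5, seed=1)
        assert report["mean"]["auc"] == pytest.approx(0.5, abs=0.08)

    def test_folds_partition_pairs(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 40)
        F = rng.standard_normal((80, 4))
        report = cross_validate(F, y, n_folds=5, seed=0)
        assert sum(f["n_test"] for f in report["folds"]) == 80
        assert len(report["folds"]) == 5
        for metric, mean in report["mean"].items():
            lo = min(f[metric] for f in report["folds"])
            hi = max(f[metric] for f in report["folds"])
            assert lo - 1e-12 <= mean <= hi + 1e-12

    def test_unknown_classifier_lists_options(self):
        with pytest.raises(ValueError, match="rf"):
            make_classifier("quantum")

    @pytest.mark.parametrize("name", ["svm", "logistic", "knn", "gbdt"])
    def test_alternative_classifiers_run(self, name):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 30)
        F = rng.standard_normal((60, 4)) + y[:, None]
        report = cross_validate(F, y, n_folds=3, classifier=name, seed=0)
        assert 0.5 < report["mean"]["auc"] <= 1.0


class TestRanking:
    def _fitted(self):
        t = table(("d1", "z1"), ("d1", "z2"), ("d2", "z3"), ("d2", "z4"),
                  ("d3", "z1"), ("d3", "z5"))
        idx = t.node_index()
        rng = np.random.default_rng(0)
        H = rng.standard_normal((t.n_nodes, 4))
        E = rng.standard_normal((t.n_nodes, 4))
        labeled = sample_negatives(t, 1.0, 0)
        F = fuse_features(labeled.pairs, idx, H, E)
        model = make_classifier("rf", 0, n_estimators=30)
        model.fit(F, labeled.labels.astype(int))
        return t, idx, H, E, model

    def test_top_k_and_exclusion(self):
        t, idx, H, E, model = self._fitted()
        ranking = rank_candidates("d1", model, t, idx, H, E, top_k=2)
        assert len(ranking) == 2
        assert not {z for z, _ in ranking} & {"z1", "z2"}

    def test_scores_descending(self):
        t, idx, H, E, model = self._fitted()
        ranking = rank_candidates("d2", model, t, idx, H, E, top_k=10)
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)

    def test_fully_connected_drug_empty(self):
        t = table(("d1", "z1"), ("d1", "z2"), ("d1", "z3"), ("d2", "z1"))
        idx = t.node_index()
        H = np.zeros((t.n_nodes, 2))
        E = np.zeros((t.n_nodes, 2))
        labeled = sample_negatives(t, 0.5, 0)
        F = fuse_features(labeled.pairs, idx, H, E)
        model = make_classifier("rf", 0, n_estimators=10)
        model.fit(F, labeled.labels.astype(int))
        assert rank_candidates("d1", model, t, idx, H, E) == []


def test_mgrl_classifier_estimator():
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1], 25)
    F = rng.standard_normal((50, 3)) + 2 * y[:, None]
    clf = MGRLClassifier(classifier="rf", random_state=0, n_estimators=50)
    clf.fit(F, y)
    proba = clf.predict_proba(F)
    assert proba.shape == (50, 2)
    assert (clf.predict(F) == y).mean() > 0.9
    assert clf.get_params()["n_estimators"] == 50
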