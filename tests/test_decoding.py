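"""LOPO classifier, evidence, accuracy, contiguity null, network selection."""

import numpy as np
import pytest

from palace.decoding import (
    ClassifierSpec,
    contiguity_null,
    predict_evidence,
    reinstatement_scores,
    score_accuracy,
    select_network,
    train_classifier,
)
from palace.templates import TemplateSet


def make_templates(patterns, pid="sub-01", kind="object"):
    return TemplateSet(patterns=np.asarray(patterns, float), class_kind=kind,
                       participant_id=pid, run_scope="joint")


class TestTrainClassifier:
    def test_separable_two_class(self, rng):
        spec = ClassifierSpec(n_classes=2)
        base = np.array([[5.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
        sets = [make_templates(base + 0.01 * rng.standard_normal((2, 3)), f"s{i}")
                for i in range(2)]
        clf = train_classifier(sets, spec)
        proba = clf.predict_proba(base)
        assert np.argmax(proba, axis=1).tolist() == [0, 1]  # training acc 1.0
        assert proba[0, 0] > 0.5

    def test_uninformative_features_near_uniform(self):
        spec = ClassifierSpec(n_classes=23, feature_standardization=False)
        same = np.ones((23, 10))
        sets = [make_templates(same, f"s{i}") for i in range(3)]
        clf = train_classifier(sets, spec)
        proba = clf.predict_proba(np.ones((5, 10)))
        assert np.allclose(proba, 1 / 23, atol=1e-3)

    def test_deterministic(self, rng):
        spec = ClassifierSpec(n_classes=4)
        sets = [make_templates(rng.standard_normal((4, 6)), f"s{i}")
                for i in range(3)]
        a = train_classifier(sets, spec).model.coef_
        b = train_classifier(sets, spec).model.coef_
        assert np.array_equal(a, b)

    def test_missing_class_rejected(self, rng):
        spec = ClassifierSpec(n_classes=5)
        ts = TemplateSet(
            patterns=rng.standard_normal((4, 6)), class_kind="object",
            participant_id="a", run_scope="joint", condition_ids=np.arange(4),
        )
        with pytest.raises(ValueError, match="missing"):
            train_classifier([ts, ts], spec)


class TestPredictEvidence:
    def _clf(self, rng, n_classes=3, n_feat=4):
        # 3+ classes: sklearn switches to a sigmoid parameterization for 2
        if n_classes < 3:
            n_classes = 3
        spec = ClassifierSpec(n_classes=n_classes, feature_standardization=False)
        sets = [make_templates(rng.standard_normal((n_classes, n_feat)), f"s{i}")
                for i in range(2)]
        return train_classifier(sets, spec)

    def test_rows_sum_to_one(self, rng):
        clf = self._clf(rng)
        P = predict_evidence(clf, rng.standard_normal((20, 4)), hrf_shift_tr=4)
        assert P.shape == (16, 3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_shift_identity_alignment(self, rng):
        clf = self._clf(rng)
        x = rng.standard_normal((10, 4))
        P0 = predict_evidence(clf, x, hrf_shift_tr=0)
        P4 = predict_evidence(clf, x, hrf_shift_tr=4)
        assert np.allclose(P0[4:], P4)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_softmax_oracle(self, trial):
        rng = np.random.default_rng(trial)
        clf = self._clf(rng, n_classes=int(rng.integers(3, 8)))
        W, b = clf.model.coef_, clf.model.intercept_
        x = rng.standard_normal((6, 4))
        P = predict_evidence(clf, x, hrf_shift_tr=0)
        logits = x @ W.T + b
        expected = np.exp(logits - logits.max(axis=1, keepdims=True))
        expected /= expected.sum(axis=1, keepdims=True)
        assert np.max(np.abs(P - expected)) < 1e-8

    def test_too_short_rejected(self, rng):
        clf = self._clf(rng)
        with pytest.raises(ValueError, match="shorter"):
            predict_evidence(clf, rng.standard_normal((3, 4)), hrf_shift_tr=4)


class TestScoreAccuracy:
    def test_one_hot_perfect(self):
        labels = np.array([0, 1, 2, -1, 1])
        P = np.zeros((5, 3))
        P[np.arange(5), np.where(labels >= 0, labels, 0)] = 1.0
        assert score_accuracy(P, labels) == 1.0

    def test_uniform_ties_resolve_to_class_zero(self):
        labels = np.array([0, 1, 0, 2, -1])
        P = np.full((5, 3), 1 / 3)
        assert score_accuracy(P, labels) == pytest.approx(2 / 4)

    def test_hand_counted_toy(self):
        P = np.array(
            [[0.5, 0.3, 0.2], [0.1, 0.8, 0.1], [0.2, 0.3, 0.5],
             [0.6, 0.2, 0.2], [0.3, 0.4, 0.3]]
        )
        labels = np.array([0, 1, 1, 2, 1])  # predictions: 0,1,2,0,1 -> 3 hits
        assert score_accuracy(P, labels) == pytest.approx(3 / 5)

    def test_no_labeled_trs_nan(self):
        assert np.isnan(score_accuracy(np.ones((3, 2)) / 2, np.full(3, -1)))


class TestContiguityNull:
    def test_uniform_evidence_constant_null(self):
        labels = np.repeat([0, 1, 2], 5)
        P = np.full((15, 3), 1 / 3)
        null = contiguity_null(labels, P, n_perm=50, seed=0)
        # argmax ties -> class 0; accuracy = fraction of TRs relabeled 0 = 1/3
        assert np.allclose(null, 1 / 3)

    def test_perfect_evidence_null_mean_matches_analytic(self):
        n_classes = 23
        labels = np.repeat(np.arange(n_classes), 4)
        P = np.zeros((len(labels), n_classes))
        P[np.arange(len(labels)), labels] = 1.0
        null = contiguity_null(labels, P, n_perm=3000, seed=1)
        # expected fixed-point fraction of a uniform permutation = 1/23
        se = np.sqrt((1 / 23) * (22 / 23) / 23 / 3000) * 23  # generous bound
        assert abs(null.mean() - 1 / 23) < 5e-3 + se

    def test_deterministic_per_seed(self, rng):
        labels = np.repeat([0, 1, 2, 3], 4)
        P = rng.dirichlet(np.ones(4), size=16)
        a = contiguity_null(labels, P, n_perm=100, seed=7)
        b = contiguity_null(labels, P, n_perm=100, seed=7)
        assert np.array_equal(a, b)

    def test_single_segment_rejected(self):
        labels = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="segments"):
            contiguity_null(labels, np.ones((10, 2)) / 2, n_perm=10, seed=0)

    def test_preserves_segment_structure(self, rng):
        # null accuracies only take values reachable by relabeling segments
        labels = np.array([0, 0, 0, 1, 1, -1, 2, 2, 2, 2])
        P = rng.dirichlet(np.ones(3), size=10)
        pred = np.argmax(P, axis=1)
        null = contiguity_null(labels, P, n_perm=200, seed=3)
        counts = {
            s: np.bincount(pred[sl], minlength=3)
            for s, sl in enumerate([slice(0, 3), slice(3, 5), slice(6, 10)])
        }
        from itertools import permutations

        reachable = {
            sum(counts[s][p[s]] for s in range(3)) / 9
            for p in permutations(range(3))
        }
        assert set(np.round(null, 12)) <= {round(v, 12) for v in reachable}


class TestSelectNetwork:
    def test_k_equals_candidates_selects_all(self, rng):
        true = rng.uniform(0, 1, 8)
        null = rng.uniform(0, 1, (8, 100))
        net = select_network(true, null, k=8)
        assert net.members.tolist() == list(range(8))

    def test_planted_units_recovered(self, rng):
        n = 60
        true = np.full(n, 0.05)
        planted = rng.choice(n, size=12, replace=False)
        true[planted] = 0.6
        null = 0.05 + rng.normal(0, 0.01, (n, 200))
        net = select_network(true, null, k=12)
        assert set(net.members.tolist()) == set(planted.tolist())

    def test_default_k_is_fifty(self, rng):
        true = rng.uniform(0, 1, 60)
        null = rng.uniform(0, 1, (60, 50))
        assert select_network(true, null).k == 50

    def test_zero_sd_unit_excluded(self, rng):
        true = np.array([0.9, 0.5, 0.4])
        null = rng.uniform(0, 0.2, (3, 50))
        null[0] = 0.1  # degenerate null
        with pytest.warns(UserWarning, match="zero null sd"):
            net = select_network(true, null, k=2)
        assert 0 not in net.members.tolist()


class TestReinstatementScores:
    def test_uniform_evidence(self):
        P = np.full((10, 4), 0.25)
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3, -1, -1])
        scores = reinstatement_scores([P], [labels], 4)
        assert np.allclose(scores, 0.25)

    def test_one_hot_evidence(self):
        labels = np.array([0, 1, 2, -1])
        P = np.zeros((4, 3))
        P[[0, 1, 2], [0, 1, 2]] = 1.0
        assert np.allclose(reinstatement_scores([P], [labels], 3), 1.0)

    def test_pooled_mean_not_mean_of_run_means(self, rng):
        # two runs, unequal TR counts and different means for class 0
        P1 = np.zeros((2, 2)); P1[:, 0] = 0.9
        P2 = np.zeros((6, 2)); P2[:, 0] = 0.3
        l1 = np.zeros(2, dtype=int)
        l2 = np.zeros(6, dtype=int)
        scores = reinstatement_scores([P1, P2], [l1, l2], 2)
        pooled_oracle = (0.9 * 2 + 0.3 * 6) / 8  # flat loop over all TRs
        assert scores[0] == pytest.approx(pooled_oracle)
        assert scores[0] != pytest.approx((0.9 + 0.3) / 2)

    def test_never_recalled_nan(self):
        P = np.full((4, 3), 1 / 3)
        labels = np.array([0, 0, 1, 1])
        scores = reinstatement_scores([P], [labels], 3)
        assert np.isnan(scores[2]) and np.isfinite(scores[:2]).all()
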