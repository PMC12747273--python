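"""Gated-attention algebra, losses, splits, and training mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchseek.mil import (
    GatedAttentionMIL,
    GatedAttentionParams,
    aggregate,
    attention_scores,
    class_weights,
    evaluate,
    mean_pool,
    split_cohort,
    total_loss,
)
from patchseek.synthetic import MILCohortSpec, gen_mil_cohort


def _random_params(d, seed=0, zero_w=False):
    rng = np.random.default_rng(seed)
    return GatedAttentionParams(
        W=np.zeros(d) if zero_w else rng.standard_normal(d),
        V=rng.standard_normal((d, d)),
        U=rng.standard_normal((d, d)),
    )


class TestAttentionScores:
    def test_identical_rows_uniform(self):
        H = np.tile(np.random.default_rng(0).standard_normal(8), (5, 1))
        s = attention_scores(H, _random_params(8))
        np.testing.assert_allclose(s, np.full(5, 0.2), atol=1e-12)

    def test_zero_w_uniform_for_any_bag(self):
        H = np.random.default_rng(1).standard_normal((7, 8))
        s = attention_scores(H, _random_params(8, zero_w=True))
        np.testing.assert_allclose(s, np.full(7, 1 / 7), atol=1e-12)

    def test_two_row_bag_matches_direct_formula_transcription(self):
        """Hand-evaluated tanh/sigmoid/softmax chain on a 2-row bag."""
        d = 3
        W = np.array([0.5, -1.0, 0.25])
        V = np.eye(d) * 0.5
        U = np.eye(d) * -0.3
        H = np.array([[1.0, 0.0, 2.0], [0.0, -1.0, 1.0]])
        logits = []
        for h in H:
            gate = np.tanh(V @ h) * (1.0 / (1.0 + np.exp(-(U @ h))))
            logits.append(W @ gate)
        expected = np.exp(logits) / np.exp(logits).sum()
        s = attention_scores(H, GatedAttentionParams(W=W, V=V, U=U))
        np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_softmax_sums_to_one_over_random_bags(self):
        rng = np.random.default_rng(3)
        params = _random_params(8, seed=4)
        for _ in range(200):
            H = rng.standard_normal((rng.integers(1, 20), 8))
            assert attention_scores(H, params).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            attention_scores(np.empty((0, 8)), _random_params(8))


class TestAggregate:
    def test_single_row_identity(self):
        H = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(aggregate(H, np.array([1.0])), H[0])

    def test_uniform_weights_give_mean(self):
        H = np.random.default_rng(0).standard_normal((6, 4))
        np.testing.assert_allclose(aggregate(H, np.full(6, 1 / 6)), H.mean(0))
        np.testing.assert_allclose(mean_pool(H), H.mean(0))

    def test_result_in_convex_hull(self):
        rng = np.random.default_rng(1)
        H = rng.standard_normal((10, 5))
        s = rng.dirichlet(np.ones(10))
        z = aggregate(H, s)
        assert np.all(z >= H.min(0) - 1e-12) and np.all(z <= H.max(0) + 1e-12)

    def test_mismatched_weights_rejected(self):
        with pytest.raises(ValueError):
            aggregate(np.ones((3, 2)), np.array([0.5, 0.5]))

    def test_mean_pool_hand_case(self):
        np.testing.assert_allclose(mean_pool(np.array([[1.0, 2.0], [3.0, 4.0]])), [2.0, 3.0])


class TestClassWeightsAndLoss:
    def test_balanced_classes(self):
        np.testing.assert_allclose(class_weights([0, 1, 2] * 4), [3.0, 3.0, 3.0])

    def test_reciprocal_frequencies(self):
        labels = [0, 0, 1, 2]
        np.testing.assert_allclose(class_weights(labels), [2.0, 4.0, 4.0])

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="re-split"):
            class_weights([0, 0, 1, 1])

    def test_perfect_onehot_prediction_zero_loss(self):
        logits = np.array([[100.0, 0.0, 0.0], [0.0, 100.0, 0.0]])
        loss = total_loss([logits], np.array([[0], [1]]), [np.array([2.0, 4.0, 4.0])])
        assert loss == pytest.approx(0.0, abs=1e-10)

    def test_single_regression_contribution(self):
        loss = total_loss(None, None, None, reg_preds=np.array([[2.0]]),
                          reg_targets=np.array([[0.0]]))
        assert loss == pytest.approx(4.0)

    def test_two_task_sum_matches_per_task_oracle(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((4, 3))
        y = np.array([0, 1, 2, 1])
        w = np.array([1.0, 2.0, 3.0])
        preds, targets = rng.standard_normal((4, 1)), rng.standard_normal((4, 1))
        # independent per-task computation
        z = logits - logits.max(1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(1, keepdims=True))
        ce = np.mean([-w[y[i]] * logp[i, y[i]] for i in range(4)])
        mse = np.mean((preds - targets) ** 2)
        combined = total_loss([logits], y[:, None], [w], preds, targets)
        assert combined == pytest.approx(ce + mse)

    def test_missing_labels_masked(self):
        logits = np.array([[0.0, 5.0, 0.0], [9.0, 9.0, 9.0]])
        loss = total_loss([logits], np.array([[1], [-1]]), [np.ones(3)])
        assert loss < 0.05  # second slide contributes nothing


class TestSplitCohort:
    def test_sizes_for_ten_patients(self):
        split = split_cohort([f"p{i}" for i in range(10)], seed=0)
        assert (len(split["train"]), len(split["val"]), len(split["test"])) == (8, 1, 1)

    def test_patient_slides_stay_together(self):
        ids = ["a", "a", "a", "b", "c", "d", "e", "f", "g", "h", "i", "j"]
        split = split_cohort(ids, seed=1)
        parts = [set(np.asarray(ids)[idx]) for idx in split.values()]
        for i, p in enumerate(parts):
            for q in parts[i + 1 :]:
                assert not (p & q)

    def test_deterministic_under_seed(self):
        ids = [f"p{i}" for i in range(20)]
        a, b = split_cohort(ids, seed=5), split_cohort(ids, seed=5)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_positive_label_constraint_enforced(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(30, 2))
        split = split_cohort([f"p{i}" for i in range(30)], labels, seed=2)
        for idx in split.values():
            assert (labels[idx] == 1).any(axis=0).all()

    def test_unsatisfiable_constraint_errors(self):
        labels = np.zeros((10, 1), dtype=int)  # no positives anywhere
        with pytest.raises(ValueError, match="constraint"):
            split_cohort([f"p{i}" for i in range(10)], labels, seed=0, max_attempts=10)


class TestTrainingMechanics:
    def test_zero_epochs_returns_initialized_model(self, small_cohort):
        c = small_cohort
        m = GatedAttentionMIL(d_proj=16, epochs=0, seed=0)
        m.fit(c.bags, c.class_labels, c.reg_targets, c.patient_ids)
        init = m._init_params(c.bags[0].shape[1], 1, 1)
        for k, v in init.items():
            np.testing.assert_array_equal(m.params_raw_[k], v)

    def test_loss_decreases_over_first_epochs(self, small_cohort):
        c = small_cohort
        m = GatedAttentionMIL(d_proj=16, epochs=5, seed=1, select_best_epoch=False)
        m.fit(c.bags, c.class_labels, c.reg_targets, c.patient_ids)
        losses = [h["loss"] for h in m.history_]
        assert losses[-1] < losses[0]

    def test_permutation_invariance_of_all_outputs(self, small_cohort):
        c = small_cohort
        m = GatedAttentionMIL(d_proj=16, epochs=3, seed=2)
        m.fit(c.bags, c.class_labels, c.reg_targets, c.patient_ids)
        bag = c.bags[0]
        perm = np.random.default_rng(0).permutation(len(bag))
        np.testing.assert_allclose(m.embed(bag), m.embed(bag[perm]), atol=1e-10)
        np.testing.assert_allclose(
            m.predict_proba([bag])[0], m.predict_proba([bag[perm]])[0], atol=1e-10
        )
        np.testing.assert_allclose(m.attention(bag)[perm], m.attention(bag[perm]), atol=1e-10)

    def test_checkpoint_round_trip(self, small_cohort, tmp_path):
        c = small_cohort
        m = GatedAttentionMIL(d_proj=16, epochs=2, seed=3)
        m.fit(c.bags, c.class_labels, c.reg_targets, c.patient_ids)
        path = tmp_path / "model.npz"
        m.save(path)
        back = GatedAttentionMIL.load(path)
        np.testing.assert_allclose(
            back.predict_proba(c.bags[:3])[0], m.predict_proba(c.bags[:3])[0]
        )


class TestEvaluate:
    def test_perfect_separation_auc_one(self, small_cohort):
        c = small_cohort
        m = GatedAttentionMIL(d_proj=16, epochs=15, seed=0)
        m.fit(c.bags, c.class_labels, c.reg_targets, c.patient_ids)
        train = m.split_["train"]
        res = evaluate(m, [c.bags[i] for i in train], c.class_labels[train],
                       c.reg_targets[train])
        assert res["auc"][0] >= 0.95  # 5-SD planted effect is separable

    def test_single_label_task_skipped_with_warning(self, small_cohort):
        c = small_cohort
        m = GatedAttentionMIL(d_proj=16, epochs=1, seed=0)
        m.fit(c.bags, c.class_labels, c.reg_targets, c.patient_ids)
        with pytest.warns(UserWarning, match="skipped"):
            res = evaluate(m, c.bags[:3], np.zeros((3, 1), dtype=int))
        assert np.isnan(res["auc"][0])

    def test_identical_predictions_give_rho_one(self):
        from scipy.stats import spearmanr

        y = np.array([0.3, -1.2, 0.8, 2.0])
        assert spearmanr(y, y).statistic == pytest.approx(1.0)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_attention_weights_positive_and_normalized(seed):
    rng = np.random.default_rng(seed)
    H = rng.standard_normal((rng.integers(1, 12), 6))
    s = attention_scores(H, _random_params(6, seed=seed % 17))
    assert np.all(s > 0)
    assert s.sum() == pytest.approx(1.0, abs=1e-9)
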