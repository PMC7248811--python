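"""Classifier pipeline: SMOTE contract, PCA reduction, MLP training,
topology selection and test-set isolation."""

from __future__ import annotations

import numpy as np
import pytest

from ehgkit.evaluate import roc_auc
from ehgkit.model import (
    MLP,
    ModelConfig,
    apply_reduce,
    fit_reduce,
    run_partition,
    run_study,
    select_topology,
    smote_balance,
    stratified_three_way_split,
    train_ann,
)


def _dist_to_segments(point, X):
    """Minimum distance from a point to any segment between rows of X."""
    best = np.inf
    for i in range(len(X)):
        for j in range(len(X)):
            if i == j:
                continue
            a, b = X[i], X[j]
            ab = b - a
            denom = ab @ ab
            t = 0.0 if denom == 0 else np.clip((point - a) @ ab / denom, 0.0, 1.0)
            best = min(best, np.linalg.norm(point - (a + t * ab)))
    return best


class TestSmote:
    def test_balances_30_110_to_equality(self, rng):
        X = rng.standard_normal((140, 5))
        y = np.array([1] * 30 + [0] * 110)
        Xb, yb = smote_balance(X, y, k=5, seed=0)
        assert (yb == 1).sum() == 110 and (yb == 0).sum() == 110
        np.testing.assert_array_equal(Xb[:140], X)  # originals unchanged
        np.testing.assert_array_equal(yb[:140], y)

    def test_1d_minority_convexity(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0], [7.0], [8.0]])
        y = np.array([1, 1, 0, 0, 0, 0])
        Xb, yb = smote_balance(X, y, k=1, seed=1)
        synth = Xb[6:]
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_synthetic_rows_on_minority_segments(self, rng):
        """Every synthetic point lies on a segment between minority rows
        (stronger than convex-hull membership)."""
        X = rng.standard_normal((60, 4))
        y = np.array([1] * 12 + [0] * 48)
        Xb, yb = smote_balance(X, y, k=5, seed=7)
        X_min = X[y == 1]
        for point in Xb[60:]:
            assert _dist_to_segments(point, X_min) < 1e-9

    def test_deterministic_per_seed(self, rng):
        X = rng.standard_normal((50, 3))
        y = np.array([1] * 10 + [0] * 40)
        a, _ = smote_balance(X, y, k=3, seed=11)
        b, _ = smote_balance(X, y, k=3, seed=11)
        np.testing.assert_array_equal(a, b)
        c, _ = smote_balance(X, y, k=3, seed=12)
        assert not np.array_equal(a, c)

    def test_minority_too_small_for_k(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.raises(ValueError, match="k\\+1"):
            smote_balance(X, y, k=5, seed=0)

    def test_already_balanced_passthrough(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.array([1] * 10 + [0] * 10)
        Xb, yb = smote_balance(X, y, k=3, seed=0)
        np.testing.assert_array_equal(Xb, X)


class TestPcaReduction:
    def test_single_dominant_direction(self, rng):
        t = rng.standard_normal(200)
        X = np.outer(t, np.ones(10)) + 0.001 * rng.standard_normal((200, 10))
        proj = fit_reduce(X, 0.98)
        assert proj.n_components == 1

    def test_isotropic_gaussian_keeps_most_components(self, rng):
        X = rng.standard_normal((3000, 29))
        proj = fit_reduce(X, 0.98)
        assert proj.n_components >= 28

    def test_retained_variance_at_least_target(self, rng):
        X = rng.standard_normal((100, 8)) @ rng.standard_normal((8, 8))
        proj = fit_reduce(X, 0.98)
        assert proj.pca.explained_variance_ratio_.sum() >= 0.98

    def test_zero_variance_feature_dropped(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 2] = 3.14
        proj = fit_reduce(X, 0.98)
        assert 2 not in proj.kept_columns
        Z = apply_reduce(proj, X)
        assert Z.shape[0] == 50

    def test_projection_orthonormal(self, rng):
        X = rng.standard_normal((80, 6))
        proj = fit_reduce(X, 0.98)
        C = proj.pca.components_
        np.testing.assert_allclose(C @ C.T, np.eye(C.shape[0]), atol=1e-10)


class TestMlp:
    def test_separable_toy_reaches_full_accuracy(self, rng):
        X = np.vstack([rng.normal([-2, -2], 0.5, (20, 2)), rng.normal([2, 2], 0.5, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = MLP(3, seed=1).fit(X, y)
        assert (((model.scores(X) >= 0.5).astype(int)) == y).mean() == 1.0

    def test_deterministic_weights_per_seed(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 2, 60)
        a = MLP(4, seed=5).fit(X, y, X[:20], y[:20])
        b = MLP(4, seed=5).fit(X, y, X[:20], y[:20])
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_shuffled_labels_give_chance_auc(self):
        """Held-out AUC about 50% when labels carry no information.

        Scored on rows untouched by training *and* early stopping — the
        early-stopping set itself is optimistically biased by design.
        """
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((120, 5))
            y = rng.integers(0, 2, 120)
            model = MLP(3, seed=seed, max_epochs=200).fit(
                X[:60], y[:60], X[60:90], y[60:90]
            )
            _, _, auc = roc_auc(model.scores(X[90:]), y[90:])
            aucs.append(auc)
        assert abs(np.mean(aucs) - 50.0) < 8.0

    def test_early_stopping_limits_epochs(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.integers(0, 2, 60)
        model = MLP(3, seed=0, max_epochs=500, patience=5)
        model.fit(X[:40], y[:40], X[40:], y[40:])
        assert model.n_epochs_ < 500


class TestTopologySelection:
    def test_tie_prefers_fewer_neurons(self):
        assert select_topology({h: 80.0 for h in range(2, 11)}) == 2

    def test_monotone_improvement_selects_largest(self):
        assert select_topology({h: 50.0 + h for h in range(2, 11)}) == 10

    def test_argmax_selected(self):
        aucs = {2: 70.0, 3: 85.0, 4: 82.0}
        assert select_topology(aucs) == 3


class TestSplit:
    def test_partition_covers_all_rows_disjointly(self, rng):
        y = np.array([1] * 30 + [0] * 60)
        tr, va, te = stratified_three_way_split(y, rng)
        combined = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(combined, np.arange(90))

    def test_class_proportions_preserved(self, rng):
        y = np.array([1] * 30 + [0] * 60)
        tr, va, te = stratified_three_way_split(y, rng)
        for idx in (tr, va, te):
            assert y[idx].sum() == 10  # 30 positives split equally


class TestStudy:
    def _noise_data(self, rng, n_pos=15, n_neg=45, d=6):
        X = rng.standard_normal((n_pos + n_neg, d))
        y = np.array([1] * n_pos + [0] * n_neg)
        return X, y

    def test_study_reproducible_bit_for_bit(self, rng):
        X, y = self._noise_data(rng)
        cfg = ModelConfig(n_partitions=3, min_valid_partitions=2, hidden_grid=(2, 3))
        a = run_study(X, y, cfg, seed=4)
        b = run_study(X, y, cfg, seed=4)
        for ra, rb in zip(a, b):
            assert ra.hidden_n == rb.hidden_n
            np.testing.assert_array_equal(ra.test_scores, rb.test_scores)
            assert ra.metrics == rb.metrics

    def test_balanced_counts_in_partition(self, rng):
        X, y = self._noise_data(rng, 15, 45)
        cfg = ModelConfig(n_partitions=1, min_valid_partitions=1, hidden_grid=(2,))
        res = run_study(X, y, cfg, seed=0)
        n_test = len(res[0].test_labels)
        assert n_test == 30  # a third of the 90 balanced rows
        assert res[0].test_labels.sum() == 15

    def test_separated_data_high_test_auc(self, rng):
        X, y = self._noise_data(rng, 20, 40)
        X[y == 1] += 4.0
        cfg = ModelConfig(n_partitions=5, min_valid_partitions=4, hidden_grid=(2, 4))
        res = run_study(X, y, cfg, seed=1)
        aucs = [r.metrics["test"]["auc"] for r in res if r.valid]
        assert np.mean(aucs) > 90.0

    def test_missing_values_rejected(self, rng):
        X, y = self._noise_data(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            run_study(X, y, ModelConfig(), seed=0)


class TestTestIsolation:
    def test_permuting_test_labels_changes_nothing_trained(self, rng):
        """No trained weight, PCA axis or topology choice depends on the
        test rows' labels."""
        X = rng.standard_normal((90, 8))
        y = rng.integers(0, 2, 90)
        split_rng = np.random.default_rng(3)
        split = stratified_three_way_split(y, split_rng)
        cfg = ModelConfig(hidden_grid=(2, 3, 4))

        res_a = run_partition(X, y, split, cfg, seed=21)
        y_perm = y.copy()
        te = split[2]
        y_perm[te] = np.random.default_rng(99).permutation(y_perm[te])
        res_b = run_partition(X, y_perm, split, cfg, seed=21)

        assert res_a.hidden_n == res_b.hidden_n
        assert res_a.n_components == res_b.n_components
        np.testing.assert_array_equal(res_a.test_scores, res_b.test_scores)
        assert res_a.metrics["train"] == res_b.metrics["train"]
        assert res_a.metrics["validation"] == res_b.metrics["validation"]
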