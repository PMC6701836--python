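"""Classifier and metric contracts.

The AUC implementation is checked against an independent brute-force
pairwise oracle; the KNN against exhaustive hand cross-validation; the CNN
against its determinism, range and forward-pass algebra contracts on tiny
grids.
"""

import numpy as np
import pytest

from vsbias import (
    CnnHyperparams,
    CnnModel,
    GridSpec,
    permutation_null_band,
    roc_auc,
    score_correlation,
    train_cnn,
    train_knn,
    voxelize,
)
from vsbias.errors import ConfigError, DimensionError, MetricError, TrainingError
from vsbias.models.cnn import load_checkpoint, save_checkpoint
from vsbias.models.knn import tanimoto_distance_matrix


def pairwise_auc_oracle(scores, labels):
    """Brute-force P(active > decoy) + half ties over all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    act = scores[labels == 1]
    dec = scores[labels == 0]
    total = 0.0
    for a in act:
        for d in dec:
            total += 1.0 if a > d else (0.5 if a == d else 0.0)
    return total / (len(act) * len(dec))


class TestRocAuc:
    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 21)
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            # quantized scores force ties into the comparison
            scores = np.round(rng.random(n), 1)
            assert abs(roc_auc(scores, labels)
                       - pairwise_auc_oracle(scores, labels)) < 1e-12

    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0], 0.75),
            ([1.0, 0.9, 0.1, 0.0], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3 + s):
            assert roc_auc(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(MetricError):
            roc_auc([0.1, 0.2], [1, 1])


def test_permutation_null_band_covers_half():
    rng = np.random.default_rng(1)
    scores = rng.random(120)
    labels = np.r_[np.ones(40, int), np.zeros(80, int)]
    lo, hi = permutation_null_band(scores, labels, seed=5)
    assert lo < 0.5 < hi
    assert 0.35 < lo < 0.48 and 0.52 < hi < 0.65


class TestKnn:
    def test_best_k_one_on_tight_separated_clusters(self):
        """Two tight, well-separated fingerprint clusters: exhaustive CV
        prefers K=1 (every left-out point's nearest neighbor is a
        same-class clustermate)."""
        fps = np.zeros((6, 64), np.uint8)
        fps[:3, :8] = 1   # class-1 cluster
        fps[3:, 40:48] = 1  # class-0 cluster
        fps[1, 8] = 1
        fps[4, 48] = 1  # slight within-cluster variation
        model = train_knn(fps, [1, 1, 1, 0, 0, 0], seed=0)
        assert model.best_k == 1

    def test_identical_fingerprints_tiebreak_to_k1(self):
        fps = np.ones((8, 32), np.uint8)
        model = train_knn(fps, [1, 1, 1, 1, 0, 0, 0, 0], seed=0)
        assert model.best_k == 1
        assert all(auc == pytest.approx(0.5) for auc in model.cv_auc_per_k.values())

    def test_determinism(self, rng):
        fps = (rng.random((20, 128)) < 0.2).astype(np.uint8)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        a = train_knn(fps, labels, seed=3)
        b = train_knn(fps, labels, seed=3)
        assert a.best_k == b.best_k
        np.testing.assert_array_equal(a.predict(fps), b.predict(fps))

    def test_leave_one_in_k1_reproduces_labels(self, rng):
        fps = (rng.random((12, 256)) < 0.15).astype(np.uint8)
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        model = train_knn(fps, labels, seed=0)
        scores = model.predict(fps, k=1)
        assert roc_auc(scores, labels) == 1.0

    def test_too_few_examples_raises(self):
        with pytest.raises(TrainingError):
            train_knn(np.ones((3, 8), np.uint8), [1, 0, 0])

    def test_fold_reduction_warns(self, caplog):
        fps = (np.random.default_rng(0).random((7, 16)) < 0.5).astype(np.uint8)
        with caplog.at_level("WARNING"):
            train_knn(fps, [1, 1, 1, 0, 0, 0, 0], n_folds=5, seed=0)
        assert any("reducing CV folds" in r.message for r in caplog.records)


def test_tanimoto_distance_matrix_values():
    a = np.array([[1, 1, 0, 0], [0, 0, 0, 0]], np.uint8)
    b = np.array([[1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 0, 0]], np.uint8)
    d = tanimoto_distance_matrix(a, b)
    assert d[0, 0] == pytest.approx(2.0 / 3.0)  # sim 1/3
    assert d[0, 1] == pytest.approx(0.0)
    assert d[1, 2] == pytest.approx(0.0)  # all-zero pair: distance 0 convention
    assert d[1, 0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# CNN


def _toy_grids(n, tiny_grid_spec, type_map, separable=True, seed=0):
    """Tiny labeled grids: actives put density at one corner slot, decoys at
    the opposite one (or both random when not separable)."""
    from vsbias.records import AtomCloud

    rng = np.random.default_rng(seed)
    grids, labels = [], []
    for i in range(n):
        label = i % 2
        if separable:
            pos = np.array([6.0, 6.0, 6.0]) if label else np.array([-6.0, -6.0, -6.0])
        else:
            pos = rng.uniform(-6, 6, size=3)
        pos = pos + rng.normal(0, 0.5, size=3)
        cloud = AtomCloud(pos[None, :], ["LA"])
        grids.append(voxelize(None, cloud, tiny_grid_spec, type_map))
        labels.append(label)
    return grids, np.array(labels)


class TestCnn:
    def test_hyperparam_validation(self):
        with pytest.raises(ConfigError):
            CnnHyperparams(batch_size=7)
        with pytest.raises(ConfigError):
            CnnHyperparams(learning_rate=0.0)

    def test_training_determinism_and_range(self, tiny_grid_spec, type_map):
        grids, labels = _toy_grids(16, tiny_grid_spec, type_map)
        hyper = CnnHyperparams(iterations=30, seed=4)
        m1 = train_cnn(grids, labels, hyper)
        m2 = train_cnn(grids, labels, hyper)
        for w1, w2 in zip(m1.conv_weights, m2.conv_weights):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(m1.fc_weight, m2.fc_weight)
        scores = m1.predict(grids)
        assert scores.shape == (16,)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_learns_separable_toy(self, tiny_grid_spec, type_map):
        grids, labels = _toy_grids(24, tiny_grid_spec, type_map, seed=1)
        model = train_cnn(grids, labels, CnnHyperparams(iterations=150, seed=1))
        test_grids, test_labels = _toy_grids(20, tiny_grid_spec, type_map, seed=9)
        assert roc_auc(model.predict(test_grids), test_labels) >= 0.95
        assert model.loss_history[-1][1] <= model.loss_history[0][1]

    def test_shuffled_labels_stay_in_null_band(self, tiny_grid_spec, type_map):
        """Training labels made orthogonal to the separable feature (each
        spatial class half-relabeled): the fitted model carries no signal,
        so held-out AUC must sit in the permutation null band."""
        grids, labels = _toy_grids(24, tiny_grid_spec, type_map, seed=2)
        null_labels = np.array([(i // 2) % 2 for i in range(len(labels))])
        model = train_cnn(grids, null_labels,
                          CnnHyperparams(iterations=60, seed=2))
        test_grids, test_labels = _toy_grids(40, tiny_grid_spec, type_map, seed=8)
        scores = model.predict(test_grids)
        lo, hi = permutation_null_band(scores, test_labels, seed=0)
        assert lo <= roc_auc(scores, test_labels) <= hi

    def test_duplicate_grids_identical_scores(self, tiny_grid_spec, type_map):
        grids, labels = _toy_grids(8, tiny_grid_spec, type_map)
        model = train_cnn(grids, labels, CnnHyperparams(iterations=10, seed=0))
        scores = model.predict([grids[0], grids[1], grids[0]])
        assert scores[0] == scores[2]

    def test_single_class_raises(self, tiny_grid_spec, type_map):
        grids, _ = _toy_grids(6, tiny_grid_spec, type_map)
        with pytest.raises(TrainingError):
            train_cnn(grids, np.ones(6, int), CnnHyperparams(iterations=5))

    def test_channel_mismatch_raises(self, tiny_grid_spec, type_map):
        grids, labels = _toy_grids(8, tiny_grid_spec, type_map)
        model = train_cnn(grids, labels, CnnHyperparams(iterations=5, seed=0))
        bad = np.zeros((2, model.n_channels + 1, 8, 8, 8), np.float32)
        with pytest.raises(DimensionError):
            model.predict(bad)

    def test_zeroed_receptor_weights_ignore_receptor(self, tiny_grid_spec, type_map):
        """Forward-pass algebra: zero first-layer receptor weights make
        ablated and unablated inputs score identically."""
        from vsbias import ablate_receptor
        from vsbias.records import AtomCloud

        rng = np.random.default_rng(5)
        grids, labels = [], []
        for i in range(10):
            lig = AtomCloud(rng.uniform(-6, 6, (2, 3)), ["LA", "LB"])
            rec = AtomCloud(rng.uniform(-8, 8, (3, 3)), ["R0", "RP", "RN"])
            grids.append(voxelize(rec, lig, tiny_grid_spec, type_map))
            labels.append(i % 2)
        model = train_cnn(grids, np.array(labels), CnnHyperparams(iterations=10, seed=0))
        w = model.first_layer_weights  # (C_in, 27, F) view of conv_weights[0]
        w[: tiny_grid_spec.n_receptor_channels] = 0.0
        model.conv_weights[0] = w.reshape(model.conv_weights[0].shape)
        s_with = model.predict(grids)
        s_without = model.predict([ablate_receptor(g) for g in grids])
        np.testing.assert_array_equal(s_with, s_without)

    def test_checkpoint_roundtrip(self, tmp_path, tiny_grid_spec, type_map):
        grids, labels = _toy_grids(8, tiny_grid_spec, type_map)
        model = train_cnn(grids, labels, CnnHyperparams(iterations=10, seed=0))
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, type_map_hash="abc")
        loaded = load_checkpoint(path)
        np.testing.assert_array_equal(model.predict(grids), loaded.predict(grids))
        assert loaded.hyper == model.hyper


def test_cnn_ligand_bias_regime():
    """Single-target CNN on a strongly separable biased dataset: held-out
    AUC >= 0.95, and test-time receptor ablation changes almost nothing
    (small delta, paired scores nearly perfectly correlated) — the model
    rode the ligand bias, not the receptor."""
    from vsbias.pipeline import ligand_only_cnn_experiment

    res = ligand_only_cnn_experiment(seed=1, iterations=400)
    abl = res["ablation"]
    assert abl.auc_with >= 0.95
    assert abl.delta <= 0.05
    assert res["correlation"]["r2"] >= 0.9


def test_score_correlation_contracts(rng):
    a = rng.random(10)
    r2, slope = score_correlation(a, a)
    assert r2 == pytest.approx(1.0) and slope == pytest.approx(1.0)
    r2, slope = score_correlation(a, 2 * a + 1)
    assert r2 == pytest.approx(1.0) and slope == pytest.approx(2.0)
    # 5-point hand dataset vs normal-equations solve
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
    A = np.stack([x, np.ones_like(x)], axis=1)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    r2_hand = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    r2, slope = score_correlation(x, y)
    assert slope == pytest.approx(beta[0])
    assert r2 == pytest.approx(r2_hand)
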