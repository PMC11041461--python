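"""EUP-only and gated-fusion classifiers: algebra, gradients, training."""

import numpy as np
import pytest

from eupkit import _nn
from eupkit.eup_features import FeatureBundle, PostFeatures
from eupkit.fusion_classifier import (
    CHANNELS,
    EUPClassifier,
    GatedFusionClassifier,
    concat_eup,
    gate,
)

D = 4  # embedding dimension for these tests
H = 3  # hidden dimension


def make_features(rng, n, d=D, f=None):
    return PostFeatures(
        ids=[f"p{i}" for i in range(n)],
        X_M=rng.normal(size=(n, 2 * d)),
        X_C=rng.normal(size=(n, 2 * d)),
        X_F=rng.normal(size=(n, d)),
        f=rng.uniform(0, 1, size=n) if f is None else np.full(n, float(f)),
        u_post=rng.uniform(0, 1, size=n),
    )


def make_bundle(rng, h=H, f=0.5):
    return FeatureBundle(rng.normal(size=h), rng.normal(size=h), rng.normal(size=h),
                         rng.normal(size=h), f)


class TestConcat:
    def test_order_and_slicing(self, rng):
        bundle = make_bundle(rng, h=2)
        out = concat_eup(bundle)
        assert out.shape == (8,)
        assert np.array_equal(out[:2], bundle.I_M)
        assert np.array_equal(out[2:4], bundle.I_C)
        assert np.array_equal(out[4:6], bundle.I_F)
        assert np.array_equal(out[6:], bundle.I_P)

    def test_zero_bundle(self):
        zeros = FeatureBundle(*(np.zeros(3),) * 4, 0.0)
        assert np.array_equal(concat_eup(zeros), np.zeros(12))


class TestGate:
    def test_zero_parameters_give_half(self):
        o, I_X = np.zeros(5), np.zeros(H)
        assert np.allclose(gate(o, I_X, np.zeros((5 + H, H)), np.zeros(H)), 0.5)

    def test_saturated_bias(self, rng):
        o, I_X = rng.normal(size=5), rng.normal(size=H)
        W = rng.normal(size=(5 + H, H)) * 0.01
        assert np.all(np.abs(gate(o, I_X, W, np.full(H, 50.0)) - 1.0) < 1e-9)
        assert np.all(gate(o, I_X, W, np.full(H, -50.0)) < 1e-9)

    def test_strictly_inside_unit_interval(self, rng):
        for _ in range(20):
            g = gate(rng.normal(size=4), rng.normal(size=H), rng.normal(size=(4 + H, H)), rng.normal(size=H))
            assert np.all(g > 0.0) and np.all(g < 1.0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            gate(np.zeros(3), np.zeros(H), np.zeros((99, H)), np.zeros(H))


@pytest.fixture
def fused_results(rng):
    n = 24
    features = make_features(rng, n)
    y = np.array([0, 1] * (n // 2))
    o = rng.normal(size=(n, 5))
    model = GatedFusionClassifier(features, y, o, hidden_dim=H)
    return model.fit(seed=0, epochs=2), features, o


class TestFusion:
    def test_saturated_gates_sum_channels(self, fused_results, rng):
        results, features, o_all = fused_results
        for ch in CHANNELS:
            results.params[f"g_{ch}_W"] *= 0.0
            results.params[f"g_{ch}_b"][:] = 50.0
        bundle = results.transform(features)[0]
        fused = results.fuse(o_all[0], bundle)
        direct = bundle.I_M + bundle.I_C + bundle.I_F + bundle.I_P
        assert np.all(np.abs(fused - direct) < 1e-6)

    def test_closed_gates_zero_output(self, fused_results):
        results, features, o_all = fused_results
        for ch in CHANNELS:
            results.params[f"g_{ch}_W"] *= 0.0
            results.params[f"g_{ch}_b"][:] = -50.0
        bundle = results.transform(features)[0]
        assert np.all(np.abs(results.fuse(o_all[0], bundle)) < 1e-6)

    def test_half_gates_double_equal_channels(self, fused_results, rng):
        results, _, o_all = fused_results
        for ch in CHANNELS:
            results.params[f"g_{ch}_W"] *= 0.0
            results.params[f"g_{ch}_b"][:] = 0.0
        v = rng.normal(size=H)
        bundle = FeatureBundle(v.copy(), v.copy(), v.copy(), v.copy(), 0.5)
        assert np.allclose(results.fuse(o_all[0], bundle), 2 * v)

    def test_fused_mode_requires_baseline(self, fused_results):
        results, features, _ = fused_results
        with pytest.raises(ValueError, match="baseline"):
            results.predict_proba(features, baseline=None)

    def test_baseline_dimension_contract(self, rng):
        from eupkit.data_io import RunConfig

        features = make_features(rng, 8)
        y = np.array([0, 1] * 4)
        with pytest.raises(ValueError, match="dimension"):
            GatedFusionClassifier(features, y, rng.normal(size=(8, 5)),
                                  hidden_dim=H, config=RunConfig(baseline_dim=64))


class TestHeads:
    def test_probabilities_sum_to_one(self, rng):
        features = make_features(rng, 12)
        y = np.array([0, 1] * 6)
        results = EUPClassifier(features, y, hidden_dim=H).fit(seed=0, epochs=2)
        probs = results.predict_proba(features)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(results.predict(features), probs.argmax(axis=1))

    def test_zero_head_gives_uniform(self, rng):
        features = make_features(rng, 8)
        results = EUPClassifier(features, np.array([0, 1] * 4), hidden_dim=H).fit(seed=0, epochs=1)
        results.params["out_W"] *= 0.0
        results.params["out_b"][:] = 0.0
        probs = results.predict_from_bundle(make_bundle(rng))
        assert np.allclose(probs, [0.5, 0.5])

    def test_swapping_head_columns_swaps_probabilities(self, rng):
        features = make_features(rng, 10)
        results = EUPClassifier(features, np.array([0, 1] * 5), hidden_dim=H).fit(seed=0, epochs=2)
        probs = results.predict_proba(features)
        results.params["out_W"] = results.params["out_W"][:, ::-1].copy()
        results.params["out_b"] = results.params["out_b"][::-1].copy()
        swapped = results.predict_proba(features)
        assert np.allclose(probs, swapped[:, ::-1], atol=1e-12)


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        features = make_features(rng, n)
        features.X_F[:, 0] = 2.0 * y - 1.0  # one perfectly separating coordinate
        model = EUPClassifier(features, y, hidden_dim=4)
        results = model.fit(seed=0, epochs=200, learning_rate=1e-2)
        assert np.mean(results.predict(features) == y) == 1.0

    def test_same_seed_gives_identical_weights(self, rng):
        features = make_features(rng, 30)
        y = np.array([0, 1] * 15)
        a = EUPClassifier(features, y, hidden_dim=H).fit(seed=11, epochs=5)
        b = EUPClassifier(features, y, hidden_dim=H).fit(seed=11, epochs=5)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_single_class_rejected(self, rng):
        features = make_features(rng, 10)
        with pytest.raises(ValueError, match="single-class"):
            EUPClassifier(features, np.zeros(10, dtype=int), hidden_dim=H).fit(seed=0)

    def test_dropping_all_channels_rejected(self, rng):
        features = make_features(rng, 10)
        model = EUPClassifier(features, np.array([0, 1] * 5), hidden_dim=H)
        with pytest.raises(ValueError, match="all four"):
            model.fit(seed=0, drop_channels=CHANNELS)

    def test_unknown_channel_rejected(self, rng):
        features = make_features(rng, 10)
        model = EUPClassifier(features, np.array([0, 1] * 5), hidden_dim=H)
        with pytest.raises(ValueError, match="unknown"):
            model.fit(seed=0, drop_channels=("sentiment",))

    def test_one_gradient_step_reduces_loss(self, rng):
        features = make_features(rng, 32)
        y = np.array([0, 1] * 16)
        model = EUPClassifier(features, y, hidden_dim=H)
        params = model._init_params(np.random.default_rng(0))
        mask = {ch: 1.0 for ch in CHANNELS}
        probs, cache = model._forward(params, (features, None), mask)
        loss_before = _nn.cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        grads = model._backward(params, cache, dlogits, mask)
        for key, grad in grads.items():
            params[key] = params[key] - 1e-3 * grad
        probs_after, _ = model._forward(params, (features, None), mask)
        assert _nn.cross_entropy(probs_after, y) < loss_before

    def test_labels_independent_of_features_stay_at_chance(self, rng):
        n_train, n_eval = 500, 500
        features = make_features(rng, n_train + n_eval)
        y = rng.integers(0, 2, size=n_train + n_eval)
        train = features.subset(np.arange(n_train))
        holdout = features.subset(np.arange(n_train, n_train + n_eval))
        results = EUPClassifier(train, y[:n_train], hidden_dim=H).fit(seed=0, epochs=30)
        accuracy = np.mean(results.predict(holdout) == y[n_train:])
        band = 1.96 * np.sqrt(0.25 / n_eval)
        assert abs(accuracy - 0.5) <= band

    def test_early_stopping_restores_best_epoch(self, rng):
        n = 80
        features = make_features(rng, n)
        y = np.array([0, 1] * (n // 2))
        val = make_features(rng, 40)
        y_val = np.array([0, 1] * 20)
        results = EUPClassifier(features, y, hidden_dim=H).fit(
            seed=0, val_data=(val, y_val), epochs=40, patience=3
        )
        assert results.best_val_macro_f1 == pytest.approx(results.history["val_macro_f1"].max())
        assert len(results.history) <= 40


class TestResultsReporting:
    def test_summary_mentions_model_and_dropped_channels(self, rng):
        features = make_features(rng, 12)
        y = np.array([0, 1] * 6)
        results = EUPClassifier(features, y, hidden_dim=H).fit(seed=0, epochs=2, drop_channels=("macro",))
        text = results.summary()
        assert "EUP" in text and "macro" in text
        assert str(results.n_params) in text

    def test_evaluate_returns_metric_dict(self, rng):
        features = make_features(rng, 20)
        y = np.array([0, 1] * 10)
        results = EUPClassifier(features, y, hidden_dim=H).fit(seed=0, epochs=2)
        metrics = results.evaluate(features, y)
        assert set(metrics) >= {"accuracy", "macro_f1", "f1_class0", "f1_class1", "sp_auc"}
        assert 0.0 <= metrics["accuracy"] <= 1.0

    def test_plot_history_returns_axis(self, rng):
        features = make_features(rng, 12)
        results = EUPClassifier(features, np.array([0, 1] * 6), hidden_dim=H).fit(seed=0, epochs=2)
        ax = results.plot_history()
        assert ax.get_xlabel() == "epoch"


class TestCheckpoints:
    def test_eup_checkpoint_round_trip(self, rng, tmp_path):
        from eupkit.fusion_classifier import load_checkpoint

        features = make_features(rng, 20)
        y = np.array([0, 1] * 10)
        results = EUPClassifier(features, y, hidden_dim=H).fit(seed=0, epochs=3,
                                                               drop_channels=("micro",))
        path = tmp_path / "model.json"
        results.save(path, scorer_fingerprint="abc", f_bounds=(0.1, 0.9))
        restored, payload = load_checkpoint(path)
        assert np.allclose(restored.predict_proba(features), results.predict_proba(features))
        assert restored.mask == results.mask
        assert payload["scorer_sha256"] == "abc"
        assert payload["f_bounds"] == [0.1, 0.9]

    def test_fused_checkpoint_round_trip(self, rng, tmp_path):
        from eupkit.fusion_classifier import load_checkpoint

        n = 20
        features = make_features(rng, n)
        y = np.array([0, 1] * (n // 2))
        o = rng.normal(size=(n, 5))
        results = GatedFusionClassifier(features, y, o, hidden_dim=H).fit(seed=0, epochs=3)
        path = tmp_path / "model.json"
        results.save(path)
        restored, _ = load_checkpoint(path)
        assert np.allclose(restored.predict_proba(features, baseline=o),
                           results.predict_proba(features, baseline=o))
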