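"""Predictor families: features, penalized logistic fit, volumetric network."""

import warnings

import numpy as np
import pytest

from octneed import _nn
from octneed.biomarkers import FluidMetrics
from octneed.evaluation import make_folds, roc_auc
from octneed.models import (
    FEATURE_NAMES,
    FluidLogit,
    NetConfig,
    VolumeNet,
    featurize,
    fine_tune,
    fit_logistic,
    pretrain_source,
    train_from_scratch,
)

TINY = NetConfig(input_shape=(8, 12, 12), stem_pool=(2, 2, 2), channels=(3, 4),
                 head_width=6, epochs=4, batch_size=8, patience=3)


def _tiny_data(n=16, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2) + TINY.input_shape).astype(np.float32) * 0.3
    y = (rng.random(n) < 0.5).astype(int)
    if signal:
        X[y == 1, :, 2:6, 3:9, 3:9] += 0.4
    return X, y


class TestFeaturize:
    def test_zero_fluid_gives_zero_features(self):
        z = FluidMetrics(0, 0, 0)
        assert np.all(featurize(z, z).as_array() == 0.0)

    def test_equal_visits_give_zero_deltas(self):
        m = FluidMetrics(4.2, 17.0, 43.0)
        fv = featurize(m, m)
        assert fv.delta_irf_nl == 0.0 and fv.delta_srf_nl == 0.0

    def test_missing_visit_rejected(self):
        with pytest.raises(ValueError):
            featurize(None, FluidMetrics(0, 0, 0))

    def test_standardization_gives_unit_moments(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(1.0, 1.0, size=(200, 8))
        y = (rng.random(200) < 0.5).astype(int)
        res = FluidLogit(X, y).fit()
        Z = res.transformed_design()
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)


class TestFluidLogit:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.r_[np.zeros(30), np.ones(30)]
        res = FluidLogit(X, y, log_transform=False).fit(l2_strength=1e-4)
        assert (res.predict(X) == y).all()

    def test_parameter_recovery_within_20_percent(self):
        """n=500 draws from a known logistic model recover each coefficient.

        Estimates are averaged over three simulation seeds; a single draw
        leaves each coefficient's sampling error at roughly one standard
        error of the 20% band.
        """
        beta = np.array([1.1, -0.9, 0.8])
        ests = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 3))
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = (rng.random(500) < p).astype(int)
            res = FluidLogit(X, y, log_transform=False, standardize=False).fit(l2_strength=1e-3)
            ests.append(res.coefficients)
        rel = np.abs(np.mean(ests, axis=0) - beta) / np.abs(beta)
        assert np.all(rel < 0.20)

    def test_probabilities_in_open_unit_interval(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < 0.5).astype(int)
        p = FluidLogit(X, y).fit().predict_proba(X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_decision_boundary_linear(self):
        """Equal linear predictor eta implies equal probability (linearity)."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        y = ((X @ [1.0, -1.0, 0.5] + rng.normal(0, 0.5, 200)) > 0).astype(int)
        res = FluidLogit(X, y, log_transform=False, standardize=False).fit()
        b = res.coefficients
        # move a point within the hyperplane {x : b.x = const}: probability unchanged
        x0 = np.array([0.3, -0.2, 0.1])
        null = np.array([b[1], -b[0], 0.0])
        null /= np.linalg.norm(null)
        x1 = x0 + 2.5 * null
        p0, p1 = res.predict_proba(np.vstack([x0, x1]))
        assert p0 == pytest.approx(p1, abs=1e-9)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(size=50), np.full(50, 7.0)])
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            res = FluidLogit(X, y).fit()
        assert len(res.kept_names) == 2  # intercept + one informative feature

    def test_all_constant_features_give_chance_model(self):
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        X = np.ones((40, 3))
        with pytest.warns(UserWarning, match="intercept-only"):
            res = FluidLogit(X, y).fit()
        p = res.predict_proba(X)
        assert np.allclose(p, 0.5, atol=1e-9)

    def test_feature_ablation_drives_cv_auc_to_chance(self):
        """Constant inputs carry no signal: cross-validated AUC is ~0.5."""
        rng = np.random.default_rng(6)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        X = np.ones((n, 4))
        ids = np.array([f"P{i}" for i in range(n)])
        scores = np.zeros(n)
        plan = make_folds(ids, k=5, seed=0, labels=y)
        pos = {p: i for i, p in enumerate(ids)}
        for f in plan.folds:
            tr = [pos[p] for p in np.concatenate([f["train"], f["val"]])]
            te = [pos[p] for p in f["test"]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = FluidLogit(X[tr], y[tr]).fit()
            scores[te] = res.predict_proba(X[te]) + rng.normal(0, 1e-9, len(te))
        _, auc = roc_auc(scores, y)
        assert abs(auc - 0.5) < 0.08

    def test_hidden_layer_variant_runs(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 3))
        y = ((X[:, 0] * X[:, 1]) > 0).astype(int)  # XOR-like, non-linear
        res = FluidLogit(X, y, log_transform=False, hidden_units=8).fit()
        assert res.predict_proba(X).shape == (80,)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            FluidLogit(np.zeros((10, 3)), np.zeros(10))       # single class
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((2, 3)), np.array([0, 1]))   # n < p
        with pytest.raises(ValueError):
            fit_logistic(np.random.rand(10, 2), np.r_[np.zeros(5), np.ones(5)],
                         l2_strength=0.0)


class TestVolumeNet:
    def test_deterministic_training_same_hash(self):
        X, y = _tiny_data()
        r1 = VolumeNet(TINY).fit(X, y, X[:6], y[:6], seed=3)
        r2 = VolumeNet(TINY).fit(X, y, X[:6], y[:6], seed=3)
        assert r1.weights_hash() == r2.weights_hash()

    def test_different_seed_different_weights(self):
        X, y = _tiny_data()
        r1 = VolumeNet(TINY).fit(X, y, seed=3)
        r2 = VolumeNet(TINY).fit(X, y, seed=4)
        assert r1.weights_hash() != r2.weights_hash()

    def test_zero_epoch_fine_tune_uses_pretrained_encoder_fresh_head(self):
        X, y = _tiny_data()
        w = pretrain_source(TINY, X, y, seed=0)
        res = fine_tune(w, TINY, X, y, seed=1, epochs=0)
        for key in TINY.encoder_keys:
            np.testing.assert_array_equal(res.weights[key], w[key])
        for key in TINY.head_keys:
            if res.weights[key].size and w[key].size:
                assert not np.array_equal(res.weights[key], w[key])
        assert res.predict_proba(X).shape == (len(X),)

    def test_training_reduces_loss_and_stops_on_patience(self):
        X, y = _tiny_data(n=24, seed=1)
        cfg = NetConfig(**{**TINY.__dict__, "epochs": 30, "patience": 4})
        res = VolumeNet(cfg).fit(X, y, X, y, seed=0)
        losses = res.history["val_loss"]
        assert min(losses) <= losses[0]
        # at termination the best epoch is no later than `patience` from the end
        best = int(np.argmin(losses))
        assert len(losses) - 1 - best <= cfg.patience

    def test_probabilities_bounded(self):
        X, y = _tiny_data()
        res = VolumeNet(TINY).fit(X, y, seed=0)
        p = res.predict_proba(X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_shape_mismatch_rejected(self):
        X, y = _tiny_data()
        other = NetConfig(**{**TINY.__dict__, "channels": (4, 5)})
        w = pretrain_source(TINY, X, y, seed=0)
        with pytest.raises(ValueError):
            fine_tune(w, other, X, y)

    def test_scratch_learns_separable_signal(self):
        X, y = _tiny_data(n=40, seed=2)
        cfg = NetConfig(**{**TINY.__dict__, "epochs": 30})
        res = train_from_scratch(cfg, X, y, seed=0)
        _, auc = roc_auc(res.predict_proba(X), y)
        assert auc > 0.9  # training-set separation of an easy signal

    def test_gradients_match_finite_differences(self):
        cfg = NetConfig(input_shape=(6, 8, 8), stem_pool=(2, 2, 2), channels=(2, 3),
                        head_width=4, batch_size=4)
        rng = np.random.default_rng(0)
        w = _nn.init_weights(cfg, rng)
        X = rng.random((3, 2) + cfg.input_shape).astype(np.float32)
        y = np.array([0.0, 1.0, 1.0])
        sw = np.ones(3)
        cache = {}
        logits = _nn.forward_logits(X, w, cfg, cache)
        _, dl = _nn._bce_with_logits(logits, y, sw)
        grads = _nn._backward(dl, w, cfg, cache)

        def loss_of(wt):
            z = _nn.forward_logits(X, wt, cfg)
            return _nn._bce_with_logits(z, y, sw)[0]

        for key in w:
            idx = tuple(rng.integers(0, s) for s in w[key].shape)
            eps = 1e-3
            wp = {k: v.copy() for k, v in w.items()}
            wp[key][idx] += eps
            wm = {k: v.copy() for k, v in w.items()}
            wm[key][idx] -= eps
            numeric = (loss_of(wp) - loss_of(wm)) / (2 * eps)
            analytic = grads[key].reshape(w[key].shape)[idx]
            assert analytic == pytest.approx(numeric, rel=0.05, abs=5e-4)
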