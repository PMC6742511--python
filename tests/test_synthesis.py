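import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthreg.deformation import make_label_set
from synthreg.io import Image2D
from synthreg.synthesis import (
    ForestHyperparams,
    N_FEATURES,
    PredictionMaps,
    extract_features,
    fit,
    predict,
    sample_displacements,
)

from conftest import ramp_image


class TestFeatures:
    def test_feature_count_is_32(self, rng):
        f = extract_features(Image2D(rng.random((24, 24))))
        assert f.feature_count == N_FEATURES == 32
        assert len(f.names) == 32

    def test_constant_image(self):
        f = extract_features(Image2D(np.full((20, 20), 7.0)))
        vals = f.values
        for k, name in enumerate(f.names):
            if name.startswith("loc"):
                continue
            if name.endswith("_d0"):
                np.testing.assert_allclose(vals[..., k], 7.0)
            else:
                # discretised Gaussian-derivative kernels are zero-sum only
                # to filter precision
                np.testing.assert_allclose(vals[..., k], 0.0, atol=0.01)

    def test_ramp_first_derivative(self):
        f = extract_features(ramp_image(80))
        interior = (slice(20, -20), slice(20, -20))  # clear of filter support
        for k, name in enumerate(f.names):
            if name.endswith("_dx"):
                np.testing.assert_allclose(f.values[interior + (k,)], 1.0, atol=1e-2)
            elif name.endswith(("_dxx", "_dxxx", "_dy", "_dyy")):
                np.testing.assert_allclose(f.values[interior + (k,)], 0.0, atol=1e-2)

    def test_location_features_in_mm(self):
        f = extract_features(Image2D(np.zeros((10, 12)), spacing=0.5))
        ix = f.names.index("loc_x")
        iy = f.names.index("loc_y")
        assert f.values[0, 11, ix] == pytest.approx(5.5)
        assert f.values[9, 0, iy] == pytest.approx(4.5)


class TestPrediction:
    def _model_with_fixed_guesses(self, guesses, a=2.0, b=50.0):
        class _Stub:
            def __init__(self, g):
                self.g = g

            def predict(self, X):
                return np.full(X.shape[0], self.g)

        from synthreg.synthesis import SynthesisModel

        hyper = ForestHyperparams(a=a, b=b, n_trees=len(guesses))
        return SynthesisModel([_Stub(g) for g in guesses], hyper)

    def test_unanimous_trees_reference_values(self):
        from synthreg.synthesis import FeatureStack

        model = self._model_with_fixed_guesses([120.0] * 100)
        feats = FeatureStack(np.zeros((2, 2, 32)), [""] * 32)
        maps = predict(model, feats)
        np.testing.assert_allclose(maps.mu, 120.0)
        np.testing.assert_allclose(maps.var, 100.0 / 104.0)  # 2b/(2a+T)

    def test_two_tree_disagreement(self):
        from synthreg.synthesis import FeatureStack

        model = self._model_with_fixed_guesses([0.0, 2.0])
        feats = FeatureStack(np.zeros((1, 1, 32)), [""] * 32)
        maps = predict(model, feats)
        assert maps.mu[0, 0] == pytest.approx(1.0)
        assert maps.var[0, 0] == pytest.approx((100.0 + 2.0) / 6.0)  # = 17.0
        assert maps.var[0, 0] == pytest.approx(17.0)

    @given(st.lists(st.floats(0, 255), min_size=2, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_variance_never_below_prior_floor(self, guesses):
        g = np.asarray(guesses)
        T = len(g)
        a, b = 2.0, 50.0
        mu = g.mean()
        var = (2 * b + ((g - mu) ** 2).sum()) / (2 * a + T)
        floor = 2 * b / (2 * a + T)
        assert var >= floor - 1e-12
        if np.allclose(g, g[0]):
            assert var == pytest.approx(floor)


class TestForestFit:
    def _point_mass_beliefs(self, shape, labels, index):
        q = np.zeros((*shape, labels.n_labels))
        q[..., index] = 1.0
        return q

    def test_pointmass_zero_shift_deterministic_mapping(self, rng):
        # M is a deterministic function of a smooth H -> small held-out RMSE
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.random((32, 32)), 2.0)
        base = (base - base.min()) / (base.max() - base.min()) * 255.0
        h_img = Image2D(base)
        m_img = Image2D(255.0 - h_img.pixels)
        labels = make_label_set(1, 1)
        q = self._point_mass_beliefs((32, 32), labels, labels.zero_index)
        feats = extract_features(h_img)
        hyper = ForestHyperparams(n_trees=10, min_leaf=1)
        model = fit([feats], [m_img], [q], labels, hyper, rng)
        maps = predict(model, feats)
        rmse = np.sqrt(np.mean((maps.mu - m_img.pixels) ** 2))
        assert rmse < 6.0

    def test_constant_target_gives_constant_prediction(self, rng):
        h_img = Image2D(rng.random((16, 16)) * 255)
        m_img = Image2D(np.full((16, 16), 99.0))
        labels = make_label_set(1, 1)
        q = np.full((16, 16, labels.n_labels), 1.0 / labels.n_labels)
        feats = extract_features(h_img)
        model = fit([feats], [m_img], [q], labels, ForestHyperparams(n_trees=5), rng)
        maps = predict(model, feats)
        # interior targets are all exactly 99 (boundary shifts drop out)
        np.testing.assert_allclose(maps.mu, 99.0, atol=1e-9)

    def test_bagging_injects_randomness(self, rng):
        h_img = Image2D(rng.random((24, 24)) * 255)
        m_img = Image2D(rng.random((24, 24)) * 255)
        labels = make_label_set(2, 1)
        q = np.full((24, 24, labels.n_labels), 1.0 / labels.n_labels)
        feats = extract_features(h_img)
        hyper = ForestHyperparams(n_trees=2)
        model = fit([feats], [m_img], [q], labels, hyper, np.random.default_rng(0))
        t0, t1 = model.trees
        assert not np.array_equal(
            t0.tree_.feature[: t0.tree_.node_count], t1.tree_.feature[: t1.tree_.node_count]
        ) or t0.tree_.node_count != t1.tree_.node_count

    def test_empty_training_set_rejected(self, rng):
        labels = make_label_set(1, 1)
        with pytest.raises(ValueError):
            fit([], [], [], labels, ForestHyperparams(n_trees=1), rng)

    def test_feature_mismatch_rejected(self, rng):
        from synthreg.synthesis import FeatureStack, SynthesisModel

        model = SynthesisModel([], ForestHyperparams(n_trees=1), feature_count=32)
        with pytest.raises(ValueError):
            predict(model, FeatureStack(np.zeros((2, 2, 5)), ["x"] * 5))


def test_sample_displacements_follows_distribution(rng):
    labels = make_label_set(1, 1)
    q = np.zeros((1000, 9))
    q[:, 4] = 0.75
    q[:, 0] = 0.25
    draws = sample_displacements(q, labels, rng)
    frac4 = np.mean([tuple(d) == tuple(labels.deltas[4]) for d in draws])
    assert frac4 == pytest.approx(0.75, abs=0.05)


def test_prediction_maps_validation():
    with pytest.raises(ValueError):
        PredictionMaps(np.zeros((2, 2)), np.zeros((2, 2)))
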