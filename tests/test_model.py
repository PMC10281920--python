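import numpy as np
import pytest
from sklearn.base import clone

from cpemip import nn
from cpemip.errors import ConfigError, ValidationError
from cpemip.mip_render import MipViewSet
from cpemip.model import (
    EnsembleClassifier,
    LungPrediction,
    ViewAveragingClassifier,
    aggregate_views,
    create_feature_extractor,
    ensemble_predict,
    extract_features,
    fuse_lr,
    load_ensemble,
    predict_lung,
    save_ensemble,
)

N_VIEWS, PX = 11, 16


def _views(rng, study_id="s1", side="left"):
    images = rng.uniform(0, 1, (N_VIEWS, PX, PX)).astype(np.float32)
    directions = [("vertical", 30.0 * i) for i in range(N_VIEWS)]
    return MipViewSet(images, directions, side, study_id)


def _head_with_fixed_p(fx, p):
    """A head whose final layer outputs logits giving softmax positive prob p."""
    head = nn.Sequential([nn.Dense(fx.feature_dim, 2)])
    head.layers[-1].params["W"][:] = 0.0
    head.layers[-1].params["b"] = np.array([0.0, np.log(p / (1 - p))], dtype=np.float32)
    return head


class TestFeatureExtraction:
    def test_one_vector_per_view_constant_length(self, rng):
        fx = create_feature_extractor(seed=0)
        feats = extract_features(_views(rng), fx)
        assert feats.shape == (N_VIEWS, fx.feature_dim)

    def test_frozen_determinism_on_duplicated_view(self, rng):
        fx = create_feature_extractor(seed=0, frozen=True)
        image = rng.uniform(0, 1, (PX, PX)).astype(np.float32)
        views = MipViewSet(np.stack([image] * N_VIEWS), [("vertical", 0.0)] * N_VIEWS, "left")
        feats = extract_features(views, fx)
        assert np.ptp(feats, axis=0).max() == 0.0  # all 11 vectors identical

    def test_zero_image_matches_hand_computed_forward_pass(self):
        # two-layer toy backend: conv (known bias) -> ReLU -> conv -> ReLU -> GAP
        rng = np.random.default_rng(0)
        net = nn.Sequential(
            [nn.Conv2d(1, 2, rng=rng), nn.ReLU(), nn.Conv2d(2, 3, rng=rng), nn.ReLU(),
             nn.GlobalAvgPool()]
        )
        net.layers[0].params["b"] = np.array([0.5, -0.3], dtype=np.float32)
        net.layers[2].params["W"][:] = 0.0
        net.layers[2].params["b"] = np.array([0.2, -1.0, 0.0], dtype=np.float32)
        out = net.forward(np.zeros((1, 1, 8, 8), dtype=np.float32))
        # zero image -> conv1 = bias -> relu -> conv2 weights are 0 so output =
        # its bias -> relu -> GAP preserves constants
        np.testing.assert_allclose(out[0], [0.2, 0.0, 0.0], atol=1e-6)

    def test_densenet_backend_needs_external_runtime(self):
        with pytest.raises(ConfigError):
            create_feature_extractor("pretrained-densenet121")

    def test_custom_callable_backend(self, rng):
        fx = create_feature_extractor(lambda imgs: imgs.reshape(len(imgs), -1)[:, :4])
        feats = extract_features(_views(rng), fx)
        assert feats.shape == (N_VIEWS, 4)


class TestAggregateViews:
    def test_mean_identities(self):
        assert aggregate_views([[1.0, 2.0]] * 5).tolist() == [1.0, 2.0]
        assert aggregate_views([[0.0, 2.0], [2.0, 0.0]]).tolist() == [1.0, 1.0]

    def test_matches_loop_oracle(self, rng):
        stack = rng.normal(size=(11, 64))
        expected = np.array([stack[:, j].sum() / 11 for j in range(64)])
        np.testing.assert_allclose(aggregate_views(stack), expected, atol=1e-12)

    def test_permutation_invariant(self, rng):
        stack = rng.normal(size=(11, 8))
        shuffled = stack[rng.permutation(11)]
        np.testing.assert_allclose(aggregate_views(stack), aggregate_views(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_views(np.empty((0, 4)))


class TestPredictionOps:
    def test_zeroed_final_layer_gives_half(self, rng):
        fx = create_feature_extractor(seed=0)
        head = _head_with_fixed_p(fx, 0.5)
        assert predict_lung(_views(rng), fx, head).p_cpe == pytest.approx(0.5)

    def test_eval_mode_deterministic(self, rng):
        fx = create_feature_extractor(seed=0)
        head = nn.Sequential([nn.Dense(fx.feature_dim, 2, rng=np.random.default_rng(3))])
        views = _views(rng)
        assert predict_lung(views, fx, head).p_cpe == predict_lung(views, fx, head).p_cpe

    def test_fuse_lr_takes_maximum(self):
        a = LungPrediction("s", "left", 0.3)
        b = LungPrediction("s", "right", 0.7)
        assert fuse_lr(a, b).p_lrmax == 0.7
        assert fuse_lr(b, a).p_lrmax == 0.7  # symmetric
        c = LungPrediction("s", "right", 0.3)
        assert fuse_lr(a, c).p_lrmax == 0.3  # equal lungs

    def test_fuse_lr_rejects_mismatched_studies(self):
        with pytest.raises(ValidationError):
            fuse_lr(LungPrediction("s1", "left", 0.1), LungPrediction("s2", "right", 0.2))

    def test_ensemble_arithmetic_and_identity(self, rng):
        fx = create_feature_extractor(seed=0)
        left, right = _views(rng, side="left"), _views(rng, side="right")
        members = [(fx, _head_with_fixed_p(fx, 0.2)), (fx, _head_with_fixed_p(fx, 0.6))]
        fused = ensemble_predict(members, left, right)
        assert fused.p_left == pytest.approx(0.4, abs=1e-6)
        same = [(fx, members[0][1])] * 5
        assert ensemble_predict(same, left, right).p_left == pytest.approx(0.2, abs=1e-6)

    def test_ensemble_matches_loop_oracle_and_bounds(self, rng):
        fx = create_feature_extractor(seed=0)
        left, right = _views(rng, side="left"), _views(rng, side="right")
        members = [
            (fx, nn.Sequential([nn.Dense(fx.feature_dim, 2, rng=np.random.default_rng(i))]))
            for i in range(5)
        ]
        singles = [predict_lung(left, f, h).p_cpe for f, h in members]
        fused = ensemble_predict(members, left, right)
        assert fused.p_left == pytest.approx(sum(singles) / 5, abs=1e-9)
        assert min(singles) <= fused.p_left <= max(singles)

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValidationError):
            ensemble_predict([], _views(rng), _views(rng))


def _toy_dataset(rng, n=24):
    """Linearly separable view stacks: class shifts the mean intensity."""
    y = np.repeat([0, 1], n // 2)
    X = rng.uniform(0, 0.3, (n, 4, PX, PX)).astype(np.float32)
    X[y == 1] += 0.4
    return X, y


class TestViewAveragingClassifier:
    def test_learns_separable_data_and_is_deterministic(self, rng):
        X, y = _toy_dataset(rng)
        kw = dict(epochs=8, learning_rate=5e-3, random_state=0)
        a = ViewAveragingClassifier(**kw).fit(X, y)
        b = ViewAveragingClassifier(**kw).fit(X, y)
        assert [h["train_loss"] for h in a.history_] == [h["train_loss"] for h in b.history_]
        proba = a.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert proba[y == 1, 1].mean() > proba[y == 0, 1].mean()

    def test_prediction_invariant_to_view_order(self, rng):
        X, y = _toy_dataset(rng)
        clf = ViewAveragingClassifier(epochs=2, random_state=0).fit(X, y)
        permuted = X[:, ::-1]
        np.testing.assert_allclose(
            clf.predict_proba(X), clf.predict_proba(permuted), atol=1e-6
        )

    def test_sklearn_protocol(self):
        clf = ViewAveragingClassifier(epochs=3, dropout=0.2)
        params = clf.get_params()
        assert params["dropout"] == 0.2
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_ensemble_save_load_round_trip(self, tmp_path, rng):
        X, y = _toy_dataset(rng)
        members = [
            ViewAveragingClassifier(epochs=2, random_state=i).fit(X, y) for i in range(2)
        ]
        ensemble = EnsembleClassifier(members)
        save_ensemble(ensemble, tmp_path / "ens")
        loaded = load_ensemble(tmp_path / "ens")
        np.testing.assert_allclose(
            loaded.predict_proba(X), ensemble.predict_proba(X), atol=1e-6
        )

    def test_ensemble_bounded_by_members(self, rng):
        X, y = _toy_dataset(rng)
        members = [
            ViewAveragingClassifier(epochs=2, random_state=i).fit(X, y) for i in range(3)
        ]
        ens = EnsembleClassifier(members).score_lungs(X)
        singles = np.stack([m.score_lungs(X) for m in members])
        assert (ens <= singles.max(axis=0) + 1e-9).all()
        assert (ens >= singles.min(axis=0) - 1e-9).all()
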