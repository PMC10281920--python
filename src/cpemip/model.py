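"""Per-lung CPE classifier: frozen-or-trainable multi-view feature extractor,
element-wise view averaging, three-layer perceptron head, softmax output,
left/right-max fusion and softmax-averaged ensembling.

The architecture processes each projection image independently through a
convolutional backbone, averages the per-view feature vectors element-wise
(making the prediction invariant to view ordering) and classifies the
averaged vector with a three-layer MLP (linear -> ReLU -> alpha-dropout ->
batch-norm, twice, then linear -> softmax).  A patient-level score is the
maximum of the two per-lung positive-class probabilities (LR_max), and an
ensemble averages the softmax outputs of several independently trained
models before fusion.

Exposed in two shapes: a scikit-learn style estimator
(:class:`ViewAveragingClassifier`) and thin functional operations
(``extract_features`` / ``aggregate_views`` / ``predict_lung`` /
``fuse_lr`` / ``ensemble_predict``) over the same machinery.

Only the small trainable CNN backend is bundled; any callable mapping an
``(n_images, h, w)`` stack to ``(n_images, d)`` features (e.g. a wrapped
ImageNet-pretrained network) can be plugged in as a custom backend.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .errors import ConfigError, ValidationError
from .mip_render import MipViewSet

TINY_CNN = "tiny-cnn-test"


def _build_tiny_cnn(rng: np.random.Generator, channels: Sequence[int] = (8, 16, 32)) -> nn.Sequential:
    # global MAX pooling on purpose: the feature vector then encodes the
    # strongest local vascular pattern rather than the total vessel mass,
    # so predictions stay meaningful on patch-occluded inputs where most of
    # the lung is blanked out
    layers: list[nn.Layer] = []
    c_in = 1
    for c_out in channels:
        layers.append(nn.Conv2d(c_in, c_out, k=3, stride=2, rng=rng))
        layers.append(nn.ReLU())
        c_in = c_out
    layers.append(nn.GlobalMaxPool())
    return nn.Sequential(layers)


def _build_head(
    d_in: int,
    widths: Sequence[int],
    n_classes: int,
    dropout: float,
    rng: np.random.Generator,
) -> nn.Sequential:
    layers: list[nn.Layer] = []
    prev = d_in
    for width in widths:
        layers.append(nn.Dense(prev, width, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.AlphaDropout(dropout, rng=rng))
        layers.append(nn.BatchNorm1d(width))
        prev = width
    layers.append(nn.Dense(prev, n_classes, rng=rng))
    return nn.Sequential(layers)


@dataclasses.dataclass
class FeatureExtractor:
    """A (possibly frozen) image -> feature-vector backend."""

    backend: str
    net: nn.Sequential | None = None
    custom: Callable[[np.ndarray], np.ndarray] | None = None
    frozen: bool = True

    def extract(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (n, h, w) images to (n, d) feature vectors."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 3:
            raise ValidationError(f"expected (n, h, w) images, got shape {images.shape}")
        if self.custom is not None:
            return np.asarray(self.custom(images), dtype=np.float32)
        assert self.net is not None
        return self.net.forward(images[:, None, :, :], train=train and not self.frozen)

    @property
    def feature_dim(self) -> int:
        if self.custom is not None:
            probe = self.custom(np.zeros((1, 8, 8), dtype=np.float32))
            return int(np.asarray(probe).shape[1])
        last = [l for l in self.net.layers if isinstance(l, nn.Conv2d)][-1]
        return last.c_out


def create_feature_extractor(
    backend: str | Callable[[np.ndarray], np.ndarray] = TINY_CNN,
    seed: int = 0,
    frozen: bool = False,
) -> FeatureExtractor:
    """Instantiate a backbone.

    ``tiny-cnn-test`` is the bundled three-convolution backend.  A callable
    is wrapped as a frozen custom backend.  ``pretrained-densenet121`` needs
    an external deep-learning runtime and must be supplied as a callable.
    """
    if callable(backend):
        return FeatureExtractor("custom", custom=backend, frozen=True)
    if backend == TINY_CNN:
        rng = np.random.default_rng(seed)
        return FeatureExtractor(TINY_CNN, net=_build_tiny_cnn(rng), frozen=frozen)
    if backend == "pretrained-densenet121":
        raise ConfigError(
            "the pretrained DenseNet-121 backend requires an external deep-learning "
            "runtime; wrap it as a callable(images)->features and pass that instead"
        )
    raise ConfigError(f"unknown backbone backend {backend!r}")


@dataclasses.dataclass(frozen=True)
class LungPrediction:
    study_id: str
    side: str
    p_cpe: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cpe <= 1.0:
            raise ValidationError(f"p_cpe must be in [0,1], got {self.p_cpe}")


@dataclasses.dataclass(frozen=True)
class StudyPrediction:
    study_id: str
    p_left: float
    p_right: float

    @property
    def p_lrmax(self) -> float:
        return max(self.p_left, self.p_right)


def extract_features(views: MipViewSet, fx: FeatureExtractor) -> np.ndarray:
    """One feature vector per view image, (n_views, d)."""
    return fx.extract(views.images)


def aggregate_views(vectors: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of the per-view feature vectors."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValidationError("aggregate_views needs a non-empty (n_views, d) stack")
    return vectors.mean(axis=0)


def predict_lung(views: MipViewSet, fx: FeatureExtractor, head: nn.Sequential) -> LungPrediction:
    """Softmax positive-class probability of head(mean(features(views)))."""
    agg = aggregate_views(extract_features(views, fx)).astype(np.float32)
    logits = head.forward(agg[None, :], train=False)
    p = float(nn.softmax(logits)[0, 1])
    return LungPrediction(views.study_id, views.side, p)


def fuse_lr(left: LungPrediction, right: LungPrediction) -> StudyPrediction:
    """Patient-level fusion: maximum of the two per-lung CPE probabilities."""
    if left.study_id != right.study_id:
        raise ValidationError(
            f"cannot fuse lungs of different studies: {left.study_id!r} vs {right.study_id!r}"
        )
    return StudyPrediction(left.study_id, left.p_cpe, right.p_cpe)


def ensemble_predict(
    members: Sequence[tuple[FeatureExtractor, nn.Sequential]],
    views_left: MipViewSet,
    views_right: MipViewSet,
) -> StudyPrediction:
    """Average member softmax outputs per lung, then apply LR_max fusion."""
    if len(members) == 0:
        raise ValidationError("ensemble needs at least one member")
    p_left = float(np.mean([predict_lung(views_left, fx, head).p_cpe for fx, head in members]))
    p_right = float(np.mean([predict_lung(views_right, fx, head).p_cpe for fx, head in members]))
    if views_left.study_id != views_right.study_id:
        raise ValidationError("left and right view sets belong to different studies")
    return StudyPrediction(views_left.study_id, p_left, p_right)


class ViewAveragingClassifier(BaseEstimator, ClassifierMixin):
    """Multi-view image classifier with element-wise feature averaging.

    Parameters
    ----------
    backbone : backend id ("tiny-cnn-test") or a callable (frozen custom
        backend) mapping (n, h, w) images to (n, d) features.
    head_widths : hidden widths of the three-layer perceptron head.
    dropout : alpha-dropout rate in the head.
    learning_rate, batch_size, epochs : Adam training schedule.
    freeze_backbone : train only the head if True (always true for custom
        backends).
    random_state : seeds weight init, dropout and example shuffling.

    ``fit`` expects ``X`` of shape (n_lungs, n_views, px, px) with binary
    labels ``y`` (1 = CPE).  Fitted attributes carry trailing underscores.
    """

    def __init__(
        self,
        backbone: str | Callable = TINY_CNN,
        head_widths: tuple[int, int] = (256, 64),
        dropout: float = 0.1,
        learning_rate: float = 1e-4,
        batch_size: int = 8,
        epochs: int = 30,
        freeze_backbone: bool = False,
        random_state: int = 0,
    ) -> None:
        self.backbone = backbone
        self.head_widths = head_widths
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.freeze_backbone = freeze_backbone
        self.random_state = random_state

    # -- estimator API ---------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epoch_callback: Optional[Callable[[int, "ViewAveragingClassifier"], None]] = None,
        X_provider: Optional[Callable[[int], np.ndarray]] = None,
    ) -> "ViewAveragingClassifier":
        X = self._check_views(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValidationError(f"need exactly 2 classes, got {list(self.classes_)}")

        rng = np.random.default_rng(self.random_state)
        init_seed = int(rng.integers(2**31))
        self.backbone_ = create_feature_extractor(
            self.backbone, seed=init_seed, frozen=self.freeze_backbone
        )
        head_rng = np.random.default_rng(init_seed + 1)
        self.head_ = _build_head(
            self.backbone_.feature_dim, self.head_widths, 2, self.dropout, head_rng
        )
        self.n_views_ = X.shape[1]
        self.history_ = []

        params = list(self.head_.parameters())
        backbone_trains = (
            self.backbone_.net is not None and not self.backbone_.frozen
        )
        if backbone_trains:
            params = list(self.backbone_.net.parameters()) + params
        optimizer = nn.Adam(params, lr=self.learning_rate)
        loss_fn = nn.SoftmaxCrossEntropy()

        cached_feats = None
        if not backbone_trains:
            cached_feats = self._features(X)  # frozen: extract once

        n = X.shape[0]
        for epoch in range(1, self.epochs + 1):
            if X_provider is not None:
                X = self._check_views(X_provider(epoch))
                if cached_feats is not None:
                    cached_feats = self._features(X)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if cached_feats is not None:
                    feats = cached_feats[idx]  # (b, v, d)
                else:
                    b, v = len(idx), self.n_views_
                    flat = X[idx].reshape(b * v, *X.shape[2:])[:, None, :, :]
                    feats = self.backbone_.net.forward(flat, train=True).reshape(b, v, -1)
                mean_feats = feats.mean(axis=1).astype(np.float32)
                logits = self.head_.forward(mean_feats, train=True)
                losses.append(loss_fn.forward(logits, y_idx[idx]))
                grad = self.head_.backward(loss_fn.backward())
                if backbone_trains:
                    b, v = feats.shape[0], feats.shape[1]
                    per_view = np.repeat(grad / v, v, axis=0).astype(np.float32)
                    self.backbone_.net.backward(per_view)
                optimizer.step()
            self.history_.append({"epoch": epoch, "train_loss": float(np.mean(losses))})
            if epoch_callback is not None:
                epoch_callback(epoch, self)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_views(X)
        feats = self._features(X)
        mean_feats = feats.mean(axis=1).astype(np.float32)
        return nn.softmax(self.head_.forward(mean_feats, train=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score_lungs(self, X: np.ndarray) -> np.ndarray:
        """Positive-class (CPE) probability per lung example."""
        return self.predict_proba(X)[:, 1]

    def build_unfitted(self, n_views: int = 11) -> "ViewAveragingClassifier":
        """Construct backbone and head without training (for checkpoint loading)."""
        rng = np.random.default_rng(self.random_state)
        init_seed = int(rng.integers(2**31))
        self.backbone_ = create_feature_extractor(
            self.backbone, seed=init_seed, frozen=self.freeze_backbone
        )
        self.head_ = _build_head(
            self.backbone_.feature_dim, self.head_widths, 2, self.dropout,
            np.random.default_rng(init_seed + 1),
        )
        self.classes_ = np.array([0, 1])
        self.n_views_ = n_views
        self.history_ = []
        return self

    # -- persistence -----------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {f"head.{k}": v for k, v in self.head_.get_weights().items()}
        if self.backbone_.net is not None:
            out.update({f"backbone.{k}": v for k, v in self.backbone_.net.get_weights().items()})
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.head_.set_weights(
            {k[len("head."):]: v for k, v in weights.items() if k.startswith("head.")}
        )
        if self.backbone_.net is not None:
            self.backbone_.net.set_weights(
                {k[len("backbone."):]: v for k, v in weights.items() if k.startswith("backbone.")}
            )

    # -- helpers ---------------------------------------------------------
    def _check_views(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValidationError(
                f"expected (n_lungs, n_views, px, px) input, got shape {X.shape}"
            )
        return X

    def _features(self, X: np.ndarray, chunk: int = 256) -> np.ndarray:
        n, v = X.shape[:2]
        flat = X.reshape(n * v, *X.shape[2:])
        parts = [
            self.backbone_.extract(flat[i : i + chunk], train=False)
            for i in range(0, n * v, chunk)
        ]
        return np.concatenate(parts).reshape(n, v, -1)


class EnsembleClassifier:
    """Softmax-averaging ensemble of fitted ViewAveragingClassifiers."""

    def __init__(self, members: Sequence[ViewAveragingClassifier]) -> None:
        if len(members) == 0:
            raise ValidationError("ensemble needs at least one member")
        self.members = list(members)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def score_lungs(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


def save_ensemble(ensemble: EnsembleClassifier, directory) -> None:
    """Persist member hyperparameters (JSON) and weights (npz) to a directory."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    first = ensemble.members[0]
    meta = {
        "n_members": len(ensemble.members),
        "backbone": first.backbone if isinstance(first.backbone, str) else "custom",
        "head_widths": list(first.head_widths),
        "dropout": first.dropout,
        "freeze_backbone": first.freeze_backbone,
        "n_views": int(getattr(first, "n_views_", 11)),
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
    for i, member in enumerate(ensemble.members):
        np.savez(directory / f"member_{i}.npz", **member.get_weights())


def load_ensemble(directory) -> EnsembleClassifier:
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    members = []
    for i in range(meta["n_members"]):
        clf = ViewAveragingClassifier(
            backbone=meta["backbone"],
            head_widths=tuple(meta["head_widths"]),
            dropout=meta["dropout"],
            freeze_backbone=meta["freeze_backbone"],
        ).build_unfitted(n_views=meta["n_views"])
        with np.load(directory / f"member_{i}.npz") as data:
            clf.set_weights({k: data[k] for k in data.files})
        members.append(clf)
    return EnsembleClassifier(members)
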