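"""Exposure-class prediction from rendered track images.

The central estimator, :class:`SegmentImageClassifier`, is a small
convolutional network trained with the focal loss
``FL(p_t) = −(1 − p_t)^γ · log(p_t)`` (γ ≥ 0 the focusing parameter, p_t the
predicted probability of the true class), optimized with Adam
(learning rate 0.001, β1 = 0.9 by default).  Focal loss down-weights easy
examples, which matters when the merged control class outnumbers each drug
class.  Besides class probabilities the model exposes the activations of
the layer underneath the decision layer ("embeddings"), which downstream
modules analyze with PCA.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``transform``, ``get_params``); module-level functions
(`build_model`, `train`, `predict`, `extract_embeddings`) are thin wrappers
kept for pipeline-style use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from . import _nn
from .trajectory import ClassLabel, ValidationError

__all__ = [
    "TrainConfig",
    "PredictionRecord",
    "EmbeddingMatrix",
    "SegmentImageClassifier",
    "focal_loss",
    "build_model",
    "train",
    "predict",
    "extract_embeddings",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The optimizer's "momentum" is Adam's first-moment decay β1.  γ defaults
    to 2, the canonical focal-loss setting; γ = 0 recovers plain
    cross-entropy.  ``backbone`` is ``small_cnn`` (4 conv blocks; trains in
    minutes on a CPU) or ``resnet_small`` (compact residual network).
    """

    backbone: str = "small_cnn"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    gamma: float = 2.0
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if self.backbone not in _nn.BACKBONES:
            raise ValidationError(f"unknown backbone {self.backbone!r}")


@dataclass
class PredictionRecord:
    """One model prediction for one track segment."""

    segment_ref: tuple
    true_label: ClassLabel
    predicted_label: ClassLabel
    probabilities: np.ndarray  # over classes, sums to 1
    start_time: float = 0.0
    fold_id: int = 0


@dataclass
class EmbeddingMatrix:
    """Penultimate-layer activations, one row per segment."""

    rows: np.ndarray  # (n_segments, dim)
    segment_refs: list

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


def focal_loss(probabilities, true_class, gamma: float = 2.0) -> float:
    """Focal loss of one probability vector (or the batch mean for a matrix).

    ``probabilities`` is a length-K simplex vector (or an (n, K) matrix with
    ``true_class`` an index array); p_t, the true-class probability, is
    clipped to [1e−7, 1].
    """
    if gamma < 0:
        raise ValidationError(f"gamma must be >= 0, got {gamma}")
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim == 1:
        p_t = p[int(true_class)]
    else:
        p_t = p[np.arange(p.shape[0]), np.asarray(true_class, dtype=int)]
    return float(_nn.focal_loss_value(p_t, gamma).mean())


def _as_nchw(images: np.ndarray) -> np.ndarray:
    """(n, H, W, 3) uint8/float → float32 NCHW in [0, 1]."""
    x = np.asarray(images)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValidationError(f"images must be (n, H, W, 3), got {x.shape}")
    x = x.astype(np.float32)
    if x.max() > 1.0:
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class SegmentImageClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional classifier over speed-colored track images.

    Parameters mirror :class:`TrainConfig`; ``loss`` selects the focal loss
    (default) or plain cross-entropy (γ forced to 0) for comparisons.

    Attributes (after ``fit``)
    --------------------------
    classes_ : array of class labels, sorted
    loss_history_ : mean training loss per epoch
    input_shape_ : (H, W) the model was fitted on
    embedding_dim_ : width of the penultimate layer
    """

    def __init__(self, backbone: str = "small_cnn", learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, gamma: float = 2.0,
                 epochs: int = 10, batch_size: int = 32, seed: int = 0,
                 loss: str = "focal", embed_dim: int = 64):
        self.backbone = backbone
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.gamma = gamma
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.loss = loss
        self.embed_dim = embed_dim

    # -- construction -------------------------------------------------
    def _build_net(self, n_classes: int) -> None:
        if n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.backbone not in _nn.BACKBONES:
            raise ValidationError(f"unknown backbone {self.backbone!r}")
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([self.seed, 0])))
        self.net_ = _nn.BACKBONES[self.backbone](n_classes, rng, embed_dim=self.embed_dim)
        self.embedding_dim_ = self.embed_dim

    def _effective_gamma(self) -> float:
        if self.loss == "cross_entropy":
            return 0.0
        if self.loss != "focal":
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        return float(self.gamma)

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        x = _as_nchw(X)
        y = np.asarray(y, dtype=object).ravel()
        if len(y) != len(x):
            raise ValidationError("X and y length mismatch")
        self.classes_ = np.array(sorted(set(y)))
        if len(self.classes_) < 2:
            raise ValidationError("training data must contain at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        targets = np.array([class_index[v] for v in y], dtype=np.int64)
        self.input_shape_ = x.shape[2:]
        if not hasattr(self, "net_") or self.net_.head.w.value.shape[1] != len(self.classes_):
            self._build_net(len(self.classes_))
        gamma = self._effective_gamma()
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        opt = _nn.Adam(self.net_.all_params(), lr=self.learning_rate,
                       beta1=self.beta1, beta2=self.beta2)
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([self.seed, 1])))
        history = []
        n = len(x)
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.net_.forward(x[idx])
                loss, dz = _nn.focal_loss_and_grad(logits, targets[idx], gamma)
                self.net_.backward(dz)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.loss_history_ = history
        return self

    def _check_input(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise NotFittedError("model has not been built or fitted")
        x = _as_nchw(X)
        if hasattr(self, "input_shape_") and x.shape[2:] != self.input_shape_:
            raise ValidationError(
                f"image size {x.shape[2:]} does not match fitted size {self.input_shape_}"
            )
        return x

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        x = self._check_input(X)
        out = [
            _nn.softmax(self.net_.forward(x[i:i + batch_size]).astype(np.float64))
            for i in range(0, len(x), batch_size)
        ]
        return np.vstack(out) if out else np.zeros((0, len(self.classes_)))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def transform(self, X, batch_size: int = 256) -> np.ndarray:
        """Penultimate-layer embeddings, one row per image."""
        x = self._check_input(X)
        out = [self.net_.embed(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.vstack(out) if out else np.zeros((0, self.embedding_dim_))


# ---------------------------------------------------------------------------
# functional wrappers (pipeline-facing surface)
# ---------------------------------------------------------------------------

def build_model(n_classes: int, config: TrainConfig) -> SegmentImageClassifier:
    """Initialize an untrained classifier with a reproducible seed."""
    model = SegmentImageClassifier(
        backbone=config.backbone, learning_rate=config.learning_rate,
        beta1=config.beta1, beta2=config.beta2, gamma=config.gamma,
        epochs=config.epochs, batch_size=config.batch_size, seed=config.seed,
    )
    model._build_net(n_classes)
    return model


def train(model: SegmentImageClassifier, images, labels,
          config: TrainConfig | None = None):
    """Train in place; returns (model, per-epoch loss history)."""
    if config is not None:
        model.set_params(
            backbone=config.backbone, learning_rate=config.learning_rate,
            beta1=config.beta1, beta2=config.beta2, gamma=config.gamma,
            epochs=config.epochs, batch_size=config.batch_size, seed=config.seed,
        )
    if model.epochs == 0:
        labels = np.asarray(labels, dtype=object).ravel()
        classes = np.array(sorted(set(labels)))
        if len(classes) < 2:
            raise ValidationError("training data must contain at least 2 classes")
        model.classes_ = classes
        model.input_shape_ = _as_nchw(images).shape[2:]
        if not hasattr(model, "net_"):
            model._build_net(len(classes))
        model.loss_history_ = []
        return model, []
    model.fit(images, labels)
    return model, model.loss_history_


def predict(model: SegmentImageClassifier, images, *, true_labels=None,
            refs=None, start_times=None, fold_id: int = 0) -> list[PredictionRecord]:
    """Predict every image, returning one :class:`PredictionRecord` each."""
    proba = model.predict_proba(images)
    n = proba.shape[0]
    if true_labels is None:
        true_labels = [None] * n
    if refs is None:
        refs = [("", i) for i in range(n)]
    if start_times is None:
        start_times = [0.0] * n
    records = []
    for i in range(n):
        records.append(
            PredictionRecord(
                segment_ref=refs[i],
                true_label=true_labels[i],
                predicted_label=model.classes_[int(proba[i].argmax())],
                probabilities=proba[i],
                start_time=float(start_times[i]),
                fold_id=fold_id,
            )
        )
    return records


def extract_embeddings(model: SegmentImageClassifier, images, refs=None) -> EmbeddingMatrix:
    rows = model.transform(images)
    if refs is None:
        refs = [("", i) for i in range(rows.shape[0])]
    return EmbeddingMatrix(rows=rows, segment_refs=list(refs))
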