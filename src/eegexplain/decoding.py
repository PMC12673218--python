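"""Decoders and the participant-wise cross-validated training protocol.

Three decoder families are provided as scikit-learn style estimators:

* :class:`EEGNetClassifier` — a compact 3-convolution CNN (temporal filters,
  a depthwise spatial filter spanning all electrodes, then a separable
  temporal convolution) trained with SGD + momentum and staircase LR decay;
* :class:`ResidualCNNClassifier` — a reduced residual CNN (initial temporal
  convolution plus identity-shortcut blocks) trained with Adam;
* :class:`PointwiseLogisticDecoder` — a time-point-by-time-point multinomial
  logistic regression baseline.

Splits are made at the participant level: all trials of a participant fall
into exactly one of train/validation/test within a fold, which prevents
identity leakage and forces generalisation to unseen people.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .nn import layers as L
from .nn.network import Network, softmax
from .nn.optim import Adam, SGDMomentum
from .simulate import EpochsSet

# --------------------------------------------------------------------------
# losses / metrics
# --------------------------------------------------------------------------


def one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, labels)
    if not np.all(classes[idx] == labels):
        raise ValueError("labels contain classes unknown to the decoder")
    out = np.zeros((len(labels), len(classes)))
    out[np.arange(len(labels)), idx] = 1.0
    return out


def cross_entropy(true_onehot: np.ndarray, predicted_probs: np.ndarray) -> float:
    """Batch-mean categorical cross-entropy, -sum_c t_c log f(y)_c."""
    t = np.asarray(true_onehot, dtype=float)
    p = np.asarray(predicted_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1 per trial")
    if np.any(p[t > 0] == 0):
        warnings.warn("zero probability at the true class; clamping at eps",
                      RuntimeWarning, stacklevel=2)
    p = np.maximum(p, np.finfo(float).eps)
    return float(-(t * np.log(p)).sum(axis=-1).mean())


def categorical_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Correct predictions / all predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise ValueError("predictions and labels must be nonempty and equal length")
    return float(np.mean(predictions == labels))


# --------------------------------------------------------------------------
# participant-wise splits
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Fold-wise (train, val, test) participant assignments, pairwise disjoint."""

    folds: tuple[tuple[tuple, tuple, tuple], ...]

    def __post_init__(self):
        for tr, va, te in self.folds:
            s_tr, s_va, s_te = set(tr), set(va), set(te)
            if s_tr & s_va or s_tr & s_te or s_va & s_te:
                raise ValueError("train/val/test participant sets must be disjoint")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_participant_splits(participants, n_folds: int = 5,
                            fractions: tuple[float, float, float] = (0.81, 0.10, 0.09),
                            seed: int = 0) -> SplitPlan:
    """Rotate participants through train/validation/test sets over folds.

    Set sizes are ``round(fraction * N)`` (at least 1) for validation and
    test, with the remainder going to train; the test window rotates across
    folds so held-out participants vary.
    """
    parts = np.asarray(sorted(set(participants)))
    N = len(parts)
    if N < 3:
        raise ValueError("need at least 3 participants (one per set)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = max(1, round(fractions[1] * N))
    n_test = max(1, round(fractions[2] * N))
    if n_val + n_test >= N:
        raise ValueError("not enough participants for the requested fractions")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(parts)
    step = max(1, N // n_folds)
    folds = []
    for i in range(n_folds):
        order = np.roll(shuffled, -i * step)
        test = tuple(order[:n_test].tolist())
        val = tuple(order[n_test:n_test + n_val].tolist())
        train = tuple(order[n_test + n_val:].tolist())
        folds.append((train, val, test))
    return SplitPlan(tuple(folds))


def subset_by_participants(epochs: EpochsSet, members) -> EpochsSet:
    return epochs.select(np.isin(epochs.participants, list(members)))


# --------------------------------------------------------------------------
# architecture / training configuration records
# --------------------------------------------------------------------------

FAMILIES = ("eegnet_style", "residual_small", "logistic_pointwise")


@dataclass(frozen=True)
class ArchitectureSpec:
    family: str = "eegnet_style"
    temporal_kernel_length: int = 16
    spatial_depth_multiplier: int = 2
    separable_kernel_length: int = 64
    n_filters: int = 8
    dropout_rate: float = 0.25
    residual_blocks: int = 4

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.temporal_kernel_length, self.separable_kernel_length) < 1:
            raise ValueError("kernel lengths must be >= 1")

    @property
    def named_layers(self) -> tuple[str, ...]:
        if self.family == "eegnet_style":
            return ("conv1", "conv2", "conv3")
        if self.family == "residual_small":
            return tuple(f"conv{i}" for i in range(1, 2 * self.residual_blocks + 2))
        return ()


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd_momentum"
    learning_rate: float = 1e-4
    momentum: float = 0.5
    lr_decay_factor: float = 0.94
    decay_staircase: bool = True
    lr_decay_every: int = 10
    batch_size: int = 64
    max_epochs: int = 500
    early_stop_patience: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.early_stop_patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")


# --------------------------------------------------------------------------
# CNN estimators
# --------------------------------------------------------------------------


class EarlyStopper:
    """Stop training when the monitored loss has not decreased for
    ``patience`` consecutive epochs; tracks the best epoch for weight restore.

    With patience 25 and a loss that only decreases at the first epoch, the
    26th epoch triggers the stop.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record this epoch's loss; return True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class _CNNClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery for the numpy CNN decoders."""

    # subclasses set: family; _build(n_channels, n_samples, n_classes, rng)

    def _validate_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_channels, n_samples)")
        return X

    def _make_optimizer(self, net):
        if self.optimizer == "sgd_momentum":
            return SGDMomentum(net, lr=self.learning_rate, momentum=self.momentum,
                               decay=self.lr_decay_factor, staircase=self.decay_staircase,
                               decay_every=self.lr_decay_every)
        if self.optimizer == "adam":
            return Adam(net, lr=self.learning_rate)
        raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, n_ch, n_t = X.shape
        if min(self._kernels()) > n_t:
            raise ValueError("convolution kernel longer than the input time axis")
        self.scale_ = float(X.std()) or 1.0
        X = X / self.scale_
        rng = np.random.default_rng([int(self.random_state or 0), 1])
        self.net_ = self._build(n_ch, n_t, len(self.classes_), rng)
        if str(self.compute_dtype) in ("float32", "<f4"):
            self.net_.cast(np.float32)
        self.n_channels_, self.n_samples_ = n_ch, n_t
        opt = self._make_optimizer(self.net_)
        shuffle_rng = np.random.default_rng([int(self.random_state or 0), 2])

        T = one_hot(y, self.classes_)
        has_val = X_val is not None
        if has_val:
            X_val = self._validate_X(X_val) / self.scale_
            T_val = one_hot(np.asarray(y_val), self.classes_)

        stopper = EarlyStopper(self.early_stop_patience)
        best_state = None
        hist = []
        for epoch in range(self.max_epochs):
            opt.set_epoch(epoch)
            order = shuffle_rng.permutation(n)
            tr_loss_sum = 0.0
            tr_correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, tb = X[idx], T[idx]
                logits = self.net_.forward(xb, training=True)
                probs = softmax(logits)
                p = np.maximum(probs, np.finfo(float).eps)
                loss = float(-(tb * np.log(p)).sum(axis=1).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or check the input scale")
                tr_loss_sum += loss * len(idx)
                tr_correct += int((probs.argmax(1) == tb.argmax(1)).sum())
                self.net_.backward((probs - tb) / len(idx), input_grad=False)
                opt.step()
            train_loss = tr_loss_sum / n
            train_acc = tr_correct / n
            if has_val:
                val_probs = self.net_.predict_proba(X_val)
                val_loss = cross_entropy(T_val, val_probs)
                val_acc = float((val_probs.argmax(1) == T_val.argmax(1)).mean())
            else:
                val_loss, val_acc = train_loss, train_acc
            hist.append((epoch, train_loss, val_loss, train_acc, val_acc))
            improved = val_loss < stopper.best_loss
            stop = stopper.update(epoch, val_loss)
            if improved:
                best_state = self.net_.state_dict()
            if stop:
                break
        if best_state is not None:
            self.net_.load_state_dict(best_state)
        self.best_epoch_ = stopper.best_epoch
        self.history_ = pd.DataFrame(
            hist, columns=["epoch", "train_loss", "val_loss", "train_acc", "val_acc"])
        return self

    def predict_proba(self, X):
        X = self._validate_X(X) / self.scale_
        return self.net_.predict_proba(X)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    @property
    def named_layers_(self) -> tuple[str, ...]:
        return tuple(self.net_.registry)


class EEGNetClassifier(_CNNClassifierBase):
    """Compact 3-convolution EEG decoder.

    Layer roles: ``conv1`` extracts temporal filters shared across
    electrodes, ``conv2`` is a depthwise spatial filter spanning the full
    electrode axis, and ``conv3`` is a separable temporal convolution mixing
    the resulting spatio-temporal features.  Defaults follow the compact-CNN
    convention for EEG (temporal kernel 16, separable kernel 64, SGD with
    momentum 0.5, learning rate 1e-4, staircase decay 0.94, batch 64,
    early stopping with patience 25).
    """

    family = "eegnet_style"

    def __init__(self, temporal_kernel_length: int = 16, separable_kernel_length: int = 64,
                 n_filters: int = 8, spatial_depth_multiplier: int = 2,
                 dropout_rate: float = 0.25, optimizer: str = "sgd_momentum",
                 learning_rate: float = 1e-4, momentum: float = 0.5,
                 lr_decay_factor: float = 0.94, decay_staircase: bool = True,
                 lr_decay_every: int = 10, batch_size: int = 64, max_epochs: int = 500,
                 early_stop_patience: int = 25, random_state: int | None = 0,
                 compute_dtype: str = "float64"):
        self.temporal_kernel_length = temporal_kernel_length
        self.separable_kernel_length = separable_kernel_length
        self.n_filters = n_filters
        self.spatial_depth_multiplier = spatial_depth_multiplier
        self.dropout_rate = dropout_rate
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lr_decay_factor = lr_decay_factor
        self.decay_staircase = decay_staircase
        self.lr_decay_every = lr_decay_every
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state
        self.compute_dtype = compute_dtype

    def _kernels(self):
        return (self.temporal_kernel_length, self.separable_kernel_length)

    def _build(self, n_ch, n_t, n_classes, rng):
        F1 = self.n_filters
        D = self.spatial_depth_multiplier
        F2 = F1 * D
        drop_rng = np.random.default_rng([int(self.random_state or 0), 3])
        conv1 = L.TemporalConv(1, F1, self.temporal_kernel_length, rng)
        conv2 = L.SpatialDepthwiseConv(F1, D, n_ch, rng)
        conv3_depth = L.DepthwiseTemporalConv(F2, self.separable_kernel_length, rng)
        conv3_point = L.PointwiseConv(F2, F2, rng)
        stack = [
            conv1,
            conv2, L.BatchNorm(F2), L.ELU(),
            L.Dropout(self.dropout_rate, drop_rng),
            conv3_depth, conv3_point, L.BatchNorm(F2), L.ELU(),
            L.AvgPoolTime(8),
            L.Dropout(self.dropout_rate, drop_rng),
            L.Flatten(),
            L.Dense(F2 * (n_t // 8), n_classes, rng),
        ]
        registry = {"conv1": conv1, "conv2": conv2, "conv3": conv3_point}
        return Network(stack, registry, time_strides={k: 1 for k in registry})


class ResidualCNNClassifier(_CNNClassifierBase):
    """Reduced residual CNN: initial temporal convolution plus
    identity-shortcut blocks of two temporal convolutions each, global
    average pooling and a softmax head; trained with Adam (lr 1e-3).

    A deliberately shallow stand-in for image-scale residual networks,
    keeping the early / intermediate / late layer roles addressable for
    attribution while remaining trainable at workstation scale.
    """

    family = "residual_small"

    def __init__(self, n_blocks: int = 4, kernel_length: int = 7, n_filters: int = 16,
                 dropout_rate: float = 0.25, optimizer: str = "adam",
                 learning_rate: float = 1e-3, momentum: float = 0.0,
                 lr_decay_factor: float = 1.0, decay_staircase: bool = True,
                 lr_decay_every: int = 10, batch_size: int = 64, max_epochs: int = 500,
                 early_stop_patience: int = 25, random_state: int | None = 0,
                 compute_dtype: str = "float64"):
        self.n_blocks = n_blocks
        self.kernel_length = kernel_length
        self.n_filters = n_filters
        self.dropout_rate = dropout_rate
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lr_decay_factor = lr_decay_factor
        self.decay_staircase = decay_staircase
        self.lr_decay_every = lr_decay_every
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state
        self.compute_dtype = compute_dtype

    def _kernels(self):
        return (self.kernel_length,)

    def _build(self, n_ch, n_t, n_classes, rng):
        F1 = self.n_filters
        F2 = 2 * F1
        k = self.kernel_length
        drop_rng = np.random.default_rng([int(self.random_state or 0), 3])
        registry: dict[str, L.Layer] = {}
        strides: dict[str, int] = {}
        conv_i = 1

        def named_conv(in_f, out_f, stride):
            nonlocal conv_i
            c = L.TemporalConv(in_f, out_f, k, rng)
            registry[f"conv{conv_i}"] = c
            strides[f"conv{conv_i}"] = stride
            conv_i += 1
            return c

        stack: list[L.Layer] = [named_conv(1, F1, 1), L.BatchNorm(F1), L.ReLU(),
                                L.AvgPoolTime(2)]
        half = (self.n_blocks + 1) // 2
        for b in range(self.n_blocks):
            if b == half:  # widen and downsample mid-stack
                stack += [L.PointwiseConv(F1, F2, rng), L.BatchNorm(F2), L.ReLU(),
                          L.AvgPoolTime(2)]
            f = F1 if b < half else F2
            stride = 2 if b < half else 4
            inner = [named_conv(f, f, stride), L.BatchNorm(f), L.ReLU(),
                     named_conv(f, f, stride), L.BatchNorm(f)]
            stack += [L.ResidualBlock(inner), L.ReLU()]
        stack += [L.Dropout(self.dropout_rate, drop_rng), L.GlobalAvgPool(),
                  L.Dense(F2 if self.n_blocks > half else F1, n_classes, rng)]
        return Network(stack, registry, time_strides=strides)


# --------------------------------------------------------------------------
# time-point-wise logistic regression baseline
# --------------------------------------------------------------------------


class PointwiseLogisticDecoder(ClassifierMixin, BaseEstimator):
    """One multinomial logistic regression per time point (ridge-penalised).

    ``score_timecourse`` returns the per-time-point test accuracy curve; the
    headline number for this baseline is the maximum of that curve.
    """

    def __init__(self, regularization: float = 1.0, max_iter: int = 200):
        self.regularization = regularization
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.models_ = []
        for t in range(X.shape[2]):
            m = LogisticRegression(C=1.0 / self.regularization, max_iter=self.max_iter)
            m.fit(X[:, :, t], y)
            self.models_.append(m)
        return self

    def predict_timecourse(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([m.predict(X[:, :, t]) for t, m in enumerate(self.models_)])

    def score_timecourse(self, X, y) -> np.ndarray:
        preds = self.predict_timecourse(X)
        y = np.asarray(y)
        return np.array([categorical_accuracy(p, y) for p in preds])

    def predict(self, X):
        """Majority prediction of the best-performing time point on the
        training data is not defined; use the peak accuracy workflow via
        score_timecourse. For API completeness, predict at the middle sample."""
        X = np.asarray(X, dtype=float)
        return self.models_[len(self.models_) // 2].predict(X[:, :, len(self.models_) // 2])


def pointwise_logreg_baseline(train: EpochsSet, test: EpochsSet,
                              regularization: float = 1.0):
    """Accuracy(t) of per-time-point logistic regression, and its maximum."""
    if train.n_channels != test.n_channels or train.n_samples != test.n_samples:
        raise ValueError("train and test must share channel and sample grids")
    dec = PointwiseLogisticDecoder(regularization=regularization)
    dec.fit(train.data, train.labels)
    curve = dec.score_timecourse(test.data, test.labels)
    return curve, float(curve.max())


# --------------------------------------------------------------------------
# spec-level wrappers: build / train / evaluate
# --------------------------------------------------------------------------


@dataclass
class TrainedDecoder:
    """A fitted decoder plus its provenance for attribution."""

    estimator: _CNNClassifierBase
    spec: ArchitectureSpec
    history: pd.DataFrame
    fold_id: int
    class_names: tuple[str, ...]
    train_participants: tuple = ()
    val_participants: tuple = ()

    @property
    def net(self) -> Network:
        return self.estimator.net_


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    per_trial_predictions: np.ndarray
    per_trial_correct: np.ndarray

    def __post_init__(self):
        if self.accuracy != float(np.mean(self.per_trial_correct)):
            raise ValueError("accuracy must equal mean(per_trial_correct)")


def build_decoder(spec: ArchitectureSpec, n_channels: int, n_samples: int,
                  n_classes: int, seed: int = 0,
                  train_config: TrainConfig | None = None) -> _CNNClassifierBase:
    """Instantiate an untrained estimator for the given architecture family."""
    cfg = train_config or default_train_config(spec.family)
    common = dict(dropout_rate=spec.dropout_rate, optimizer=cfg.optimizer,
                  learning_rate=cfg.learning_rate, momentum=cfg.momentum,
                  lr_decay_factor=cfg.lr_decay_factor,
                  decay_staircase=cfg.decay_staircase,
                  lr_decay_every=cfg.lr_decay_every, batch_size=cfg.batch_size,
                  max_epochs=cfg.max_epochs,
                  early_stop_patience=cfg.early_stop_patience, random_state=seed)
    if spec.family == "eegnet_style":
        if max(spec.temporal_kernel_length, spec.separable_kernel_length) > n_samples:
            raise ValueError("kernel longer than the input time axis")
        est = EEGNetClassifier(temporal_kernel_length=spec.temporal_kernel_length,
                               separable_kernel_length=spec.separable_kernel_length,
                               n_filters=spec.n_filters,
                               spatial_depth_multiplier=spec.spatial_depth_multiplier,
                               **common)
    elif spec.family == "residual_small":
        est = ResidualCNNClassifier(n_blocks=spec.residual_blocks,
                                    n_filters=spec.n_filters * 2, **common)
    else:
        raise ValueError("build_decoder only constructs CNN families")
    return est


def default_train_config(family: str) -> TrainConfig:
    if family == "eegnet_style":
        return TrainConfig(optimizer="sgd_momentum", learning_rate=1e-4, momentum=0.5,
                           lr_decay_factor=0.94, decay_staircase=True)
    if family == "residual_small":
        return TrainConfig(optimizer="adam", learning_rate=1e-3, momentum=0.0,
                           lr_decay_factor=1.0)
    raise ValueError(f"no training defaults for family {family!r}")


def train_decoder(decoder: _CNNClassifierBase, train: EpochsSet, val: EpochsSet,
                  cfg: TrainConfig | None = None, fold_id: int = 0,
                  spec: ArchitectureSpec | None = None) -> TrainedDecoder:
    """Fit with early stopping on validation loss; leakage between train and
    validation participants is rejected."""
    overlap = set(train.participants) & set(val.participants)
    if overlap:
        raise ValueError(f"participant leakage between train and val: {sorted(overlap)}")
    if train.n_channels != val.n_channels or train.n_samples != val.n_samples:
        raise ValueError("train and val must share channel and sample grids")
    if cfg is not None:
        decoder.set_params(optimizer=cfg.optimizer, learning_rate=cfg.learning_rate,
                           momentum=cfg.momentum, lr_decay_factor=cfg.lr_decay_factor,
                           decay_staircase=cfg.decay_staircase,
                           lr_decay_every=cfg.lr_decay_every, batch_size=cfg.batch_size,
                           max_epochs=cfg.max_epochs,
                           early_stop_patience=cfg.early_stop_patience,
                           random_state=cfg.seed)
    decoder.fit(train.data, train.labels, X_val=val.data, y_val=val.labels)
    spec = spec or ArchitectureSpec(family=decoder.family)
    return TrainedDecoder(estimator=decoder, spec=spec, history=decoder.history_,
                          fold_id=fold_id, class_names=tuple(decoder.classes_.tolist()),
                          train_participants=tuple(sorted(set(train.participants))),
                          val_participants=tuple(sorted(set(val.participants))))


def evaluate_decoder(trained: TrainedDecoder, test: EpochsSet) -> EvaluationResult:
    """Held-out categorical accuracy with per-trial correctness retained."""
    unknown = set(np.unique(test.labels)) - set(trained.class_names)
    if unknown:
        raise ValueError(f"test classes unknown to the decoder: {sorted(unknown)}")
    preds = trained.estimator.predict(test.data)
    correct = preds == test.labels
    return EvaluationResult(accuracy=float(np.mean(correct)),
                            per_trial_predictions=preds,
                            per_trial_correct=correct)
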