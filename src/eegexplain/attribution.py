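"""Gradient attributions for trained decoders and their group-level aggregation.

Saliency is the gradient of the target class's pre-softmax score with
respect to the input, so it lives on the input channels x samples grid and
is signed at the trial level.  Grad-CAM weighs a convolution layer's feature
maps by their globally average-pooled gradients, sums, rectifies, and is
resampled back to the input grid; it is nonnegative by construction.

Group-level maps follow a strict hierarchy: average over correctly
predicted trials, then over participants, then over cross-validation folds,
separately per experimental condition (class).  Trial-level saliency is
converted to absolute values at aggregation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decoding import EvaluationResult, TrainedDecoder, one_hot
from .nn.network import softmax
from .simulate import EpochsSet

logger = logging.getLogger(__name__)

LAYER_PRESETS = ("early", "intermediate", "late")


@dataclass
class AttributionMap:
    """A channels x samples importance grid aligned to the input time axis."""

    values: np.ndarray
    method: str  # "saliency" | "gradcam"
    layer: str  # convolution identifier or "input"
    target_class: str
    sign_convention: str  # "signed" | "nonnegative"
    provenance: tuple  # (fold, participant, trial) or (..., "aggregate")
    times: np.ndarray | None = None
    dead_layer: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("attribution values must be channels x samples")
        if self.method == "gradcam" and np.any(self.values < -1e-12):
            raise ValueError("gradcam maps must be nonnegative")


# --------------------------------------------------------------------------
# trial-level attributions
# --------------------------------------------------------------------------


def _score_gradients(trained: TrainedDecoder, trials: np.ndarray,
                     target_classes: np.ndarray, capture: Sequence[str] = (),
                     score: str = "logit"):
    """Backpropagate the score of each trial's target class.

    ``score`` selects the differentiated quantity: the pre-softmax logit
    (default; standard and numerically stabler) or the softmax probability.
    Returns d(score)/d(input); captured feature maps/gradients are left on
    the network for the caller to read.
    """
    if score not in ("logit", "softmax"):
        raise ValueError(f"unknown score target {score!r}")
    net = trained.net
    net.set_capture(capture)
    classes = np.asarray(trained.class_names)
    sel = one_hot(target_classes, classes)
    # the decoder standardises its input; chain rule maps the gradient back
    # to the original microvolt scale
    scale = float(getattr(trained.estimator, "scale_", 1.0))
    logits = net.forward(trials / scale, training=False)
    if score == "softmax":
        p = softmax(logits)
        p_target = (p * sel).sum(axis=1, keepdims=True)
        sel = p_target * (sel - p)  # d softmax_c / d logits
    return net.backward(sel) / scale


def saliency_maps(trained: TrainedDecoder, trials: np.ndarray,
                  target_classes: np.ndarray, score: str = "logit") -> np.ndarray:
    """Vectorised trial-level saliency: (n_trials, channels, samples), signed."""
    trials = np.asarray(trials, dtype=float)
    return _score_gradients(trained, trials, np.asarray(target_classes),
                            score=score)


def saliency_map(trained: TrainedDecoder, trial: np.ndarray, target_class,
                 times: np.ndarray | None = None, fold: int | None = None,
                 participant=None, trial_id=None) -> AttributionMap:
    """Gradient of the target class score w.r.t. one channels x samples trial."""
    g = saliency_maps(trained, np.asarray(trial)[None], np.asarray([target_class]))[0]
    return AttributionMap(g, "saliency", "input", str(target_class), "signed",
                          (fold, participant, trial_id), times)


def _resample_to_input(cam: np.ndarray, n_channels: int, n_samples: int,
                       time_stride: int) -> np.ndarray:
    """Map a (batch, C', T') layer grid onto the input (C, T) grid: linear
    interpolation along time, nearest-neighbour/broadcast along channels."""
    B, Cp, Tp = cam.shape
    if Tp != n_samples:
        centers = (np.arange(Tp) + 0.5) * time_stride - 0.5
        t_in = np.arange(n_samples)
        cam = np.stack([
            np.stack([np.interp(t_in, centers, cam[b, c]) for c in range(Cp)])
            for b in range(B)])
    if Cp == n_channels:
        return cam
    if Cp == 1:
        return np.broadcast_to(cam, (B, n_channels, cam.shape[2])).copy()
    idx = np.minimum((np.arange(n_channels) * Cp) // n_channels, Cp - 1)
    return cam[:, idx, :]


def gradcam_maps(trained: TrainedDecoder, trials: np.ndarray,
                 target_classes: np.ndarray, layer: str,
                 score: str = "logit") -> tuple[np.ndarray, bool]:
    """Vectorised Grad-CAM at a named convolution; returns (maps, dead_flag)."""
    trials = np.asarray(trials, dtype=float)
    net = trained.net
    if layer not in net.registry:
        raise KeyError(f"layer {layer!r} not in named layers {sorted(net.registry)}")
    _score_gradients(trained, trials, np.asarray(target_classes), capture=[layer],
                     score=score)
    A, G = net.captured(layer)  # (B, K, C', T') feature maps and gradients
    w = G.mean(axis=(2, 3))  # global average pooling over the map grid (1/Z sum)
    cam = np.einsum("bk,bkct->bct", w, A, optimize=True)
    cam = np.maximum(cam, 0.0)
    dead = bool(np.all(G == 0))
    if dead:
        logger.warning("layer %r has zero gradients for all requested trials", layer)
    stride = net.time_strides.get(layer, 1)
    out = _resample_to_input(cam, trials.shape[1], trials.shape[2], stride)
    return out, dead


def gradcam_map(trained: TrainedDecoder, trial: np.ndarray, target_class, layer: str,
                times: np.ndarray | None = None, fold: int | None = None,
                participant=None, trial_id=None) -> AttributionMap:
    """ReLU of gradient-weighted feature maps at one convolution layer.

    A dead layer (all-zero gradients) yields an all-zero map flagged
    ``dead_layer`` rather than an error.
    """
    vals, dead = gradcam_maps(trained, np.asarray(trial)[None],
                              np.asarray([target_class]), layer)
    return AttributionMap(vals[0], "gradcam", layer, str(target_class), "nonnegative",
                          (fold, participant, trial_id), times, dead_layer=dead)


def resolve_layer_preset(trained: TrainedDecoder, preset: str,
                         probe_trial: np.ndarray | None = None) -> str:
    """Map early/intermediate/late onto this decoder's named convolutions.

    For the residual family the late layer is the deepest convolution that
    still receives nonzero gradients (checked on a probe trial when given).
    """
    names = list(trained.net.registry)
    if preset in names:
        return preset
    if preset not in LAYER_PRESETS:
        raise ValueError(f"unknown layer preset {preset!r}")
    if preset == "early":
        return names[0]
    if preset == "intermediate":
        return names[1] if len(names) > 1 else names[0]
    # late: deepest with gradient flow
    for name in reversed(names):
        if probe_trial is None:
            return name
        _, dead = gradcam_maps(trained, probe_trial[None],
                               np.asarray([trained.class_names[0]]), name)
        if not dead:
            return name
    return names[-1]


# --------------------------------------------------------------------------
# correct-trial filtering and hierarchical aggregation
# --------------------------------------------------------------------------


def select_correct_trials(evaluation: EvaluationResult) -> np.ndarray:
    """Indices of correctly predicted trials (the only ones attributed)."""
    return np.flatnonzero(evaluation.per_trial_correct)


def aggregate_maps(maps: Sequence[AttributionMap]) -> AttributionMap:
    """Hierarchical mean: trials -> participants -> folds, in that order.

    All maps must share method, layer and target class.  Saliency values are
    rectified (absolute value) before any averaging, so aggregates of both
    methods are nonnegative.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to aggregate")
    key = (maps[0].method, maps[0].layer, maps[0].target_class)
    shape = maps[0].values.shape
    for m in maps:
        if (m.method, m.layer, m.target_class) != key:
            raise ValueError("maps mix methods, layers or classes")
        if m.values.shape != shape:
            raise ValueError("maps must share the channels x samples grid")

    by_fold: dict = {}
    for m in maps:
        fold, participant = m.provenance[0], m.provenance[1]
        v = np.abs(m.values) if m.method == "saliency" else m.values
        by_fold.setdefault(fold, {}).setdefault(participant, []).append(v)

    fold_means = []
    for fold, parts in sorted(by_fold.items(), key=lambda kv: str(kv[0])):
        part_means = [np.mean(vs, axis=0) for _, vs in
                      sorted(parts.items(), key=lambda kv: str(kv[0]))]
        fold_means.append(np.mean(part_means, axis=0))
    agg = np.mean(fold_means, axis=0)
    return AttributionMap(agg, maps[0].method, maps[0].layer, maps[0].target_class,
                          "nonnegative", ("all", "all", "aggregate"), maps[0].times)


@dataclass
class ConditionMaps:
    """Aggregate and per-participant maps for one (method, layer, condition).

    ``per_participant_eeg`` holds the mean EEG over exactly the trials that
    produced each participant's feature map, so interpretability scores
    correlate like with like.
    """

    method: str
    layer: str
    condition: str
    aggregate: np.ndarray  # channels x samples
    per_participant: dict  # participant -> channels x samples (fold-averaged)
    per_participant_eeg: dict  # participant -> mean EEG over the same trials
    times: np.ndarray


def attribute_condition(trained_folds: Sequence[TrainedDecoder], epochs: EpochsSet,
                        evaluations: Sequence[EvaluationResult], condition: str,
                        method: str, layer: str, batch_size: int = 128) -> ConditionMaps:
    """Trial-level attributions for one class across folds, aggregated.

    For each fold's decoder, all correctly predicted trials of the condition
    (from every participant, by default) are attributed with the trial's
    true class as the backpropagation target, then averaged
    trials -> participants -> folds.
    """
    if method not in ("saliency", "gradcam"):
        raise ValueError(f"unknown method {method!r}")
    fold_means = []
    per_participant_accum: dict = {}
    per_participant_eeg_accum: dict = {}
    for trained, evaluation in zip(trained_folds, evaluations):
        correct = select_correct_trials(evaluation)
        sel = correct[epochs.labels[correct] == condition]
        if sel.size == 0:
            logger.warning("fold %s: no correct %r trials; fold skipped for this "
                           "condition", trained.fold_id, condition)
            continue
        part_means = {}
        for p in np.unique(epochs.participants[sel]):
            idx = sel[epochs.participants[sel] == p]
            vals_sum = None
            for start in range(0, idx.size, batch_size):
                chunk = idx[start:start + batch_size]
                if method == "saliency":
                    v = np.abs(saliency_maps(trained, epochs.data[chunk],
                                             epochs.labels[chunk]))
                else:
                    v, _ = gradcam_maps(trained, epochs.data[chunk],
                                        epochs.labels[chunk], layer)
                vals_sum = v.sum(axis=0) if vals_sum is None else vals_sum + v.sum(axis=0)
            part_means[p] = vals_sum / idx.size
            per_participant_eeg_accum.setdefault(p, []).append(
                epochs.data[idx].mean(axis=0))
        for p, m in part_means.items():
            per_participant_accum.setdefault(p, []).append(m)
        fold_means.append(np.mean(list(part_means.values()), axis=0))
    if not fold_means:
        raise ValueError(f"no correct trials for condition {condition!r} in any fold")
    per_participant = {p: np.mean(ms, axis=0) for p, ms in per_participant_accum.items()}
    per_participant_eeg = {p: np.mean(ms, axis=0)
                           for p, ms in per_participant_eeg_accum.items()}
    return ConditionMaps(method=method, layer=layer, condition=condition,
                         aggregate=np.mean(fold_means, axis=0),
                         per_participant=per_participant,
                         per_participant_eeg=per_participant_eeg, times=epochs.times)
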