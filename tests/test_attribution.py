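"""Saliency and Grad-CAM against independent oracles; aggregation rules."""

from types import SimpleNamespace

import numpy as np
import pytest

from eegexplain.attribution import (AttributionMap, aggregate_maps,
                                    gradcam_map, gradcam_maps,
                                    resolve_layer_preset, saliency_map,
                                    saliency_maps, select_correct_trials)
from eegexplain.decoding import (ArchitectureSpec, EvaluationResult,
                                 TrainedDecoder, one_hot)
from eegexplain.nn import layers as L
from eegexplain.nn.network import Network


def _stub(net, class_names):
    est = SimpleNamespace(net_=net, scale_=1.0)
    return TrainedDecoder(est, ArchitectureSpec(), None, 0, tuple(class_names))


def test_saliency_of_linear_model_equals_weight_row():
    """For S_c = w_c . x the input gradient is w_c, independent of x."""
    rng = np.random.default_rng(0)
    dense = L.Dense(4 * 6, 3, rng)
    net = Network([L.Flatten(), dense], registry={})
    trained = _stub(net, ["a", "b", "c"])
    for x in (np.zeros((4, 6)), rng.normal(size=(4, 6))):
        m = saliency_map(trained, x, "b")
        assert m.values.shape == (4, 6)
        assert np.allclose(m.values, dense.W[1].reshape(4, 6))
        assert m.sign_convention == "signed" and m.layer == "input"
    # softmax score target: d softmax_b/dx = p_b (w_b - sum_j p_j w_j)
    x = rng.normal(size=(4, 6))
    z = dense.W @ x.ravel() + dense.b
    p = np.exp(z - z.max())
    p /= p.sum()
    expected = p[1] * (dense.W[1] - p @ dense.W)
    g = saliency_maps(trained, x[None], np.array(["b"]), score="softmax")[0]
    assert np.allclose(g, expected.reshape(4, 6))


@pytest.mark.parametrize("family", ["eegnet", "resnet"])
def test_saliency_matches_finite_differences(family, fitted_eegnet,
                                             fitted_resnet, tiny_epochs):
    trained = fitted_eegnet if family == "eegnet" else fitted_resnet
    x = tiny_epochs.data[3]
    cls = trained.class_names[0]
    g = saliency_maps(trained, x[None], np.array([cls]))[0]
    net, scale = trained.net, trained.estimator.scale_
    rng = np.random.default_rng(1)
    eps = 1e-3
    def fd_at(c, t, e):
        xp, xm = x.copy(), x.copy()
        xp[c, t] += e
        xm[c, t] -= e
        # S evaluated through the decoder's own input scaling; the gradient
        # w.r.t. the raw input needs no extra factor in the difference quotient
        return (net.forward(xp[None] / scale)[0, 0]
                - net.forward(xm[None] / scale)[0, 0]) / (2 * e)

    checked = 0
    for _ in range(20):
        c = int(rng.integers(x.shape[0]))
        t = int(rng.integers(x.shape[1]))
        fd, fd2 = fd_at(c, t, eps), fd_at(c, t, eps / 2)
        if abs(fd - fd2) > 1e-4 * max(abs(fd), 1e-6):
            continue  # secant straddles a ReLU kink; fd is not a valid oracle
        assert abs(fd - g[c, t]) <= 1e-3 * max(abs(fd), 1e-6)
        checked += 1
    assert checked >= 10


@pytest.mark.parametrize("family", ["eegnet", "resnet"])
def test_gradcam_matches_explicit_per_map_loop(family, fitted_eegnet,
                                               fitted_resnet, tiny_epochs):
    """Vectorised Grad-CAM equals the brute-force loop over feature maps
    (pool each map's gradient, weight, sum, rectify) at every named layer."""
    trained = fitted_eegnet if family == "eegnet" else fitted_resnet
    net = trained.net
    trials = tiny_epochs.data[:3]
    targets = tiny_epochs.labels[:3]
    classes = np.asarray(trained.class_names)
    for layer in net.registry:
        fast, _ = gradcam_maps(trained, trials, targets, layer)
        net.set_capture([layer])
        net.forward(trials / trained.estimator.scale_)
        net.backward(one_hot(targets, classes))
        A, G = net.captured(layer)
        B, K = A.shape[:2]
        slow = np.zeros(A.shape[:1] + A.shape[2:])
        for b in range(B):
            for k in range(K):
                w_kc = G[b, k].mean()  # (1/Z) sum_i sum_j dS/dA
                slow[b] += w_kc * A[b, k]
        slow = np.maximum(slow, 0.0)
        from eegexplain.attribution import _resample_to_input
        slow = _resample_to_input(slow, trials.shape[1], trials.shape[2],
                                  net.time_strides.get(layer, 1))
        assert np.allclose(fast, slow, atol=1e-6), layer
        assert fast.min() >= 0.0
        assert fast.shape == trials.shape


def test_gradcam_dead_layer_flagged_not_error(fitted_eegnet, tiny_epochs):
    """Zeroing the head silences all gradients; the map is zeros + flag."""
    trained = fitted_eegnet
    state = trained.net.state_dict()
    try:
        head = trained.net.layers[-1]
        head.W[...] = 0.0
        head.b[...] = 0.0
        m = gradcam_map(trained, tiny_epochs.data[0], tiny_epochs.labels[0],
                        "conv1")
        assert m.dead_layer
        assert np.all(m.values == 0)
    finally:
        trained.net.load_state_dict(state)


def test_layer_presets(fitted_eegnet, fitted_resnet, tiny_epochs):
    probe = tiny_epochs.data[0]
    assert resolve_layer_preset(fitted_eegnet, "early") == "conv1"
    assert resolve_layer_preset(fitted_eegnet, "intermediate") == "conv2"
    assert resolve_layer_preset(fitted_eegnet, "late") == "conv3"
    late = resolve_layer_preset(fitted_resnet, "late", probe)
    assert late in fitted_resnet.net.registry
    with pytest.raises(ValueError):
        resolve_layer_preset(fitted_eegnet, "deepest")


def test_select_correct_trials_indices():
    ev = EvaluationResult(0.5, np.array(["a", "a", "a", "a"]),
                          np.array([True, False, True, False]))
    assert list(select_correct_trials(ev)) == [0, 2]
    ev_none = EvaluationResult(0.0, np.array(["a"]), np.array([False]))
    assert select_correct_trials(ev_none).size == 0


def _map(vals, fold, participant, method="gradcam"):
    return AttributionMap(np.asarray(vals, float), method, "conv1", "a",
                          "nonnegative" if method == "gradcam" else "signed",
                          (fold, participant, 0))


def test_hierarchical_mean_order_of_averaging():
    """Participant A: one trial at 1.0; participant B: three at 0.0.
    Trials->participants gives 0.5; a pooled mean would give 0.25."""
    maps = [_map([[1.0]], 0, "A")] + [_map([[0.0]], 0, "B")] * 3
    agg = aggregate_maps(maps)
    assert agg.values[0, 0] == 0.5


def test_balanced_design_equals_pooled_mean():
    rng = np.random.default_rng(0)
    vals = rng.random((4, 3, 5))  # 2 participants x 2 trials
    maps = [_map(vals[0], 0, "A"), _map(vals[1], 0, "A"),
            _map(vals[2], 0, "B"), _map(vals[3], 0, "B")]
    agg = aggregate_maps(maps)
    assert np.allclose(agg.values, vals.mean(axis=0))


def test_aggregation_is_idempotent_and_rectifies_saliency():
    m = np.array([[1.0, -2.0], [0.5, -0.25]])
    maps = [_map(m, f, p, method="saliency") for f in (0, 1) for p in ("A", "B")]
    agg = aggregate_maps(maps)
    assert np.allclose(agg.values, np.abs(m))
    assert agg.sign_convention == "nonnegative"
    with pytest.raises(ValueError):
        aggregate_maps([])


def test_aggregate_rejects_mixed_maps():
    with pytest.raises(ValueError, match="mix"):
        aggregate_maps([_map([[1.0]], 0, "A"),
                        _map([[1.0]], 0, "A", method="saliency")])
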