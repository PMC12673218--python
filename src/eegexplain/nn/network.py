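"""Feed-forward network container with input- and feature-map gradient access."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer, call_backward, call_forward


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """Ordered stack of layers mapping ``(batch, channels, time)`` to class logits.

    Parameters
    ----------
    layers
        Sequence of layers; the first axis-expanding reshape (adding the
        feature-map axis) is handled internally.
    registry
        Mapping from attribution-eligible layer names (e.g. ``"conv1"``) to
        the layer objects whose *post-activation* output constitutes the
        feature maps A^k for that name.  Layers may be nested inside
        residual blocks.
    time_strides
        Mapping from each registered name to the cumulative temporal
        downsampling factor at that point in the stack (1 when no pooling
        precedes it); used to align feature-map grids with the input axis.
    """

    def __init__(self, layers: list[Layer], registry: dict[str, Layer],
                 time_strides: dict[str, int] | None = None):
        self.layers = layers
        self.registry = registry
        self.time_strides = dict(time_strides or {})
        self.dtype = np.float64

    def cast(self, dtype) -> None:
        """Switch the compute precision of the whole stack (weights + activations)."""
        for layer in self.layers:
            layer.cast(dtype)
        self.dtype = dtype

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Return logits for inputs shaped (batch, channels, time)."""
        h = np.asarray(x, dtype=self.dtype)[:, None, :, :]  # add feature-map axis
        for layer in self.layers:
            h = call_forward(layer, h, training)
        self._n_input = x.shape
        return h

    def backward(self, grad_logits: np.ndarray, input_grad: bool = True):
        """Backpropagate d(score)/d(logits); return d(score)/d(input).

        With ``input_grad=False`` (the training path) the first layer only
        accumulates parameter gradients and None is returned.
        """
        g = np.asarray(grad_logits, dtype=self.dtype)
        for layer in reversed(self.layers[1:]):
            g = call_backward(layer, g)
        first = self.layers[0]
        if not input_grad and hasattr(first, "backward_params_only"):
            if getattr(first, "capture", False):
                first.captured_grad = g
            first.backward_params_only(g)
            return None
        g = call_backward(first, g)
        return g[:, 0, :, :]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    # -- attribution plumbing ----------------------------------------------
    def set_capture(self, names) -> None:
        for layer in self.registry.values():
            layer.capture = False
            layer.captured_output = None
            layer.captured_grad = None
        for name in names:
            if name not in self.registry:
                raise KeyError(f"unknown layer {name!r}; known: {sorted(self.registry)}")
            self.registry[name].capture = True

    def captured(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        layer = self.registry[name]
        if layer.captured_output is None or layer.captured_grad is None:
            raise RuntimeError(f"layer {name!r} was not captured in the last pass")
        return layer.captured_output, layer.captured_grad

    # -- parameters ----------------------------------------------------------
    def named_params(self):
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                yield f"layer{i}.{k}", layer, k, v

    def trainable(self):
        """(param, grad) pairs for the optimiser, re-read each call."""
        pairs = []
        for layer in self.layers:
            p, g = layer.params(), layer.grads()
            for k in g:  # grads() keys define what is trained
                pairs.append((p[k], g[k]))
        return pairs

    def n_parameters(self) -> int:
        return int(sum(v.size for _, _, _, v in self.named_params()))

    def state_dict(self) -> dict:
        return {name: v.copy() for name, _, _, v in self.named_params()}

    def load_state_dict(self, state: dict) -> None:
        for name, _, _, v in self.named_params():
            v[...] = state[name]

    def clone_state(self) -> dict:
        return copy.deepcopy(self.state_dict())
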