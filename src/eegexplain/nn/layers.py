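"""Neural-network layers operating on 4-D arrays ``(batch, maps, channels, time)``.

Every layer implements an explicit ``forward``/``backward`` pair so that
gradients can be propagated all the way back to the input (for saliency
maps) and captured at intermediate feature maps (for Grad-CAM).  All
arithmetic is float64 numpy; the networks used here are small enough that
this is both fast and numerically transparent.

Backward passes are verified against central finite differences in the
test suite; do not "optimise" a backward without re-running those checks.
"""

from __future__ import annotations

import numpy as np
from scipy import fft


class Layer:
    """Base class: a differentiable map with named parameters."""

    def cast(self, dtype) -> None:
        """Convert all float64 array state (weights, stats) to ``dtype``."""
        for k, v in list(self.__dict__.items()):
            if isinstance(v, np.ndarray) and v.dtype == np.float64:
                setattr(self, k, v.astype(dtype))

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class TemporalConv(Layer):
    """Convolution along the time axis only (kernel height 1), 'same' padding.

    Weights have shape ``(out_maps, in_maps, kernel)`` and are shared across
    EEG channels, matching the temporal filters of compact EEG CNNs.  Both
    passes run as FFT correlations along time, which is exact for the batch
    sizes and kernel lengths used here and far cheaper than sliding windows.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.in_maps, self.out_maps, self.kernel = in_maps, out_maps, kernel
        self.W = _he_init(rng, (out_maps, in_maps, kernel), fan_in=in_maps * kernel)
        self.b = np.zeros(out_maps)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # 'same' padding: left (k-1)//2, right k//2
        self.pl = (kernel - 1) // 2
        self.pr = kernel // 2

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def _plan(self, T: int):
        n = fft.next_fast_len(T + self.kernel - 1)
        self._T, self._N = T, n

    def forward(self, x, training=False):
        T = x.shape[3]
        self._plan(T)
        n = self._N
        self._X = fft.rfft(x, n=n, axis=3)  # cached for the weight gradient
        # correlation with W == convolution with time-reversed W; the 'same'
        # window is then the contiguous slice [pr, pr + T)
        Wrf = fft.rfft(self.W[:, :, ::-1], n=n, axis=2)
        Yf = np.einsum("bfcn,ofn->bocn", self._X, Wrf, optimize=True)
        y_full = fft.irfft(Yf, n=n, axis=3)
        return y_full[..., self.pr:self.pr + T] + self.b[None, :, None, None]

    def backward(self, grad_out):
        n, T, k = self._N, self._T, self.kernel
        Gf = fft.rfft(grad_out, n=n, axis=3)
        # dW[u] = sum_{b,c,t} g[t] x[t - pl + u]
        Cf = np.einsum("bocn,bfcn->ofn", np.conj(Gf), self._X, optimize=True)
        c = fft.irfft(Cf, n=n, axis=2)
        self.dW = c[..., (np.arange(k) - self.pl) % n]
        self.db = grad_out.sum(axis=(0, 2, 3))
        # dx[s] = sum_{o,u} g[s + pl - u] W[u] = (g * W)[s + pl]
        Wf = fft.rfft(self.W, n=n, axis=2)
        Xf = np.einsum("bocn,ofn->bfcn", Gf, Wf, optimize=True)
        d_full = fft.irfft(Xf, n=n, axis=3)
        return d_full[..., self.pl:self.pl + T]

    def backward_params_only(self, grad_out):
        """Weight/bias gradients without the (unused) input gradient."""
        n, k = self._N, self.kernel
        Gf = fft.rfft(grad_out, n=n, axis=3)
        Cf = np.einsum("bocn,bfcn->ofn", np.conj(Gf), self._X, optimize=True)
        c = fft.irfft(Cf, n=n, axis=2)
        self.dW = c[..., (np.arange(k) - self.pl) % n]
        self.db = grad_out.sum(axis=(0, 2, 3))
        return np.zeros_like(self._x) if hasattr(self, "_x") else None


class DepthwiseTemporalConv(Layer):
    """Per-feature-map temporal convolution ('same' padding), FFT-based.

    The depthwise half of a separable convolution: map ``f`` gets its own
    kernel of length ``kernel``; no cross-map mixing.
    """

    def __init__(self, n_maps: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.n_maps, self.kernel = n_maps, kernel
        self.W = _he_init(rng, (n_maps, kernel), fan_in=kernel)
        self.b = np.zeros(n_maps)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.pl = (kernel - 1) // 2

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        T = x.shape[3]
        k = self.kernel
        n = fft.next_fast_len(T + k - 1)
        self._T, self._N = T, n
        pr = k // 2
        self._X = fft.rfft(x, n=n, axis=3)
        Wrf = fft.rfft(self.W[:, ::-1], n=n, axis=1)
        y_full = fft.irfft(self._X * Wrf[None, :, None, :], n=n, axis=3)
        return y_full[..., pr:pr + T] + self.b[None, :, None, None]

    def backward(self, grad_out):
        n, T, k = self._N, self._T, self.kernel
        Gf = fft.rfft(grad_out, n=n, axis=3)
        c = fft.irfft((np.conj(Gf) * self._X).sum(axis=(0, 2)), n=n, axis=1)
        self.dW = c[:, (np.arange(k) - self.pl) % n]
        self.db = grad_out.sum(axis=(0, 2, 3))
        Wf = fft.rfft(self.W, n=n, axis=1)
        d_full = fft.irfft(Gf * Wf[None, :, None, :], n=n, axis=3)
        return d_full[..., self.pl:self.pl + T]


class SpatialDepthwiseConv(Layer):
    """Depthwise convolution spanning the full channel (electrode) axis.

    Each of the ``in_maps`` temporal feature maps gets ``depth_mult`` spatial
    filters of length ``n_channels``; the channel axis collapses to 1.
    """

    def __init__(self, in_maps: int, depth_mult: int, n_channels: int, rng: np.random.Generator):
        self.in_maps, self.depth_mult, self.n_channels = in_maps, depth_mult, n_channels
        self.W = _he_init(rng, (in_maps, depth_mult, n_channels), fan_in=n_channels)
        self.b = np.zeros(in_maps * depth_mult)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x = x
        out = np.einsum("bfct,fdc->bfdt", x, self.W, optimize=True)
        B, F, D, T = out.shape
        out = out.reshape(B, F * D, 1, T)
        return out + self.b[None, :, None, None]

    def backward(self, grad_out):
        B, FD, _, T = grad_out.shape
        g = grad_out.reshape(B, self.in_maps, self.depth_mult, T)
        self.dW = np.einsum("bfct,bfdt->fdc", self._x, g, optimize=True)
        self.db = grad_out.sum(axis=(0, 2, 3))
        return np.einsum("bfdt,fdc->bfct", g, self.W, optimize=True)


class PointwiseConv(Layer):
    """1x1 convolution mixing feature maps."""

    def __init__(self, in_maps: int, out_maps: int, rng: np.random.Generator):
        self.W = _he_init(rng, (out_maps, in_maps), fan_in=in_maps)
        self.b = np.zeros(out_maps)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x = x
        return np.einsum("bfct,of->boct", x, self.W, optimize=True) + self.b[None, :, None, None]

    def backward(self, grad_out):
        self.dW = np.einsum("bfct,boct->of", self._x, grad_out, optimize=True)
        self.db = grad_out.sum(axis=(0, 2, 3))
        return np.einsum("boct,of->bfct", grad_out, self.W, optimize=True)


class BatchNorm(Layer):
    """Per-feature-map batch normalisation over (batch, channel, time)."""

    def __init__(self, n_maps: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(n_maps)
        self.beta = np.zeros(n_maps)
        self.dgamma = np.zeros(n_maps)
        self.dbeta = np.zeros(n_maps)
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def grads(self):
        # running stats are state, not trained parameters
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training=False):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            # in-place so external references (checkpoints) stay valid
            self.running_mean *= m
            self.running_mean += (1 - m) * mean
            self.running_var *= m
            self.running_var += (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._training = training
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._invstd[None, :, None, None]
        self._n = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad_out):
        axes = (0, 2, 3)
        self.dgamma = (grad_out * self._xhat).sum(axis=axes)
        self.dbeta = grad_out.sum(axis=axes)
        g = grad_out * self.gamma[None, :, None, None]
        if not self._training:
            return g * self._invstd[None, :, None, None]
        n = self._n
        s1 = g.sum(axis=axes)[None, :, None, None]
        s2 = (g * self._xhat).sum(axis=axes)[None, :, None, None]
        return (self._invstd[None, :, None, None] / n) * (n * g - s1 - self._xhat * s2)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training=False):
        self._x = x
        return np.where(x > 0, x, self.alpha * np.expm1(x))

    def backward(self, grad_out):
        return grad_out * np.where(self._x > 0, 1.0, self.alpha * np.exp(self._x))


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class AvgPoolTime(Layer):
    """Non-overlapping average pooling along time; trailing remainder dropped."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x, training=False):
        B, F, C, T = x.shape
        self._T = T
        Tp = (T // self.pool) * self.pool
        self._Tp = Tp
        return x[..., :Tp].reshape(B, F, C, Tp // self.pool, self.pool).mean(axis=4)

    def backward(self, grad_out):
        B, F, C, To = grad_out.shape
        g = np.repeat(grad_out, self.pool, axis=3) / self.pool
        if self._Tp < self._T:
            g = np.pad(g, ((0, 0), (0, 0), (0, 0), (0, self._T - self._Tp)))
        return g


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Mean over channel and time axes -> (batch, maps)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out):
        B, F, C, T = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], self._shape) / (C * T)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad_out):
        self.dW = grad_out.T @ self._x
        self.db = grad_out.sum(axis=0)
        return grad_out @ self.W


def call_forward(layer: Layer, x: np.ndarray, training: bool) -> np.ndarray:
    """Run a layer forward, recording its output if the layer is flagged for capture."""
    out = layer.forward(x, training=training)
    if getattr(layer, "capture", False):
        layer.captured_output = out
    return out


def call_backward(layer: Layer, grad_out: np.ndarray) -> np.ndarray:
    """Run a layer backward, recording d(score)/d(output) if flagged for capture."""
    if getattr(layer, "capture", False):
        layer.captured_grad = grad_out
    return layer.backward(grad_out)


class ResidualBlock(Layer):
    """Identity-shortcut block: y = x + f(x), with shape-preserving inner layers."""

    def __init__(self, inner: list):
        self.inner = inner

    def cast(self, dtype):
        for layer in self.inner:
            layer.cast(dtype)

    def params(self):
        out = {}
        for i, layer in enumerate(self.inner):
            for k, v in layer.params().items():
                out[f"inner{i}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, layer in enumerate(self.inner):
            for k, v in layer.grads().items():
                out[f"inner{i}.{k}"] = v
        return out

    def forward(self, x, training=False):
        h = x
        for layer in self.inner:
            h = call_forward(layer, h, training)
        if h.shape != x.shape:
            raise ValueError("residual block inner layers must preserve shape")
        return h + x

    def backward(self, grad_out):
        g = grad_out
        for layer in reversed(self.inner):
            g = call_backward(layer, g)
        return g + grad_out
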