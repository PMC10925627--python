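"""Minimal CNN building blocks in numpy with full backpropagation.

Layers operate on (N, C, H, W) float64 arrays.  Convolutions are 3x3,
stride 1, zero-padded ("same"), implemented by im2col matmul; pooling is
2x2 max with stride 2.  Backward passes propagate gradients to both
parameters and the input, which is what makes input-gradient saliency maps
possible on top of the same code path.  Everything is deterministic given
the initialization seed (single-threaded numpy).
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from numpy.typing import NDArray


class Layer:
    """Base layer: parameters, gradients and a trainable flag."""

    trainable: bool = True

    def params(self) -> dict[str, NDArray]:
        return {}

    def grads(self) -> dict[str, NDArray]:
        return {}

    def forward(self, x: NDArray) -> NDArray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: NDArray) -> NDArray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 same-padding convolution, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, 3, 3))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: NDArray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: NDArray) -> NDArray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n, c, h, w, 3, 3)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        wmat = self.W.reshape(self.out_ch, c * 9).T
        out = cols @ wmat + self.b
        self._cols, self._shape = cols, (n, c, h, w)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: NDArray) -> NDArray:
        n, c, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dW[...] = (self._cols.T @ dflat).T.reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(self.out_ch, c * 9)).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1:-1, 1:-1]


class InputHighpass(Layer):
    """Fixed background-suppression front end.

    Subtracts a Gaussian blur (sigma in pixels) from each image and
    standardizes the result per image.  The smooth background of a brain
    slice is removed while lesion-scale structure survives, which makes the
    classification task learnable by a small network within a short epoch
    budget.  The layer has no parameters; its backward pass propagates the
    high-pass (mean/std treated as constants), so input-gradient saliency
    maps flow through it onto the raw image.
    """

    trainable = False

    def __init__(self, sigma: float):
        self.sigma = sigma

    def forward(self, x: NDArray) -> NDArray:
        from scipy import ndimage as ndi

        hp = x - ndi.gaussian_filter(x, (0, 0, self.sigma, self.sigma), mode="reflect")
        mu = hp.mean(axis=(1, 2, 3), keepdims=True)
        std = hp.std(axis=(1, 2, 3), keepdims=True)
        self._std = np.maximum(std, 1e-9)
        return (hp - mu) / self._std

    def backward(self, dout: NDArray) -> NDArray:
        from scipy import ndimage as ndi

        d = dout / self._std
        return d - ndi.gaussian_filter(d, (0, 0, self.sigma, self.sigma), mode="reflect")


class BatchNorm(Layer):
    """Per-channel batch normalization with learnable scale and shift.

    During training, batch statistics normalize the activations and running
    statistics accumulate for inference.  When the layer is frozen (its
    block is not being fine-tuned) it behaves as at inference even in
    training mode, so a frozen block's behaviour is bit-stable.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def extra_state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: NDArray) -> NDArray:
        if self.training and self.trainable:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mu[None, :, None, None]) / self._std
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: NDArray) -> NDArray:
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        if not (self.training and self.trainable):
            return dxhat / self._std
        return (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std


class ReLU(Layer):
    trainable = False

    def forward(self, x: NDArray) -> NDArray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: NDArray) -> NDArray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties split the gradient evenly."""

    trainable = False

    def forward(self, x: NDArray) -> NDArray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._counts = self._mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout: NDArray) -> NDArray:
        d = dout[:, :, :, None, :, None] * self._mask / self._counts
        n, c, h, w = self._shape
        return d.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Average over the spatial axes: (N, C, H, W) -> (N, C)."""

    trainable = False

    def forward(self, x: NDArray) -> NDArray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: NDArray) -> NDArray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    trainable = False

    def forward(self, x: NDArray) -> NDArray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: NDArray) -> NDArray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: NDArray) -> NDArray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: NDArray) -> NDArray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: NDArray) -> NDArray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: NDArray, labels: NDArray) -> tuple[float, NDArray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Sequential:
    """A stack of layers with forward/backward through the whole stack."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: NDArray) -> NDArray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: NDArray) -> NDArray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str, NDArray]]:
        return [
            (layer, name, arr)
            for layer in self.layers
            for name, arr in layer.params().items()
        ]

    def parameter_count(self, trainable_only: bool = False) -> int:
        return sum(
            arr.size
            for layer, _, arr in self.parameters()
            if not trainable_only or layer.trainable
        )

    def parameters_hash(self) -> str:
        h = hashlib.sha256()
        for _, _, arr in self.parameters():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def train_mode(self, flag: bool) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = flag

    def state(self) -> dict:
        params = [arr.copy() for _, _, arr in self.parameters()]
        extras = [
            {k: v.copy() for k, v in layer.extra_state().items()}
            for layer in self.layers
            if hasattr(layer, "extra_state")
        ]
        return {"params": params, "extras": extras}

    def load_state(self, state: dict) -> None:
        for (_, _, arr), saved in zip(self.parameters(), state["params"], strict=True):
            arr[...] = saved
        stateful = [l for l in self.layers if hasattr(l, "extra_state")]
        for layer, saved in zip(stateful, state["extras"], strict=True):
            for k, v in saved.items():
                getattr(layer, k)[...] = v


class SGD:
    """SGD with momentum; frozen layers are skipped entirely."""

    def __init__(self, model: Sequential, lr: float, momentum: float):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.velocity = {
            id(arr): np.zeros_like(arr) for _, _, arr in model.parameters()
        }

    def step(self) -> None:
        for layer, name, arr in self.model.parameters():
            if not layer.trainable:
                continue
            g = layer.grads()[name]
            v = self.velocity[id(arr)]
            v *= self.momentum
            v -= self.lr * g
            arr += v
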