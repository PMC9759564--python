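"""A compact numpy CNN engine: 3x3 same-padding convolutions, ReLU,
2x2/stride-2 max pooling, dense layers, softmax cross-entropy, and SGD
with momentum plus L2 regularization.

Everything is float32, batch-first channel-first (B, C, H, W), and
deterministic given a :class:`numpy.random.Generator`. Sized for
desk-scale images (tens of pixels a side), where im2col plus a BLAS
matmul is the fastest route.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense",
           "Network", "softmax", "SGDMomentum"]


def _im2col(xp: np.ndarray, h: int, w: int) -> np.ndarray:
    # xp: padded input (B, C, h+2, w+2) -> (B*h*w, C*9)
    b, c = xp.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (B, C, h, w, 3, 3) -> (B, h, w, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * h * w, c * 9)


class Conv2D:
    """3x3 convolution, padding 1 (spatial size preserved)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 9
        self.w = (rng.standard_normal((out_ch, in_ch, 3, 3))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._cache: tuple | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col(xp, h, w)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        self._cache = (cols, (bsz, c, h, w))
        return out.reshape(bsz, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray):
        cols, (bsz, c, h, w) = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.w.shape[0])
        self.dw = (dmat.T @ cols).reshape(self.w.shape)
        self.db = dmat.sum(axis=0)
        dcols = (dmat @ self.w.reshape(self.w.shape[0], -1)).reshape(
            bsz, h, w, c, 3, 3)
        dxp = np.zeros((bsz, c, h + 2, w + 2), dtype=dcols.dtype)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + w] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    @property
    def grads(self):
        return [self.dw, self.db]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    params: list = []
    grads: list = []

    def forward(self, x):
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, :h2 * 2, :w2 * 2].reshape(b, c, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (b, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((b, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = dxr.reshape(
            b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h2 * 2, w2 * 2)
        return dx


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    @property
    def grads(self):
        return [self.dw, self.db]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A feed-forward layer stack trained with softmax cross-entropy."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy over the batch; backpropagates in place."""
        logits = self.forward(x)
        probs = softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = [softmax(self.forward(x[i:i + batch]))
                for i in range(0, x.shape[0], batch)]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch).argmax(axis=1)


class SGDMomentum:
    """Classical momentum update with (uncoupled) L2 penalty."""

    def __init__(self, net: Network, lr: float, momentum: float, l2: float):
        self.net, self.lr, self.mu, self.l2 = net, lr, momentum, l2
        self._vel = [[np.zeros_like(p) for p in layer.params]
                     for layer in net.layers]

    def step(self) -> None:
        for layer, vels in zip(self.net.layers, self._vel):
            for p, g, v in zip(layer.params, layer.grads, vels):
                np.multiply(v, self.mu, out=v)
                v -= self.lr * (g + self.l2 * p)
                p += v
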