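"""Minimal numpy neural-network layers with explicit backpropagation.

The three networks in this package (interval scorer, shared-convolution
recognizer head, cycle classifier) are small 2-D CNNs over 8 x T or
6 x T "virtual images" with horizontal-only kernels and strides.  They
are implemented directly on numpy: layers store their parameters and
parameter gradients, ``forward`` caches what ``backward`` needs, and an
Adam optimizer updates parameters in place.  All randomness flows
through an explicit ``numpy.random.Generator``.

Array convention: activations are ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import numpy as np


class Conv2d:
    """2-D convolution, stride along width only, symmetric width padding.

    No height padding: kernels either preserve height (kh=1) or collapse
    it entirely (kh = input height).
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], stride_w: int = 1,
                 pad_w: int = 0, rng: np.random.Generator | None = None):
        kh, kw = kernel
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kh * kw
        # He initialization (ReLU activations follow every conv here)
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kh, kw))
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.stride_w = stride_w
        self.pad_w = pad_w
        self._x_pad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        oc, ic, kh, kw = self.W.shape
        if self.pad_w:
            x = np.pad(x, ((0, 0), (0, 0), (0, 0), (self.pad_w, self.pad_w)))
        self._x_pad = x
        B, C, H, Wp = x.shape
        h_out = H - kh + 1
        w_out = (Wp - kw) // self.stride_w + 1
        out = np.broadcast_to(self.b[None, :, None, None],
                              (B, oc, h_out, w_out)).copy()
        s = self.stride_w
        for di in range(kh):
            for dj in range(kw):
                sl = x[:, :, di:di + h_out, dj:dj + s * w_out:s]
                out += np.einsum("bchw,oc->bohw", sl, self.W[:, :, di, dj],
                                 optimize=True)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x_pad
        oc, ic, kh, kw = self.W.shape
        B, C, H, Wp = x.shape
        _, _, h_out, w_out = gout.shape
        s = self.stride_w
        gx = np.zeros_like(x)
        self.gb += gout.sum(axis=(0, 2, 3))
        for di in range(kh):
            for dj in range(kw):
                sl = x[:, :, di:di + h_out, dj:dj + s * w_out:s]
                self.gW[:, :, di, dj] += np.einsum(
                    "bohw,bchw->oc", gout, sl, optimize=True)
                gx[:, :, di:di + h_out, dj:dj + s * w_out:s] += np.einsum(
                    "bohw,oc->bchw", gout, self.W[:, :, di, dj], optimize=True)
        if self.pad_w:
            gx = gx[:, :, :, self.pad_w:-self.pad_w]
        return gx

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask

    def zero_grad(self) -> None:
        pass

    def parameters(self):
        return []


class Linear:
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ gout
        self.gb += gout.sum(axis=0)
        return gout @ self.W.T

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out


class ResidualBlock:
    """Two 1 x 3 convolutions with an additive identity shortcut."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, (1, 3), pad_w=1, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, (1, 3), pad_w=1, rng=rng)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + y)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gout)
        g_branch = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(g)))
        return g + g_branch

    def zero_grad(self) -> None:
        for layer in (self.conv1, self.conv2):
            layer.zero_grad()

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


# ---------------------------------------------------------------------------
# losses


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray,
                          weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean (optionally weighted) cross-entropy over rows.

    Returns the loss and its gradient with respect to ``logits``.
    ``weights`` re-weights rows; the normalizer is the number of rows
    (unweighted) or the weight sum.
    """
    p = softmax(logits, axis=-1)
    n = logits.shape[0]
    logp = np.log(np.clip(p, 1e-12, None))
    per_row = -(onehot * logp).sum(axis=-1)
    if weights is None:
        loss = float(per_row.mean())
        grad = (p - onehot) / n
    else:
        wsum = float(weights.sum())
        if wsum <= 0:
            return 0.0, np.zeros_like(logits)
        loss = float((weights * per_row).sum() / wsum)
        grad = (p - onehot) * weights[:, None] / wsum
    return loss, grad


def smooth_l1(x: np.ndarray | float) -> np.ndarray | float:
    """Huber-style loss: 0.5 x^2 inside (-1, 1), |x| - 0.5 outside."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1.0, 0.5 * x * x, np.abs(x) - 0.5)
    return out if out.ndim else float(out)


def smooth_l1_grad(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1.0, x, np.sign(x))
    return out if out.ndim else float(out)


class Adam:
    """Adam optimizer over ``(param, grad)`` pairs, updating in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
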