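"""Minimal convolutional-network core (NumPy, CPU).

Implements exactly the pieces the hybrid counting model needs — 2-D
convolution with "same" padding, stride 1 and arbitrary dilation rate,
ReLU, 2x2 stride-2 max pooling, channel concatenation, and the Adam
optimizer — with hand-written backward passes.  Feature maps are
``(H, W, C)`` float32 arrays; a convolution is evaluated as k*k shifted
slices of the padded input times the corresponding ``(Cin, Cout)`` weight
block, which keeps both directions as plain BLAS matmuls.

Keeping the network in NumPy makes gradients first-class values: the
receptive-field checks differentiate an output unit with respect to the
input image and inspect which pixels carry nonzero gradient.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv2D:
    """k x k convolution, stride 1, "same" padding, dilation rate r, + bias.

    Weights are drawn from N(0, init_std); init_std 0.01 matches the
    counting model's Gaussian initialization.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        init_std: float | str = 0.01,
    ) -> None:
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        if dilation < 1:
            raise ValueError("dilation rate must be >= 1")
        rng = rng or np.random.default_rng()
        self.k = kernel_size
        self.r = dilation
        if init_std == "he":  # variance-preserving: std = sqrt(2 / fan_in)
            std = float(np.sqrt(2.0 / (kernel_size * kernel_size * in_channels)))
        else:
            std = float(init_std)
        self.w = rng.normal(0.0, std, (kernel_size, kernel_size, in_channels, out_channels)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)

    @property
    def pad(self) -> int:
        return (self.k - 1) * self.r // 2

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (output, cache); cache is the padded input."""
        h, w, _ = x.shape
        p = self.pad
        xp = np.pad(x, ((p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (h, w, self.b.size)).astype(DTYPE).copy()
        for i in range(self.k):
            for j in range(self.k):
                sl = xp[i * self.r : i * self.r + h, j * self.r : j * self.r + w]
                out += sl @ self.w[i, j]
        return out, xp

    def backward(
        self, dout: np.ndarray, xp: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (dx, dw, db) for upstream gradient ``dout``."""
        h, w, _ = dout.shape
        p = self.pad
        dw = np.zeros_like(self.w)
        dxp = np.zeros_like(xp)
        flat_dout = dout.reshape(-1, dout.shape[2])
        for i in range(self.k):
            for j in range(self.k):
                sl = xp[i * self.r : i * self.r + h, j * self.r : j * self.r + w]
                dw[i, j] = sl.reshape(-1, sl.shape[2]).T @ flat_dout
                dxp[i * self.r : i * self.r + h, j * self.r : j * self.r + w] += (
                    dout @ self.w[i, j].T
                )
        db = dout.sum(axis=(0, 1))
        dx = dxp[p : p + h, p : p + w] if p else dxp
        return dx, dw, db

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 stride-2 max pooling; even spatial dims required."""
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("max pooling requires even spatial dimensions")
    blocks = x.reshape(h // 2, 2, w // 2, 2, c)
    flat = blocks.transpose(0, 2, 4, 1, 3).reshape(h // 2, w // 2, c, 4)
    arg = flat.argmax(axis=3)
    out = np.take_along_axis(flat, arg[..., None], axis=3)[..., 0]
    return out, arg


def maxpool2_backward(dout: np.ndarray, arg: np.ndarray) -> np.ndarray:
    hh, ww, c = dout.shape
    dflat = np.zeros((hh, ww, c, 4), dtype=dout.dtype)
    np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=3)
    return (
        dflat.reshape(hh, ww, c, 2, 2)
        .transpose(0, 3, 1, 4, 2)
        .reshape(hh * 2, ww * 2, c)
    )


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
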