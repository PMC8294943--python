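"""Minimal 3D convolutional network core.

Self-contained NumPy implementation of the few layer types the
autoencoder needs: 3x3x3 stride-1 zero-padded convolutions (optionally
fused with a rectified-linear activation), 2x2x2 stride-2 average
pooling with ceil-mode zero padding, nearest-neighbour unpooling, and
the Adam optimizer.  Convolutions are lowered to a single BLAS GEMM per
layer through an im2col transform; gradients are computed by the exact
adjoint of every forward step, so a forward/backward pair is a true
(sub)gradient of the loss.

Tensors use a channel-major ``(C, B, D, H, W)`` layout: with the GEMM
shaped ``(C_out, C_in*27) @ (C_in*27, B*V)`` the spatial/batch axis is
the long GEMM dimension, which is the orientation single-threaded BLAS
handles best.

Everything is float32 and deterministic given the weight seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "AvgPool3d",
    "Unpool3d",
    "Adam",
    "Sequential",
    "he_uniform",
]

_K = 3  # convolution kernel side; the architecture fixes 3x3x3 stride 1


def he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He (fan-in) uniform initialization, the usual choice for ReLU nets."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _pad1(x: np.ndarray) -> np.ndarray:
    """Zero-pad the three trailing (spatial) axes by one voxel each side."""
    C, B, D, H, W = x.shape
    xp = np.zeros((C, B, D + 2, H + 2, W + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1, 1:-1] = x
    return xp


def _im2col(xp: np.ndarray) -> np.ndarray:
    """Unfold a zero-padded (C, B, D+2, H+2, W+2) tensor into (C*27, B*V).

    Rows are ordered channel-major then kernel offset (i, j, k), matching
    the ``(C_out, C_in*27)`` weight layout.  Implemented as a zero-copy
    strided view whose reshape materializes in one pass.
    """
    C, B, Dp, Hp, Wp = xp.shape
    D, H, W = Dp - 2, Hp - 2, Wp - 2
    sC, sB, sD, sH, sW = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(C, _K, _K, _K, B, D, H, W),
        strides=(sC, sD, sH, sW, sB, sD, sH, sW),
    )
    return view.reshape(C * _K ** 3, B * D * H * W)


def _flip_weights(W: np.ndarray, cin: int, cout: int) -> np.ndarray:
    """Rearrange (C_out, C_in*27) weights into the transposed-convolution
    layout (C_in, C_out*27) with the kernel offsets reversed.

    For a stride-1, padding-1 convolution the input gradient is itself a
    stride-1, padding-1 convolution of the output gradient with these
    flipped weights, which keeps the whole backward pass on the GEMM
    fast path (no scatter-add).
    """
    w = W.reshape(cout, cin, _K ** 3)
    return w[:, :, ::-1].transpose(1, 0, 2).reshape(cin, cout * _K ** 3).copy()


class Conv3d:
    """3x3x3 stride-1 convolution with zero padding 1 (shape preserving).

    ``relu=True`` fuses a rectified-linear activation into the layer;
    the final reconstruction layer uses ``relu=False`` because the
    standardized targets are negative off the mean and a ReLU there
    would clip half the signal.
    """

    kind = "conv"

    def __init__(self, in_channels: int, out_channels: int, relu: bool = True,
                 rng: np.random.Generator | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.relu = relu
        fan_in = in_channels * _K ** 3
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = he_uniform(rng, fan_in, (out_channels, fan_in))
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._shape = None   # cached input shape for the backward pass
        self._cols = None    # cached im2col matrix (reused by backward)
        self._mask = None    # ReLU activation mask

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        C, B, D, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {C}")
        cols = _im2col(_pad1(x))
        out = self.W @ cols
        out += self.b[:, None]
        out = out.reshape(self.out_channels, B, D, H, W)
        if self.relu:
            mask = out > 0
            out *= mask
        else:
            mask = None
        if keep:
            self._shape, self._cols, self._mask = x.shape, cols, mask
        return out

    def backward(self, g: np.ndarray, need_input_grad: bool = True):
        C, B, D, H, W = self._shape
        if self.relu:
            g = g * self._mask
        gflat = g.reshape(self.out_channels, -1)
        cols = self._cols
        self.gW = gflat @ cols.T
        self.gb = gflat.sum(axis=1)
        self._cols = None  # release
        if not need_input_grad:
            return None
        gcols = _im2col(_pad1(g.reshape(self.out_channels, B, D, H, W)))
        wf = _flip_weights(self.W, self.in_channels, self.out_channels)
        return (wf @ gcols).reshape(C, B, D, H, W)

    def parameters(self):
        return [("W", self), ("b", self)]


class AvgPool3d:
    """2x2x2 stride-2 average pooling, ceil mode.

    Odd spatial extents are implicitly zero padded to even before
    pooling and the divisor stays 8 (zeros count), so the operation is
    linear and its adjoint is an exact /8 broadcast.
    """

    kind = "pool"

    def __init__(self):
        self._in_dims = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        C, B, D, H, W = x.shape
        if keep:
            self._in_dims = (D, H, W)
        pd, ph, pw = D % 2, H % 2, W % 2
        if pd or ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)))
        D2, H2, W2 = (D + pd) // 2, (H + ph) // 2, (W + pw) // 2
        return (
            x.reshape(C, B, D2, 2, H2, 2, W2, 2)
            .mean(axis=(3, 5, 7), dtype=np.float32)
        )

    def backward(self, g: np.ndarray, need_input_grad: bool = True):
        D, H, W = self._in_dims
        g = g.astype(np.float32, copy=False) / 8.0
        up = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4)
        return up[:, :, :D, :H, :W]

    def parameters(self):
        return []


class Unpool3d:
    """Nearest-neighbour x2 upsampling: each value fills its 2x2x2 cell.

    Average pooling keeps no argmax switches, so value replication is
    the natural (adjoint-consistent) unpooling.
    """

    kind = "unpool"

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), 2, axis=4)

    def backward(self, g: np.ndarray, need_input_grad: bool = True):
        C, B, D, H, W = g.shape
        return g.reshape(C, B, D // 2, 2, H // 2, 2, W // 2, 2).sum(
            axis=(3, 5, 7), dtype=np.float32
        )

    def parameters(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, keep=keep)
        return x

    def backward(self, g: np.ndarray, need_input_grad: bool = True):
        for i in range(len(self.layers) - 1, -1, -1):
            need = need_input_grad or i > 0
            g = self.layers[i].backward(g, need_input_grad=need)
        return g

    def conv_layers(self):
        return [l for l in self.layers if isinstance(l, Conv3d)]


class Adam:
    """Adam with the conventional bias-corrected moment estimates."""

    def __init__(self, convs, alpha: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.convs = list(convs)
        self.alpha, self.beta1, self.beta2, self.eps = alpha, beta1, beta2, eps
        self.t = 0
        self._m = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in self.convs]
        self._v = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in self.convs]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for c, (mW, mb), (vW, vb) in zip(self.convs, self._m, self._v):
            for p, g, m, v in ((c.W, c.gW, mW, vW), (c.b, c.gb, mb, vb)):
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * np.square(g)
                p -= self.alpha * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
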