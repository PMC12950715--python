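"""TinyWeedNet computation graph: layers, blocks, forward and backprop.

The network is a compact image classifier built exclusively from operators
that embedded inference runtimes support natively: standard / pointwise /
depthwise convolutions, batch normalization, ReLU, sigmoid, max and global
pooling, concatenation, element-wise add/multiply and a fully connected
layer.  Topology::

    stem (3x3 s2) -> MSC (1x1 | 3x3 | 5x5 | pool+1x1, concat)
        -> 5x inverted-residual blocks with channel attention
        -> 1x1 projection -> GAP -> dropout -> FC logits

Everything runs in float32 numpy.  Each layer implements ``forward`` and
``backward`` explicitly; there is no autograd.  Convolutions use an
im2col/col2im formulation so the heavy lifting is a single BLAS matmul.

Weight conventions (frozen by calibrating the closed-form parameter count of
:mod:`tinyweednet.complexity` against the reference totals):

* standard and pointwise convolutions carry a bias term;
* depthwise convolutions are bias-free;
* every convolution is followed by affine batch normalization (except inside
  the channel-attention excite layer, which feeds the sigmoid directly);
* the channel-attention squeeze is Conv1x1 + BN + ReLU with a hidden width of
  ``max(1, C // R)`` shared between the average- and max-pooled descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import ArchConfig

__all__ = [
    "TensorSpec",
    "LayerSpec",
    "TinyWeedNet",
    "assemble_network",
    "infer_shapes",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1
MIN_INPUT_SIDE = 32


@dataclass(frozen=True)
class TensorSpec:
    """(channels, height, width) contract for an activation tensor.

    Pooled vectors are represented with ``height == width == 1``.
    """

    channels: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if min(self.channels, self.height, self.width) < 1:
            raise ValueError(f"invalid tensor spec {self}")


@dataclass(frozen=True)
class LayerSpec:
    """Typed description of a single primitive layer."""

    kind: str
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    in_channels: int = 0
    out_channels: int = 0
    has_bias: bool = False


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------


def _conv_windows(x: np.ndarray, k: int, stride: int, pad: int, fill: float = 0.0):
    """Padded sliding windows of shape (N, C, Ho, Wo, k, k)."""
    if pad:
        x = np.pad(
            x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=fill
        )
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride], x.shape


def _col2im(gwin: np.ndarray, padded_shape, k: int, stride: int, pad: int):
    """Scatter window gradients (N, C, Ho, Wo, k, k) back to the input."""
    n, c, hp, wp = padded_shape
    ho, wo = gwin.shape[2], gwin.shape[3]
    gx = np.zeros((n, c, hp, wp), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gwin[
                :, :, :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d:
    """Standard convolution, bias enabled by default."""

    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, rng=None):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        std = np.sqrt(2.0 / (k * k * cout))  # Kaiming fan-out
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def forward(self, x, train=False):
        win, pshape = _conv_windows(x, self.k, self.stride, self.pad)
        n, _, ho, wo = win.shape[0], win.shape[1], win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        wmat = self.W.data.reshape(self.cout, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.data
        out = out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        self._cache = (cols, pshape, (n, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, gy):
        cols, pshape, (n, ho, wo) = self._cache
        g = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        wmat = self.W.data.reshape(self.cout, -1)
        self.W.grad += (g.T @ cols).reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        gcols = g @ wmat
        gwin = gcols.reshape(n, ho, wo, self.cin, self.k, self.k).transpose(
            0, 3, 1, 2, 4, 5
        )
        return _col2im(gwin, pshape, self.k, self.stride, self.pad)

    def params(self):
        return [("W", self.W)] + ([("b", self.b)] if self.b is not None else [])

    def spec(self):
        return LayerSpec(
            "conv", self.k, self.stride, self.pad, self.cin, self.cout,
            self.b is not None,
        )


class DepthwiseConv2d:
    """Per-channel 3x3 convolution (groups == channels), bias-free.

    Computed as k*k shifted multiply-adds, which is much faster in numpy than
    an im2col formulation for single-channel kernels.
    """

    def __init__(self, channels, k=3, stride=1, pad=1, rng=None):
        self.c, self.k, self.stride, self.pad = channels, k, stride, pad
        std = np.sqrt(2.0 / (k * k))
        self.W = Param(rng.normal(0.0, std, size=(channels, k, k)))
        self._cache = None

    def _out_side(self, side):
        return (side + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=False):
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho, wo = self._out_side(x.shape[2]), self._out_side(x.shape[3])
        out = np.zeros((x.shape[0], self.c, ho, wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += self.W.data[None, :, i, j, None, None] * xp[
                    :, :, i : i + s * ho : s, j : j + s * wo : s
                ]
        self._cache = (xp, x.shape, (ho, wo))
        return out

    def backward(self, gy):
        xp, xshape, (ho, wo) = self._cache
        p, s, k = self.pad, self.stride, self.k
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, :, i : i + s * ho : s, j : j + s * wo : s]
                self.W.grad[:, i, j] += (gy * xp[sl]).sum(axis=(0, 2, 3))
                gxp[sl] += gy * self.W.data[None, :, i, j, None, None]
        return gxp[:, :, p:-p, p:-p] if p else gxp

    def params(self):
        return [("W", self.W)]

    def spec(self):
        return LayerSpec(
            "depthwise_conv", self.k, self.stride, self.pad, self.c, self.c, False
        )


class BatchNorm2d:
    """Affine batch normalization over (N, H, W) per channel."""

    def __init__(self, channels):
        self.c = channels
        self.momentum = BN_MOMENTUM
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = xhat * self.gamma.data[None, :, None, None] + self.beta.data[
            None, :, None, None
        ]
        self._cache = (xhat, inv, x.shape, train)
        return out.astype(np.float32, copy=False)

    def backward(self, gy):
        xhat, inv, shape, train = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.data[None, :, None, None]
        if not train:
            # running statistics are constants: plain rescale
            return (g * inv[None, :, None, None]).astype(np.float32, copy=False)
        n_eff = shape[0] * shape[2] * shape[3]
        gsum = g.sum(axis=axes, keepdims=True)
        gxhat_sum = (g * xhat).sum(axis=axes, keepdims=True)
        gx = (g - gsum / n_eff - xhat * gxhat_sum / n_eff) * inv[None, :, None, None]
        return gx.astype(np.float32, copy=False)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def spec(self):
        return LayerSpec("batch_norm", in_channels=self.c, out_channels=self.c)


class ReLU:
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask

    def params(self):
        return []

    def spec(self):
        return LayerSpec("relu")


class Sigmoid:
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)

    def params(self):
        return []

    def spec(self):
        return LayerSpec("sigmoid")


class MaxPool2d:
    """k x k max pooling; ties share the gradient equally."""

    def __init__(self, k=3, stride=1, pad=1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        p, s, k = self.pad, self.stride, self.k
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        ho = (x.shape[2] + 2 * p - k) // s + 1
        wo = (x.shape[3] + 2 * p - k) // s + 1
        out = None
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                out = sl.copy() if out is None else np.maximum(out, sl)
        self._cache = (xp, out, (ho, wo))
        return out

    def backward(self, gy):
        xp, out, (ho, wo) = self._cache
        p, s, k = self.pad, self.stride, self.k
        count = np.zeros_like(out)
        for i in range(k):
            for j in range(k):
                count += xp[:, :, i : i + s * ho : s, j : j + s * wo : s] == out
        share = gy / count
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, :, i : i + s * ho : s, j : j + s * wo : s]
                gxp[sl] += share * (xp[sl] == out)
        gx = gxp[:, :, p:-p, p:-p] if p else gxp
        return np.nan_to_num(gx, copy=False)

    def params(self):
        return []

    def spec(self):
        return LayerSpec("max_pool", self.k, self.stride, self.pad)


class GlobalAvgPool:
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        n, c, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (h * w)

    def params(self):
        return []

    def spec(self):
        return LayerSpec("global_avg_pool")


class GlobalMaxPool:
    """(N, C, H, W) -> (N, C); ties share the gradient equally."""

    def forward(self, x, train=False):
        self._x = x
        self._out = x.max(axis=(2, 3))
        return self._out

    def backward(self, gy):
        mask = (self._x == self._out[:, :, None, None]).astype(np.float32)
        mask /= mask.sum(axis=(2, 3), keepdims=True)
        return gy[:, :, None, None] * mask

    def params(self):
        return []

    def spec(self):
        return LayerSpec("global_max_pool")


class Dropout:
    """Inverted dropout on vectors; identity in evaluation mode."""

    def __init__(self, p, rng):
        self.p = p
        self._rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask

    def params(self):
        return []

    def spec(self):
        return LayerSpec("dropout")


class Linear:
    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / cin)
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.b = Param(np.zeros(cout))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, gy):
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.data

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def spec(self):
        return LayerSpec(
            "fully_connected", in_channels=self.cin, out_channels=self.cout,
            has_bias=True,
        )


# ---------------------------------------------------------------------------
# composite blocks
# ---------------------------------------------------------------------------


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                out.append((f"{i}.{name}", p))
        return out

    def specs(self):
        return [layer.spec() for layer in self.layers]


def _conv_bn_relu(cin, cout, k, stride, pad, rng):
    return _Sequential(
        [Conv2d(cin, cout, k, stride, pad, bias=True, rng=rng),
         BatchNorm2d(cout), ReLU()]
    )


class StemBlock:
    """3x3 stride-2 convolution + BN + ReLU; halves the spatial size."""

    name = "stem"

    def __init__(self, cout, rng):
        self.seq = _conv_bn_relu(3, cout, 3, 2, 1, rng)

    forward = property(lambda self: self.seq.forward)
    backward = property(lambda self: self.seq.backward)
    params = property(lambda self: self.seq.params)
    specs = property(lambda self: self.seq.specs)


class MSCBlock:
    """Multi-scale convolution: four parallel stride-1 branches, concatenated.

    Branches: 1x1 / 3x3 / 5x5 convolutions and 3x3 max-pool + 1x1 projection,
    each Conv + BN + ReLU.  The ``no_msc`` ablation replaces the whole block
    with a single 3x3 branch of the full output width.
    """

    name = "msc"

    def __init__(self, cin, schedule, rng, single_branch=False):
        self.single_branch = single_branch
        if single_branch:
            self.branches = [_conv_bn_relu(cin, schedule.msc_out, 3, 1, 1, rng)]
        else:
            w1, w3, w5, wp = schedule.msc_branch_widths
            self.branches = [
                _conv_bn_relu(cin, w1, 1, 1, 0, rng),
                _conv_bn_relu(cin, w3, 3, 1, 1, rng),
                _conv_bn_relu(cin, w5, 5, 1, 2, rng),
                _Sequential(
                    [MaxPool2d(3, 1, 1)] + _conv_bn_relu(cin, wp, 1, 1, 0, rng).layers
                ),
            ]
        self._widths = None

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return outs[0] if self.single_branch else np.concatenate(outs, axis=1)

    def backward(self, gy):
        if self.single_branch:
            return self.branches[0].backward(gy)
        gx = None
        start = 0
        for b, w in zip(self.branches, self._widths):
            g = b.backward(gy[:, start : start + w])
            gx = g if gx is None else gx + g
            start += w
        return gx

    def params(self):
        out = []
        for i, b in enumerate(self.branches):
            for name, p in b.params():
                out.append((f"branch{i}.{name}", p))
        return out

    def specs(self):
        specs = []
        for b in self.branches:
            specs.extend(b.specs())
        if not self.single_branch:
            specs.append(LayerSpec("concat"))
        return specs


class ChannelAttention:
    """Channel gate from global average- and max-pooled descriptors.

    Both descriptors pass through a *shared* bottleneck
    (Conv1x1 -> BN -> ReLU -> Conv1x1); the two outputs are summed and
    squashed by a sigmoid, and the input is re-weighted channel-wise.  The
    two pooled vectors are stacked along the batch axis so the shared layers
    (including BN statistics) see both paths in one pass.
    """

    name = "ca"

    def __init__(self, channels, reduction_ratio, rng):
        self.c = channels
        self.reduced = max(1, channels // reduction_ratio)
        self.gap = GlobalAvgPool()
        self.gmp = GlobalMaxPool()
        self.fc1 = Conv2d(channels, self.reduced, 1, bias=True, rng=rng)
        self.bn = BatchNorm2d(self.reduced)
        self.relu = ReLU()
        self.fc2 = Conv2d(self.reduced, channels, 1, bias=True, rng=rng)
        self.sigmoid = Sigmoid()

    def forward(self, x, train=False):
        n = x.shape[0]
        q_avg = self.gap.forward(x, train)
        q_max = self.gmp.forward(x, train)
        q = np.concatenate([q_avg, q_max], axis=0)[:, :, None, None]
        z = self.fc1.forward(q, train)
        z = self.bn.forward(z, train)
        z = self.relu.forward(z, train)
        z = self.fc2.forward(z, train)
        gate = self.sigmoid.forward(z[:n] + z[n:], train)[:, :, 0, 0]
        self._x, self._gate = x, gate
        return x * gate[:, :, None, None]

    def backward(self, gy):
        x, gate = self._x, self._gate
        gx = gy * gate[:, :, None, None]
        ggate = (gy * x).sum(axis=(2, 3))
        gz_sum = self.sigmoid.backward(ggate[:, :, None, None])
        gz = np.concatenate([gz_sum, gz_sum], axis=0)
        gq = self.fc1.backward(self.bn.backward(self.relu.backward(
            self.fc2.backward(gz))))[:, :, 0, 0]
        n = x.shape[0]
        gx += self.gap.backward(gq[:n])
        gx += self.gmp.backward(gq[n:])
        return gx

    def params(self):
        out = []
        for prefix, layer in (("fc1", self.fc1), ("bn", self.bn), ("fc2", self.fc2)):
            for name, p in layer.params():
                out.append((f"{prefix}.{name}", p))
        return out

    def specs(self):
        return [
            LayerSpec("global_avg_pool"),
            LayerSpec("global_max_pool"),
            self.fc1.spec(),
            self.bn.spec(),
            LayerSpec("relu"),
            self.fc2.spec(),
            LayerSpec("sigmoid"),
            LayerSpec("channel_scale", in_channels=self.c, out_channels=self.c),
        ]


class IRBlock:
    """Inverted residual: expand (1x1) -> depthwise (3x3) -> attention ->
    project (1x1, linear bottleneck).  A residual add is used when the stride
    is 1 and the widths match."""

    def __init__(self, cin, cout, stride, config: ArchConfig, rng, index):
        self.name = f"ir{index}"
        self.cin, self.cout, self.stride = cin, cout, stride
        e = config.expand_ratio * cin
        self.expanded = e
        self.expand = _conv_bn_relu(cin, e, 1, 1, 0, rng)
        if config.ablation == "no_depthwise":
            self.dw = _Sequential(
                [Conv2d(e, e, 3, stride, 1, bias=True, rng=rng),
                 BatchNorm2d(e), ReLU()]
            )
        else:
            self.dw = _Sequential(
                [DepthwiseConv2d(e, 3, stride, 1, rng=rng), BatchNorm2d(e), ReLU()]
            )
        self.ca = (
            None
            if config.ablation == "no_attention"
            else ChannelAttention(e, config.reduction_ratio, rng)
        )
        # linear bottleneck: no activation after the projection BN
        self.project = _Sequential(
            [Conv2d(e, cout, 1, bias=True, rng=rng), BatchNorm2d(cout)]
        )
        self.residual = stride == 1 and cin == cout

    def forward(self, x, train=False):
        y = self.expand.forward(x, train)
        y = self.dw.forward(y, train)
        if self.ca is not None:
            y = self.ca.forward(y, train)
        y = self.project.forward(y, train)
        return x + y if self.residual else y

    def backward(self, gy):
        g = self.project.backward(gy)
        if self.ca is not None:
            g = self.ca.backward(g)
        g = self.dw.backward(g)
        g = self.expand.backward(g)
        return g + gy if self.residual else g

    def params(self):
        out = []
        groups = [("expand", self.expand), ("dw", self.dw)]
        if self.ca is not None:
            groups.append(("ca", self.ca))
        groups.append(("project", self.project))
        for prefix, blk in groups:
            for name, p in blk.params():
                out.append((f"{prefix}.{name}", p))
        return out

    def specs(self):
        specs = self.expand.specs() + self.dw.specs()
        if self.ca is not None:
            specs += self.ca.specs()
        specs += self.project.specs()
        if self.residual:
            specs.append(LayerSpec("add"))
        return specs


class Head:
    """Optional 1x1 projection + BN + ReLU, then GAP -> dropout -> FC."""

    name = "head"

    def __init__(self, cin, config: ArchConfig, rng):
        self.project = (
            None
            if config.ablation == "no_final_projection"
            else _conv_bn_relu(cin, config.head_channels, 1, 1, 0, rng)
        )
        fc_in = cin if self.project is None else config.head_channels
        self.fc_in = fc_in
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(config.dropout_p, rng)
        self.fc = Linear(fc_in, config.num_classes, rng)

    def forward(self, x, train=False):
        if self.project is not None:
            x = self.project.forward(x, train)
        p = self.gap.forward(x, train)
        p = self.dropout.forward(p, train)
        return self.fc.forward(p, train)

    def backward(self, gy):
        g = self.fc.backward(gy)
        g = self.dropout.backward(g)
        g = self.gap.backward(g)
        if self.project is not None:
            g = self.project.backward(g)
        return g

    def params(self):
        out = []
        if self.project is not None:
            for name, p in self.project.params():
                out.append((f"project.{name}", p))
        for name, p in self.fc.params():
            out.append((f"fc.{name}", p))
        return out

    def specs(self):
        specs = [] if self.project is None else self.project.specs()
        return specs + [
            LayerSpec("global_avg_pool"),
            LayerSpec("dropout"),
            self.fc.spec(),
        ]


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class TinyWeedNet:
    """A fully assembled network variant with seeded, deterministic weights."""

    def __init__(self, config: ArchConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        sched = config.schedule
        self.stem = StemBlock(sched.stem_out, rng)
        self.msc = MSCBlock(
            sched.stem_out, sched, rng, single_branch=config.ablation == "no_msc"
        )
        self.ir_blocks = []
        cin = sched.msc_out
        for i, (cout, stride) in enumerate(zip(sched.ir_out, sched.ir_strides), 1):
            self.ir_blocks.append(IRBlock(cin, cout, stride, config, rng, i))
            cin = cout
        self.head = Head(cin, config, rng)
        self.blocks = [self.stem, self.msc, *self.ir_blocks, self.head]

    # -- inference / training -------------------------------------------------

    def _check_input(self, x):
        side = self.config.input_side
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != side or x.shape[3] != side:
            raise ValueError(
                f"expected batch of shape (N, 3, {side}, {side}), got {x.shape}"
            )

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N, num_classes)."""
        self._check_input(batch)
        x = np.ascontiguousarray(batch, dtype=np.float32)
        for block in self.blocks:
            x = block.forward(x, train)
        return x

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        """Backpropagate after a train-mode forward pass."""
        g = np.ascontiguousarray(grad_logits, dtype=np.float32)
        for block in reversed(self.blocks):
            g = block.backward(g)
        return g

    __call__ = forward

    # -- introspection --------------------------------------------------------

    def parameters(self) -> list[tuple[str, Param]]:
        out = []
        for block in self.blocks:
            for name, p in block.params():
                out.append((f"{block.name}.{name}", p))
        return out

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad[:] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for _, p in self.parameters())

    def layer_specs(self) -> list[tuple[str, LayerSpec]]:
        """Every primitive layer, tagged with its stage name, in order."""
        out = []
        for block in self.blocks:
            for spec in block.specs():
                out.append((block.name, spec))
        return out

    def stage_widths(self) -> list[tuple[str, int]]:
        sched = self.config.schedule
        widths = [("stem", sched.stem_out), ("msc", sched.msc_out)]
        widths += [(f"ir{i + 1}", c) for i, c in enumerate(sched.ir_out)]
        if self.head.project is not None:
            widths.append(("head_conv", self.config.head_channels))
        widths.append(("gap", self.head.fc_in))
        widths.append(("fc", self.config.num_classes))
        return widths

    def state(self) -> dict:
        """Named weight arrays plus BN running statistics (for checkpoints)."""
        d = {name: p.data.copy() for name, p in self.parameters()}
        for name, bn in self._bn_layers():
            d[f"{name}.running_mean"] = bn.running_mean.copy()
            d[f"{name}.running_var"] = bn.running_var.copy()
        return d

    def load_state(self, d: dict) -> None:
        for name, p in self.parameters():
            p.data[:] = d[name]
        for name, bn in self._bn_layers():
            bn.running_mean[:] = d[f"{name}.running_mean"]
            bn.running_var[:] = d[f"{name}.running_var"]

    def _bn_layers(self):
        seen = []

        def walk(prefix, obj):
            if isinstance(obj, BatchNorm2d):
                seen.append((prefix, obj))
            elif isinstance(obj, _Sequential):
                for i, sub in enumerate(obj.layers):
                    walk(f"{prefix}.{i}", sub)
            elif isinstance(obj, MSCBlock):
                for i, b in enumerate(obj.branches):
                    walk(f"{prefix}.branch{i}", b)
            elif isinstance(obj, ChannelAttention):
                walk(f"{prefix}.bn", obj.bn)
            elif isinstance(obj, IRBlock):
                walk(f"{prefix}.expand", obj.expand)
                walk(f"{prefix}.dw", obj.dw)
                if obj.ca is not None:
                    walk(f"{prefix}.ca", obj.ca)
                walk(f"{prefix}.project", obj.project)
            elif isinstance(obj, StemBlock):
                walk(prefix, obj.seq)
            elif isinstance(obj, Head):
                if obj.project is not None:
                    walk(f"{prefix}.project", obj.project)

        for block in [self.stem, self.msc, *self.ir_blocks, self.head]:
            walk(block.name, block)
        return seen


def assemble_network(config: ArchConfig, seed: int = 0) -> TinyWeedNet:
    """Build a network variant with deterministically initialized weights."""
    return TinyWeedNet(config, seed)


def infer_shapes(
    network: TinyWeedNet | ArchConfig, input_spec: TensorSpec | None = None
) -> list[tuple[str, TensorSpec]]:
    """Activation shape after each named stage, by stride arithmetic.

    Returns ``(stage_name, TensorSpec)`` pairs for stem, MSC, the five IR
    stages, the head projection (when present), GAP and FC; pooled vectors
    use a 1x1 spatial footprint.
    """
    config = network.config if isinstance(network, TinyWeedNet) else network
    if input_spec is None:
        input_spec = TensorSpec(3, config.input_side, config.input_side)
    if input_spec.channels != 3:
        raise ValueError(f"input must have 3 channels, got {input_spec.channels}")
    if input_spec.height != input_spec.width:
        raise ValueError("input must be square")
    if input_spec.height < MIN_INPUT_SIDE:
        raise ValueError(
            f"input side must be >= {MIN_INPUT_SIDE}, got {input_spec.height}"
        )

    sched = config.schedule
    half = lambda v: (v + 1) // 2  # 3x3, stride 2, pad 1
    h = half(input_spec.height)
    shapes = [("stem", TensorSpec(sched.stem_out, h, h))]
    shapes.append(("msc", TensorSpec(sched.msc_out, h, h)))
    for i, (cout, stride) in enumerate(zip(sched.ir_out, sched.ir_strides), 1):
        if stride == 2:
            h = half(h)
        shapes.append((f"ir{i}", TensorSpec(cout, h, h)))
    if config.ablation != "no_final_projection":
        shapes.append(("head_conv", TensorSpec(sched.head_out, h, h)))
        fc_in = sched.head_out
    else:
        fc_in = sched.ir_out[-1]
    shapes.append(("gap", TensorSpec(fc_in, 1, 1)))
    shapes.append(("fc", TensorSpec(config.num_classes, 1, 1)))
    return shapes
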