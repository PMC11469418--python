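"""Layers, U-shaped encoder-decoder networks and the Adam optimizer.

The same code builds 2D (slice-wise segmentation) and 3D (patch
inpainting) networks; the spatial dimensionality is a constructor
argument.  Initialization follows the pix2pix convention of zero-mean
Gaussian weights with 0.02 standard deviation, drawn from a seeded
generator so models are reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv_nd, upsample_nearest


class Module:
    """Minimal parameter container."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state does not match the architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state does not match the architecture")
            p.data = np.asarray(a, dtype=np.float32)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv(Module):
    """Convolution with optional instance normalization and nonlinearity."""

    def __init__(self, nd, c_in, c_out, rng, kernel=3, stride=1,
                 norm=True, act="lrelu"):
        k = (kernel,) * nd
        self.w = Tensor(
            rng.normal(0.0, 0.02, size=(c_out, c_in) + k), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.act = act
        self.norm = InstanceNorm(c_out) if norm else None

    def __call__(self, x: Tensor) -> Tensor:
        y = conv_nd(x, self.w, self.b, stride=self.stride)
        if self.norm is not None:
            y = self.norm(y)
        if self.act == "lrelu":
            y = y.leaky_relu(0.2)
        elif self.act == "relu":
            y = y.relu()
        elif self.act == "tanh":
            y = y.tanh()
        return y


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        nd = x.data.ndim - 2
        axes = tuple(range(2, 2 + nd))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        shape = (1, -1) + (1,) * nd
        g = Tensor(self.gamma.data.reshape(shape), requires_grad=True, parents=(self.gamma,))
        g._backward = lambda gr: self.gamma._accum(gr.reshape(self.gamma.data.shape))
        b = Tensor(self.beta.data.reshape(shape), requires_grad=True, parents=(self.beta,))
        b._backward = lambda gr: self.beta._accum(gr.reshape(self.beta.data.shape))
        return xc * inv * g + b


class UNet(Module):
    """U-shaped encoder-decoder with skip connections.

    ``depth`` strided-conv encoder stages halve the spatial size and
    double the channel width; the decoder mirrors them with nearest
    upsampling + convolution and concatenated skips.  The head is linear
    (segmentation logits) or tanh (image synthesis in [-1, 1]).
    """

    def __init__(self, nd, c_in, c_out, base_channels, depth, rng,
                 head: str = "linear", max_width: int | None = None):
        self.nd = nd
        self.depth = depth
        widths = [base_channels * (2**i) for i in range(depth + 1)]
        if max_width is not None:
            widths = [min(w, max_width) for w in widths]
        self.stem = Conv(nd, c_in, widths[0], rng)
        self.down = [
            Conv(nd, widths[i], widths[i + 1], rng, stride=2) for i in range(depth)
        ]
        self.bottleneck = Conv(nd, widths[depth], widths[depth], rng)
        self.up = []
        self.fuse = []
        for i in reversed(range(depth)):
            self.up.append(Conv(nd, widths[i + 1], widths[i], rng))
            self.fuse.append(Conv(nd, 2 * widths[i], widths[i], rng))
        act = {"linear": "none", "tanh": "tanh"}[head]
        self.head = Conv(nd, widths[0], c_out, rng, kernel=1, norm=False, act=act)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        h = self.stem(x)
        for d in self.down:
            skips.append(h)
            h = d(h)
        h = self.bottleneck(h)
        for up, fuse, skip in zip(self.up, self.fuse, reversed(skips)):
            h = up(upsample_nearest(h, 2))
            h = fuse(concat([h, skip], axis=1))
        return self.head(h)


class PatchDiscriminator(Module):
    """Strided conv stack scoring overlapping patches as real/fake."""

    def __init__(self, nd, c_in, base_channels, rng, levels: int = 3):
        chans = [c_in] + [base_channels * (2**i) for i in range(levels)]
        self.blocks = [
            Conv(nd, chans[i], chans[i + 1], rng, stride=2, norm=(i > 0))
            for i in range(levels)
        ]
        self.head = Conv(nd, chans[-1], 1, rng, kernel=3, norm=False, act="none")

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.blocks:
            h = blk(h)
        return self.head(h)


class Adam:
    """Adam optimizer (pix2pix defaults: lr 2e-4, beta1 0.5)."""

    def __init__(self, params: list[Tensor], lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
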