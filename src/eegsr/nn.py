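"""Layers, optimizers, and the generator/critic architectures.

Everything operates on tensors shaped (batch, feature_maps, channels, time):
EEG patches enter as a single feature map over the channel x time plane and
convolutions use 3x3 kernels on that plane.  Stride-2 layers reduce the time
axis only, and the generator doubles the time axis with a fractional-stride
(transposed) convolution, so a trained generator applies to any channel count
and any patch length at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "GeneratorSpec",
    "CriticSpec",
    "Generator",
    "Critic",
    "build_generator",
    "build_critic",
    "save_generator",
    "load_generator",
    "Adam",
    "RMSprop",
    "CUBIC_KERNEL",
]

# Catmull-Rom cubic interpolation taps for factor-2 upsampling: applied to the
# zero-stuffed sequence they reproduce the samples and fill midpoints with
# (-1/16, 9/16, 9/16, -1/16) neighbour weights.
CUBIC_KERNEL = np.array([-1 / 16, 0.0, 9 / 16, 1.0, 9 / 16, 0.0, -1 / 16])


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus running statistics, in a stable order."""
        out = [p.data for p in self.parameters()]
        for m in self._submodules():
            if isinstance(m, BatchNorm):
                out.extend([m.running_mean, m.running_var])
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v._submodules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item._submodules()


class Conv2d(Module):
    """3x3 (or kxk) convolution over the (channel, time) plane.

    stride acts on the time axis only; padding keeps 'same' geometry for
    stride 1.
    """

    def __init__(self, in_maps, out_maps, kernel=3, time_stride=1, rng=None, gain=1.0):
        k = kernel
        fan_in = in_maps * k * k
        std = gain * np.sqrt(2.0 / fan_in)
        rng = rng or np.random.default_rng()
        if std > 0:
            w0 = rng.normal(0.0, std, size=(out_maps, in_maps, k, k))
        else:
            w0 = np.zeros((out_maps, in_maps, k, k))
        self.w = Parameter(w0)
        self.b = Parameter(np.zeros(out_maps))
        self.kernel = k
        self.time_stride = time_stride

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        k, st = self.kernel, self.time_stride
        p = k // 2
        xp = ad.pad2d(x, p, p)
        col = ad.im2col(xp, k, k, 1, st)  # (B, C*k*k, Ho*Wo)
        Ho = H
        Wo = (W + 2 * p - k) // st + 1
        out_maps = self.w.shape[0]
        w2 = ad.reshape(self.w, (out_maps, C * k * k))
        y = ad.matmul(w2, col)  # (B, out_maps, Ho*Wo)
        y = ad.reshape(y, (B, out_maps, Ho, Wo))
        return y + ad.reshape(self.b, (1, out_maps, 1, 1))


class ConvTranspose2dTime(Module):
    """Fractional-stride ("stride = 0.5") convolution: doubles the time axis.

    Implemented as zero-stuffing along time followed by a stride-1
    convolution, the standard equivalent form of a stride-2 transposed
    convolution.
    """

    def __init__(self, in_maps, out_maps, kernel=3, rng=None, gain=1.0):
        self.conv = Conv2d(in_maps, out_maps, kernel, 1, rng=rng, gain=gain)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(ad.zero_stuff(x, 2))


class Dense(Module):
    def __init__(self, n_in, n_out, rng=None, gain=1.0):
        std = gain * np.sqrt(2.0 / n_in)
        rng = rng or np.random.default_rng()
        self.w = Parameter(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + ad.reshape(self.b, (1, -1))


class BatchNorm(Module):
    """Batch normalization over (batch, channels, time) per feature map."""

    def __init__(self, n_maps, eps=1e-5, momentum=0.1):
        self.gamma = Parameter(np.ones(n_maps))
        self.beta = Parameter(np.zeros(n_maps))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        axes = (0, 2, 3)
        if training:
            mu = ad.tmean(x, axis=axes, keepdims=True)
            xc = x - mu
            var = ad.tmean(xc * xc, axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        inv = ad.power(var + self.eps, -0.5)
        g = ad.reshape(self.gamma, (1, -1, 1, 1))
        b = ad.reshape(self.beta, (1, -1, 1, 1))
        return xc * inv * g + b


# ---------------------------------------------------------------------------
# architecture specs
# ---------------------------------------------------------------------------


@dataclass
class GeneratorSpec:
    """Residual super-resolution generator: n_blocks residual blocks of two
    3x3/stride-1 convolutions with batch norm and ReLU, a transposed
    convolution doubling the time axis, and a linear output convolution.
    A fixed cubic-interpolation skip from the upsampled input makes the
    network learn a residual correction."""

    n_blocks: int = 16
    n_maps: int = 64
    kernel: int = 3
    upsample_factor: int = 2
    use_batchnorm: bool = True
    min_tau: int = 12


@dataclass
class CriticSpec:
    """Eight 3x3 convolutions with LeakyReLU, feature maps doubling every two
    layers and stride alternating 1,2 along time, then dense 1024 -> 1."""

    base_maps: int = 64
    n_conv: int = 8
    dense_units: int = 1024
    leaky_slope: float = 0.2
    use_batchnorm: bool = True
    sigmoid_head: bool = False

    @property
    def filter_counts(self) -> list[int]:
        return [self.base_maps * (2 ** (i // 2)) for i in range(self.n_conv)]

    @property
    def strides(self) -> list[int]:
        return [1 if i % 2 == 0 else 2 for i in range(self.n_conv)]


class ResidualBlock(Module):
    def __init__(self, n_maps, kernel, use_bn, rng):
        self.c1 = Conv2d(n_maps, n_maps, kernel, 1, rng)
        self.c2 = Conv2d(n_maps, n_maps, kernel, 1, rng)
        self.use_bn = use_bn
        if use_bn:
            self.bn1 = BatchNorm(n_maps)
            self.bn2 = BatchNorm(n_maps)

    def __call__(self, x, training=True):
        h = self.c1(x)
        if self.use_bn:
            h = self.bn1(h, training)
        h = ad.relu(h)
        h = self.c2(h)
        if self.use_bn:
            h = self.bn2(h, training)
        return h + x


class Generator(Module):
    """Maps a normalized LSS patch (B, N, tau) to an HSS patch (B, N, 2*tau).

    Fully convolutional: any channel count and any patch length >= spec.min_tau
    work at inference.  Output is in normalized [-1, 1] units; use
    :meth:`generate` for scope-denormalized, clipped microvolt output.
    """

    def __init__(self, spec: GeneratorSpec, scope=(-1.0, 1.0), seed: int = 0):
        self.spec = spec
        self.scope = tuple(scope)
        rng = np.random.default_rng(seed)
        m = spec.n_maps
        self.head = Conv2d(1, m, spec.kernel, 1, rng)
        self.blocks = [
            ResidualBlock(m, spec.kernel, spec.use_batchnorm, rng)
            for _ in range(spec.n_blocks)
        ]
        self.up = ConvTranspose2dTime(m, m, spec.kernel, rng)
        # zero-init of the residual branch's output conv: the untrained
        # generator reproduces cubic interpolation exactly and training can
        # only refine it (standard residual-learning initialization)
        self.tail = Conv2d(m, 1, spec.kernel, 1, rng, gain=0.0)
        kern = CUBIC_KERNEL.reshape(1, 1, 1, -1)
        self._cubic = kern  # fixed, not a Parameter

    def _cubic_skip(self, x: Tensor) -> Tensor:
        """Cubic-convolution factor-2 upsampling along time (fixed weights)."""
        z = ad.zero_stuff(x, 2)  # (B, 1, N, 2T)
        k = self._cubic.shape[-1]
        p = k // 2
        zp = ad.pad2d(z, 0, p)
        col = ad.im2col(zp, 1, k, 1, 1)  # (B, k, 2T)
        w = Tensor(self._cubic.reshape(1, k))
        y = ad.matmul(w, col)  # (B, 1, 2T)
        B, _, N, T2 = z.shape
        return ad.reshape(y, (B, 1, N, T2))

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        """x: (B, N, tau) normalized -> (B, N, 2*tau) normalized."""
        B, N, T = x.shape
        if T < self.spec.min_tau:
            raise ValueError(
                f"patch length {T} below generator minimum {self.spec.min_tau}"
            )
        x4 = ad.reshape(x, (B, 1, N, T))
        h = ad.relu(self.head(x4))
        for blk in self.blocks:
            h = blk(h, training)
        h = ad.relu(self.up(h))
        out = self.tail(h) + self._cubic_skip(x4)
        return ad.reshape(out, (B, N, T * self.upsample_factor()))

    def upsample_factor(self) -> int:
        return self.spec.upsample_factor

    def generate(self, patches: np.ndarray, scope=None) -> np.ndarray:
        """Inference on raw microvolt patches -> microvolt output, clipped."""
        from .trialset import normalize_scope, denormalize_scope

        scope = tuple(scope if scope is not None else self.scope)
        z = normalize_scope(np.asarray(patches, dtype=np.float64), scope)
        y = self(Tensor(z), training=False).data
        y = denormalize_scope(y, scope)
        return np.clip(y, scope[0], scope[1])


class Critic(Module):
    """Maps a normalized HSS patch (B, N, patch_len) to one score per patch."""

    def __init__(self, spec: CriticSpec, n_channels: int, patch_len: int, seed: int = 0):
        self.spec = spec
        n_down = sum(1 for s in spec.strides if s == 2)
        min_len = 2**n_down
        if patch_len < min_len:
            raise ValueError(
                f"patch length {patch_len} too short: needs >= {min_len} samples "
                f"to survive {n_down} stride-2 reductions"
            )
        rng = np.random.default_rng(seed)
        self.convs = []
        self.bns = []
        in_maps = 1
        t = patch_len
        for maps, st in zip(spec.filter_counts, spec.strides):
            self.convs.append(Conv2d(in_maps, maps, 3, st, rng))
            if spec.use_batchnorm:
                self.bns.append(BatchNorm(maps))
            t = (t + 2 - 3) // st + 1
            in_maps = maps
        flat = in_maps * n_channels * t
        self.fc1 = Dense(flat, spec.dense_units, rng)
        self.fc2 = Dense(spec.dense_units, 1, rng)
        self.n_channels = n_channels
        self.patch_len = patch_len
        self._flat = flat

    def __call__(self, x: Tensor, training: bool = True) -> Tensor:
        """x: (B, N, patch_len) normalized -> (B,) scores."""
        B, N, T = x.shape
        if (N, T) != (self.n_channels, self.patch_len):
            raise ValueError(
                f"critic built for {(self.n_channels, self.patch_len)}, got {(N, T)}"
            )
        h = ad.reshape(x, (B, 1, N, T))
        for i, conv in enumerate(self.convs):
            h = conv(h)
            if self.spec.use_batchnorm:
                h = self.bns[i](h, training)
            h = ad.leaky_relu(h, self.spec.leaky_slope)
        h = ad.reshape(h, (B, self._flat))
        h = ad.leaky_relu(self.fc1(h), self.spec.leaky_slope)
        s = ad.reshape(self.fc2(h), (B,))
        if self.spec.sigmoid_head:
            s = ad.sigmoid(s)
        return s


def build_generator(
    spec: GeneratorSpec | None = None,
    n_channels: int | None = None,
    seed: int = 0,
    scope=(-1.0, 1.0),
) -> Generator:
    """Construct a generator; `n_channels` is accepted for interface symmetry
    but the network is fully convolutional and channel-agnostic."""
    return Generator(spec or GeneratorSpec(), scope=scope, seed=seed)


def build_critic(
    spec: CriticSpec | None = None,
    n_channels: int = 8,
    patch_len: int = 24,
    seed: int = 0,
) -> Critic:
    return Critic(spec or CriticSpec(), n_channels, patch_len, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_generator(gen: Generator, path, fs_pair=None, n_channels=None) -> None:
    """Serialize generator parameters + spec metadata to a .npz container."""
    import json

    meta = {
        "n_blocks": gen.spec.n_blocks,
        "n_maps": gen.spec.n_maps,
        "kernel": gen.spec.kernel,
        "use_batchnorm": gen.spec.use_batchnorm,
        "scope": list(gen.scope),
        "fs_pair": list(fs_pair) if fs_pair else None,
        "n_channels": n_channels,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(gen.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_generator(path) -> Generator:
    import json

    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        arrays = [f[f"arr_{i}"] for i in range(len(f.files) - 1)]
    spec = GeneratorSpec(
        n_blocks=int(meta["n_blocks"]),
        n_maps=int(meta["n_maps"]),
        kernel=int(meta["kernel"]),
        use_batchnorm=bool(meta["use_batchnorm"]),
    )
    gen = Generator(spec, scope=tuple(meta["scope"]))
    targets = gen.state_arrays()
    if len(targets) != len(arrays):
        raise ValueError("checkpoint does not match the generator layout")
    for dst, src in zip(targets, arrays):
        dst[...] = src
    return gen


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the update used for GAN training (alpha=1e-5, beta1=0.5)."""

    def __init__(self, params, lr=1e-5, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


class RMSprop:
    """RMSprop as used for the Wasserstein variant (alpha=1e-5, beta=0.9)."""

    def __init__(self, params, lr=1e-5, beta=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta, self.eps = lr, beta, eps
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        for p, g, v in zip(self.params, grads, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            v *= self.beta
            v += (1 - self.beta) * gd * gd
            p.data -= self.lr * gd / (np.sqrt(v) + self.eps)
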