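"""The (2+1)D-factorized volumetric U-Net, implemented in numpy.

The network is a four-level encoder/decoder U-Net whose every 3-D
convolution is factorized into an in-plane stage (kernel 1x3x3) followed by
an across-slice stage (kernel 3x1x1), each carrying its own ELU
nonlinearity — the (2+1)D design borrowed from video models, with the slice
axis playing the role of time.  Encoder blocks are
[pair -> BN -> dropout -> pair -> BN -> (skip tap) -> 2x2x2 max-pool];
the bridge repeats the encoder body without pooling at the bottleneck
width; decoder blocks are [2x2x2 transpose conv (stride 2, ELU) ->
concatenate skip -> pair -> BN -> dropout -> pair -> BN]; a 1x1x1
convolution with softmax produces per-voxel class probabilities.

Everything here — forward pass, backpropagation, and the layer zoo — is
written directly on numpy arrays in channels-last layout (slice, row, col,
channel), with an implicit batch of one: whole volumes are processed in a
single pass, no patching.  Convolutions are evaluated as sums of shifted
channel-mixing matrix products, which keeps the heavy lifting inside BLAS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np

from .errors import ShapeError, UsageError
from .volume_io import MultiModalVolume, LabelVolume, CLASS_NAMES

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureConfig:
    """Declarative description of the (2+1)D U-Net.

    Defaults reproduce the reference architecture: encoder filter counts
    65/32/16/8 (top to bottom, halved per level), a 4-filter bridge,
    6 input channels (two modalities replicated three times), 4 output
    classes, 2x2x2 pooling, dropout 0.2 and ELU activations.
    """

    levels: int = 4
    filters_per_level: tuple = (65, 32, 16, 8)
    bridge_filters: int = 4
    in_channels: int = 6
    n_classes: int = 4
    spatial_kernel: tuple = (1, 3, 3)
    slice_kernel: tuple = (3, 1, 1)
    pool: tuple = (2, 2, 2)
    dropout_rate: float = 0.2
    activation: str = "elu"
    padding_mode: str = "same"
    # numerical knobs beyond the headline hyperparameters
    elu_alpha: float = 1.0
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3
    bn_inference: str = "batch"     # "batch": normalize with the volume's own stats
    pad_inputs: bool = False        # zero-pad non-divisible extents, crop output
    dtype: str = "float32"

    def __post_init__(self):
        self.filters_per_level = tuple(int(f) for f in self.filters_per_level)
        if len(self.filters_per_level) != self.levels:
            raise UsageError(
                f"filters_per_level has {len(self.filters_per_level)} entries "
                f"for {self.levels} levels"
            )
        if any(f <= 0 for f in self.filters_per_level) or self.bridge_filters <= 0:
            raise UsageError("filter counts must be positive")
        if self.in_channels <= 0 or self.n_classes <= 0:
            raise UsageError("channel counts must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise UsageError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        if self.activation != "elu":
            raise UsageError("only ELU activation is supported")
        if self.padding_mode != "same":
            raise UsageError("only 'same' convolution padding is supported")
        if self.bn_inference not in ("batch", "running"):
            raise UsageError("bn_inference must be 'batch' or 'running'")

    @property
    def pool_factor(self):
        return tuple(p ** self.levels for p in self.pool)


def level_shape(cfg: ArchitectureConfig, input_extents, level: int):
    """Spatial extents after ``level`` pooling stages (level 0 = input)."""
    if not (0 <= level <= cfg.levels):
        raise UsageError(f"level must lie in [0, {cfg.levels}], got {level}")
    out = []
    for e in input_extents:
        div = 2 ** level
        if e % div:
            raise ShapeError(f"extent {e} not divisible by 2^{level}")
        out.append(e // div)
    return tuple(out)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _elu(z, alpha):
    return np.where(z > 0, z, alpha * np.expm1(z))


def _elu_grad_from_output(out, alpha):
    # ELU is monotone with elu(0) = 0, so the sign of the output matches the
    # sign of the pre-activation; for z <= 0, d/dz = alpha*exp(z) = out + alpha.
    return np.where(out > 0, np.asarray(1.0, dtype=out.dtype), out + alpha)


class _Conv3D:
    """Same-padded 3-D convolution with optional fused ELU."""

    kind = "Conv3D"

    def __init__(self, in_channels, filters, kernel, rng, dtype, activation="elu", alpha=1.0):
        self.in_channels = int(in_channels)
        self.filters = int(filters)
        self.kernel = tuple(kernel)
        self.activation = activation
        self.alpha = alpha
        fan_in = math.prod(self.kernel) * self.in_channels
        fan_out = math.prod(self.kernel) * self.filters
        limit = math.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, self.kernel + (self.in_channels, self.filters)).astype(dtype)
        self.b = np.zeros(self.filters, dtype=dtype)
        self._cache = None

    trainable = (("W", "gW"), ("b", "gb"))

    @property
    def parameter_count(self):
        return self.W.size + self.b.size

    def output_shape(self, in_shape):
        return in_shape[:3] + (self.filters,)

    def forward(self, x, training=False):
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        if pd or ph or pw:
            xp = np.pad(x, ((pd, pd), (ph, ph), (pw, pw), (0, 0)))
        else:
            xp = x
        D, H, W = x.shape[:3]
        out = np.empty(x.shape[:3] + (self.filters,), dtype=x.dtype)
        out[...] = self.b
        for i, j, k in product(range(kd), range(kh), range(kw)):
            out += np.tensordot(xp[i:i + D, j:j + H, k:k + W], self.W[i, j, k], axes=([3], [0]))
        if self.activation == "elu":
            out = _elu(out, self.alpha)
        if training:
            self._cache = (xp, out, (D, H, W))
        return out

    def backward(self, grad):
        xp, out, (D, H, W) = self._cache
        if self.activation == "elu":
            grad = grad * _elu_grad_from_output(out, self.alpha)
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        self.gb = grad.sum(axis=(0, 1, 2))
        self.gW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for i, j, k in product(range(kd), range(kh), range(kw)):
            self.gW[i, j, k] = np.tensordot(
                xp[i:i + D, j:j + H, k:k + W], grad, axes=([0, 1, 2], [0, 1, 2])
            )
            dxp[i:i + D, j:j + H, k:k + W] += np.tensordot(grad, self.W[i, j, k], axes=([3], [1]))
        self._cache = None
        if pd or ph or pw:
            return np.ascontiguousarray(dxp[pd:pd + D, ph:ph + H, pw:pw + W])
        return dxp


class _ConvTranspose3D:
    """Stride-2 2x2x2 transpose convolution (learned upsampling) with ELU."""

    kind = "ConvT3d"

    def __init__(self, in_channels, filters, rng, dtype, kernel=(2, 2, 2), alpha=1.0):
        self.in_channels = int(in_channels)
        self.filters = int(filters)
        self.kernel = tuple(kernel)
        self.stride = tuple(kernel)
        self.activation = "elu"
        self.alpha = alpha
        fan_in = self.in_channels  # each output voxel sees exactly one input voxel
        fan_out = math.prod(self.kernel) * self.filters
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, self.kernel + (self.in_channels, self.filters)).astype(dtype)
        self.b = np.zeros(self.filters, dtype=dtype)
        self._cache = None

    trainable = (("W", "gW"), ("b", "gb"))

    @property
    def parameter_count(self):
        return self.W.size + self.b.size

    def output_shape(self, in_shape):
        d, h, w = in_shape[:3]
        return (2 * d, 2 * h, 2 * w, self.filters)

    def forward(self, x, training=False):
        D, H, W = x.shape[:3]
        out = np.empty((2 * D, 2 * H, 2 * W, self.filters), dtype=x.dtype)
        for a, b, c in product((0, 1), repeat=3):
            out[a::2, b::2, c::2] = np.tensordot(x, self.W[a, b, c], axes=([3], [0])) + self.b
        out = _elu(out, self.alpha)
        if training:
            self._cache = (x, out)
        return out

    def backward(self, grad):
        x, out = self._cache
        grad = grad * _elu_grad_from_output(out, self.alpha)
        self.gb = grad.sum(axis=(0, 1, 2))
        self.gW = np.empty_like(self.W)
        dx = np.zeros_like(x)
        for a, b, c in product((0, 1), repeat=3):
            g = grad[a::2, b::2, c::2]
            self.gW[a, b, c] = np.tensordot(x, g, axes=([0, 1, 2], [0, 1, 2]))
            dx += np.tensordot(g, self.W[a, b, c], axes=([3], [1]))
        self._cache = None
        return dx


class _BatchNorm:
    """Per-channel normalization over the spatial extent of the volume.

    With a batch of one this normalizes each channel by the current
    volume's own statistics (instance-normalization behavior).  Running
    averages are tracked during training and used at inference only when
    the config selects ``bn_inference='running'``.
    """

    kind = "BN"

    def __init__(self, channels, dtype, momentum=0.99, eps=1e-3, inference="batch"):
        self.channels = int(channels)
        self.momentum = momentum
        self.eps = eps
        self.inference = inference
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    trainable = (("gamma", "ggamma"), ("beta", "gbeta"))

    @property
    def parameter_count(self):
        return self.gamma.size + self.beta.size

    def output_shape(self, in_shape):
        return in_shape

    def forward(self, x, training=False):
        if training or self.inference == "batch":
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            if training:
                m = self.momentum
                self.running_mean[...] = m * self.running_mean + (1 - m) * mean
                self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + np.asarray(self.eps, dtype=x.dtype))
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat, std)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, std = self._cache
        n = xhat.shape[0] * xhat.shape[1] * xhat.shape[2]
        self.ggamma = (grad * xhat).sum(axis=(0, 1, 2))
        self.gbeta = grad.sum(axis=(0, 1, 2))
        dx = (self.gamma / std) * (grad - self.gbeta / n - xhat * (self.ggamma / n))
        self._cache = None
        return dx.astype(xhat.dtype, copy=False)


class _Dropout:
    """Inverted dropout; identity at inference."""

    kind = "Dropout"
    trainable = ()
    parameter_count = 0

    def __init__(self, rate):
        self.rate = float(rate)
        self._mask = None

    def output_shape(self, in_shape):
        return in_shape

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise UsageError("dropout in training mode requires a random generator")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class _MaxPool3D:
    """2x2x2 max pooling; gradient routed to the first maximum in each window."""

    kind = "MPool3D"
    trainable = ()
    parameter_count = 0

    def __init__(self, pool=(2, 2, 2)):
        self.pool = tuple(pool)

    def output_shape(self, in_shape):
        d, h, w, c = in_shape
        pd, ph, pw = self.pool
        if d % pd or h % ph or w % pw:
            raise ShapeError(f"extents {in_shape[:3]} not divisible by pool {self.pool}")
        return (d // pd, h // ph, w // pw, c)

    def forward(self, x, training=False):
        D, H, W, C = x.shape
        pd, ph, pw = self.pool
        if D % pd or H % ph or W % pw:
            raise ShapeError(f"extents {(D, H, W)} not divisible by pool {self.pool}")
        d, h, w = D // pd, H // ph, W // pw
        win = pd * ph * pw
        xr = (
            x.reshape(d, pd, h, ph, w, pw, C)
            .transpose(0, 2, 4, 1, 3, 5, 6)
            .reshape(d, h, w, win, C)
        )
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._cache = (idx, (D, H, W, C))
        return out

    def backward(self, grad):
        idx, (D, H, W, C) = self._cache
        pd, ph, pw = self.pool
        d, h, w = D // pd, H // ph, W // pw
        win = pd * ph * pw
        g = np.zeros((d, h, w, win, C), dtype=grad.dtype)
        np.put_along_axis(g, idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        self._cache = None
        return (
            g.reshape(d, h, w, pd, ph, pw, C)
            .transpose(0, 3, 1, 4, 2, 5, 6)
            .reshape(D, H, W, C)
        )


# ---------------------------------------------------------------------------
# (2+1)D pair and U-Net blocks
# ---------------------------------------------------------------------------

class ConvPair21D:
    """The factorized convolution unit: 1x3x3 ELU conv then 3x1x1 ELU conv.

    Both stages carry the full ``filters`` output width — no intermediate
    bottleneck — so the unit's trainable parameter count is
    ``kh*kw*cin*f + f`` plus ``kd*f*f + f``.
    """

    def __init__(self, in_channels, filters, cfg: ArchitectureConfig, rng):
        self.spatial = _Conv3D(in_channels, filters, cfg.spatial_kernel, rng,
                               cfg.dtype, activation=cfg.activation, alpha=cfg.elu_alpha)
        self.slice = _Conv3D(filters, filters, cfg.slice_kernel, rng,
                             cfg.dtype, activation=cfg.activation, alpha=cfg.elu_alpha)
        self.filters = int(filters)

    @property
    def layers(self):
        return [self.spatial, self.slice]

    @property
    def parameter_count(self):
        return self.spatial.parameter_count + self.slice.parameter_count

    def output_shape(self, in_shape):
        return in_shape[:3] + (self.filters,)

    def forward(self, x, training=False):
        return self.slice.forward(self.spatial.forward(x, training), training)

    def backward(self, grad):
        return self.spatial.backward(self.slice.backward(grad))

    def __call__(self, x, training=False):
        return self.forward(x, training)


def build_conv21d_pair(in_channels, filters, cfg: ArchitectureConfig = None, rng=None) -> ConvPair21D:
    """Construct a (2+1)D convolution pair as a standalone transform."""
    if in_channels <= 0 or filters <= 0:
        raise UsageError("channel counts must be positive")
    cfg = cfg if cfg is not None else ArchitectureConfig(in_channels=in_channels)
    rng = rng if rng is not None else np.random.default_rng(0)
    return ConvPair21D(in_channels, filters, cfg, rng)


def _make_bn(channels, cfg):
    return _BatchNorm(channels, cfg.dtype, cfg.bn_momentum, cfg.bn_eps, cfg.bn_inference)


class _EncoderBlock:
    def __init__(self, in_channels, filters, cfg, rng):
        self.pair1 = ConvPair21D(in_channels, filters, cfg, rng)
        self.bn1 = _make_bn(filters, cfg)
        self.drop = _Dropout(cfg.dropout_rate)
        self.pair2 = ConvPair21D(filters, filters, cfg, rng)
        self.bn2 = _make_bn(filters, cfg)
        self.pool = _MaxPool3D(cfg.pool)
        self.filters = filters

    @property
    def layers(self):
        return self.pair1.layers + [self.bn1, self.drop] + self.pair2.layers + [self.bn2, self.pool]

    def forward(self, x, training, rng):
        h = self.pair1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.drop.forward(h, training, rng)
        h = self.pair2.forward(h, training)
        tap = self.bn2.forward(h, training)
        return self.pool.forward(tap, training), tap

    def backward(self, grad, skip_grad):
        g = self.pool.backward(grad) + skip_grad
        g = self.bn2.backward(g)
        g = self.pair2.backward(g)
        g = self.drop.backward(g)
        g = self.bn1.backward(g)
        return self.pair1.backward(g)


class _BridgeBlock:
    """Encoder body without pooling, at the bottleneck filter count."""

    def __init__(self, in_channels, filters, cfg, rng):
        self.pair1 = ConvPair21D(in_channels, filters, cfg, rng)
        self.bn1 = _make_bn(filters, cfg)
        self.drop = _Dropout(cfg.dropout_rate)
        self.pair2 = ConvPair21D(filters, filters, cfg, rng)
        self.bn2 = _make_bn(filters, cfg)
        self.filters = filters

    @property
    def layers(self):
        return self.pair1.layers + [self.bn1, self.drop] + self.pair2.layers + [self.bn2]

    def forward(self, x, training, rng):
        h = self.pair1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.drop.forward(h, training, rng)
        h = self.pair2.forward(h, training)
        return self.bn2.forward(h, training)

    def backward(self, grad):
        g = self.bn2.backward(grad)
        g = self.pair2.backward(g)
        g = self.drop.backward(g)
        g = self.bn1.backward(g)
        return self.pair1.backward(g)


class _DecoderBlock:
    def __init__(self, in_channels, skip_channels, filters, cfg, rng):
        self.up = _ConvTranspose3D(in_channels, filters, rng, cfg.dtype,
                                   kernel=cfg.pool, alpha=cfg.elu_alpha)
        self.skip_channels = int(skip_channels)
        self.pair1 = ConvPair21D(filters + skip_channels, filters, cfg, rng)
        self.bn1 = _make_bn(filters, cfg)
        self.drop = _Dropout(cfg.dropout_rate)
        self.pair2 = ConvPair21D(filters, filters, cfg, rng)
        self.bn2 = _make_bn(filters, cfg)
        self.filters = filters

    @property
    def layers(self):
        return [self.up] + self.pair1.layers + [self.bn1, self.drop] + self.pair2.layers + [self.bn2]

    def forward(self, x, skip, training, rng):
        u = self.up.forward(x, training)
        if u.shape[:3] != skip.shape[:3]:
            raise ShapeError(f"decoder/skip extent mismatch: {u.shape[:3]} vs {skip.shape[:3]}")
        h = np.concatenate([u, skip], axis=3)
        h = self.pair1.forward(h, training)
        h = self.bn1.forward(h, training)
        h = self.drop.forward(h, training, rng)
        h = self.pair2.forward(h, training)
        return self.bn2.forward(h, training)

    def backward(self, grad):
        g = self.bn2.backward(grad)
        g = self.pair2.backward(g)
        g = self.drop.backward(g)
        g = self.bn1.backward(g)
        g = self.pair1.backward(g)
        gu, gskip = g[..., : self.up.filters], g[..., self.up.filters:]
        return self.up.backward(np.ascontiguousarray(gu)), np.ascontiguousarray(gskip)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities, channels-last."""

    probs: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4:
            raise ShapeError(f"expected (slice,row,col,class) grid, got {self.probs.shape}")
        sums = self.probs.sum(axis=3)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ShapeError("class probabilities must sum to 1 per voxel")
        if self.probs.min() < -1e-7 or self.probs.max() > 1 + 1e-7:
            raise ShapeError("probabilities must lie in [0, 1]")

    @property
    def n_classes(self):
        return self.probs.shape[3]


def softmax(logits, axis=-1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SegModel:
    """A built (2+1)D U-Net instance: configuration plus trainable weights."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = config
        self.encoders = []
        cin = cfg.in_channels
        for f in cfg.filters_per_level:
            self.encoders.append(_EncoderBlock(cin, f, cfg, rng))
            cin = f
        self.bridge = _BridgeBlock(cin, cfg.bridge_filters, cfg, rng)
        cin = cfg.bridge_filters
        self.decoders = []  # bottom-up; decoder i consumes skip of encoder levels-1-i
        for f in reversed(cfg.filters_per_level):
            self.decoders.append(_DecoderBlock(cin, f, f, cfg, rng))
            cin = f
        self.classifier = _Conv3D(cin, cfg.n_classes, (1, 1, 1), rng, cfg.dtype, activation=None)
        self.mode = "inference"

    # -- structure ---------------------------------------------------------

    @property
    def blocks(self):
        return self.encoders + [self.bridge] + self.decoders + [self.classifier]

    def layers(self):
        out = []
        for blk in self.encoders:
            out.extend(blk.layers)
        out.extend(self.bridge.layers)
        for blk in self.decoders:
            out.extend(blk.layers)
        out.append(self.classifier)
        return out

    def layer_table(self):
        """Audit view of the built network: one row per layer with the
        attributes that define it (kind, filters, kernel, stride/pool,
        activation, dropout rate)."""
        rows = []
        for lyr in self.layers():
            row = {"layer": lyr.kind, "filters": None, "kernel": None,
                   "strides": None, "pool": None, "activation": None, "dropout": None}
            if lyr.kind == "Conv3D":
                row.update(filters=lyr.filters, kernel=lyr.kernel, strides=(1, 1, 1),
                           activation=("softmax" if lyr is self.classifier else lyr.activation))
            elif lyr.kind == "ConvT3d":
                row.update(filters=lyr.filters, kernel=lyr.kernel, strides=lyr.stride,
                           activation=lyr.activation)
            elif lyr.kind == "MPool3D":
                row.update(strides=lyr.pool, pool=lyr.pool)
            elif lyr.kind == "Dropout":
                row.update(dropout=lyr.rate)
            rows.append(row)
        # concatenate joints are graph edges, not parameterized layers; add
        # them where they occur for a faithful sequential audit
        table = []
        i = 0
        for row in rows:
            table.append(row)
            if row["layer"] == "ConvT3d":
                table.append({"layer": "Concatenate", "filters": None, "kernel": None,
                              "strides": None, "pool": None, "activation": None, "dropout": None})
        return table

    def parameter_count(self):
        return sum(lyr.parameter_count for lyr in self.layers())

    def trainables(self):
        """(layer, param-attr, grad-attr) triples in deterministic order."""
        out = []
        for lyr in self.layers():
            for p, g in lyr.trainable:
                out.append((lyr, p, g))
        return out

    def get_weights(self):
        """Copies of all weights and batch-norm running statistics."""
        arrays = []
        for lyr in self.layers():
            for p, _ in lyr.trainable:
                arrays.append(getattr(lyr, p).copy())
            if lyr.kind == "BN":
                arrays.append(lyr.running_mean.copy())
                arrays.append(lyr.running_var.copy())
        return arrays

    def set_weights(self, arrays):
        it = iter(arrays)
        for lyr in self.layers():
            for p, _ in lyr.trainable:
                tgt = getattr(lyr, p)
                tgt[...] = next(it)
            if lyr.kind == "BN":
                lyr.running_mean[...] = next(it)
                lyr.running_var[...] = next(it)

    # -- shape trace -------------------------------------------------------

    def trace_shapes(self, input_extents):
        """Walk the layer graph symbolically and report named feature shapes.

        Returns a dict with the input, per-level post-pool shapes
        ("after_pool_k"), the bridge input/output, per-level decoder outputs
        and the classifier output, each as (slice, row, col, channels).
        """
        cfg = self.config
        shape = tuple(input_extents) + (cfg.in_channels,)
        trace = {"input": shape}
        skips = []
        h = shape
        for k, enc in enumerate(self.encoders, start=1):
            for lyr in enc.layers[:-1]:
                h = lyr.output_shape(h)
            skips.append(h)
            h = enc.pool.output_shape(h)
            trace[f"after_pool_{k}"] = h
        trace["bridge_input"] = h
        for lyr in self.bridge.layers:
            h = lyr.output_shape(h)
        trace["bridge_output"] = h
        for i, dec in enumerate(self.decoders):
            u = dec.up.output_shape(h)
            skip = skips[len(skips) - 1 - i]
            h = u[:3] + (u[3] + skip[3],)
            for lyr in dec.layers[1:]:
                h = lyr.output_shape(h)
            trace[f"decoder_{i + 1}"] = h
        trace["output"] = self.classifier.output_shape(h)
        return trace

    # -- execution ---------------------------------------------------------

    def forward(self, x, training=False, rng=None, shape_log=None):
        """Run the network on a channels-last array, returning logits.

        ``shape_log``, when given a dict, records the actual array extents
        at the same checkpoints as :meth:`trace_shapes`.
        """
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ShapeError(
                f"expected (slice,row,col,{self.config.in_channels}) input, got {x.shape}"
            )
        div = 2 ** self.config.levels
        if any(e % div for e in x.shape[:3]):
            raise ShapeError(
                f"spatial extents {x.shape[:3]} not divisible by 2^levels = {div}"
            )
        x = np.ascontiguousarray(x, dtype=self.config.dtype)
        log = shape_log if shape_log is not None else None
        if log is not None:
            log["input"] = x.shape
        skips = []
        h = x
        for k, enc in enumerate(self.encoders, start=1):
            h, tap = enc.forward(h, training, rng)
            skips.append(tap)
            if log is not None:
                log[f"after_pool_{k}"] = h.shape
        if log is not None:
            log["bridge_input"] = h.shape
        h = self.bridge.forward(h, training, rng)
        if log is not None:
            log["bridge_output"] = h.shape
        for i, dec in enumerate(self.decoders):
            h = dec.forward(h, skips[len(skips) - 1 - i], training, rng)
            if log is not None:
                log[f"decoder_{i + 1}"] = h.shape
        logits = self.classifier.forward(h, training)
        if log is not None:
            log["output"] = logits.shape
        return logits

    def backward(self, grad_logits):
        """Backpropagate a logit gradient, populating per-layer gradients."""
        g = self.classifier.backward(grad_logits)
        skip_grads = []
        for dec in reversed(self.decoders):
            g, gs = dec.backward(g)
            skip_grads.append(gs)
        # skip_grads is ordered top-encoder first; encoders unwind bottom-up
        g = self.bridge.backward(g)
        for enc, gs in zip(reversed(self.encoders), reversed(skip_grads)):
            g = enc.backward(g, gs)
        return g


def build_model(cfg: ArchitectureConfig, seed: int = 0) -> SegModel:
    """Build a seeded model instance; identical (cfg, seed) pairs yield
    bitwise-identical initial parameters."""
    return SegModel(cfg, seed=seed)


def _pad_to_multiple(x, div):
    pads = []
    for e in x.shape[:3]:
        total = (-e) % div
        pads.append((total // 2, total - total // 2))
    pads.append((0, 0))
    return np.pad(x, pads), pads


def predict(model: SegModel, volume: MultiModalVolume, pad=None):
    """Segment a multi-modal volume.

    Returns the per-voxel class probabilities and the argmax label map
    (ties resolved toward the lowest class index).  Dropout is inactive;
    inference is deterministic.  Extents that are not divisible by
    2^levels raise unless padding is enabled (``pad=True`` or
    ``config.pad_inputs``), in which case the input is symmetrically
    zero-padded and the output cropped back.
    """
    cfg = model.config
    x = volume.channels
    if x.shape[3] != cfg.in_channels:
        raise ShapeError(f"model expects {cfg.in_channels} channels, volume has {x.shape[3]}")
    div = 2 ** cfg.levels
    do_pad = cfg.pad_inputs if pad is None else pad
    pads = None
    orig = x.shape[:3]
    if any(e % div for e in orig):
        if not do_pad:
            raise ShapeError(
                f"extents {orig} not divisible by 2^levels = {div}; enable padding to proceed"
            )
        x, pads = _pad_to_multiple(x, div)
    logits = model.forward(x, training=False)
    if pads is not None:
        sl = tuple(slice(p0, p0 + e) for (p0, _), e in zip(pads[:3], orig))
        logits = logits[sl]
    probs = softmax(logits.astype(np.float64))
    labels = probs.argmax(axis=3)
    pv = ProbabilityVolume(probs=probs, class_names=CLASS_NAMES[: cfg.n_classes])
    lv = LabelVolume(labels=labels, class_names=CLASS_NAMES[: cfg.n_classes],
                     spacing=volume.spacing, origin=volume.origin)
    return pv, lv


# ---------------------------------------------------------------------------
# Checkpoint serialization
# ---------------------------------------------------------------------------

def save_model(model: SegModel, path_prefix: str) -> None:
    """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (architecture)."""
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.get_weights())}
    np.savez(f"{path_prefix}.npz", **arrays)
    manifest = {"config": asdict(model.config), "seed": model.seed}
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_model(path_prefix: str) -> SegModel:
    with open(f"{path_prefix}.json") as fh:
        manifest = json.load(fh)
    cfgd = manifest["config"]
    for key in ("filters_per_level", "spatial_kernel", "slice_kernel", "pool"):
        cfgd[key] = tuple(cfgd[key])
    model = SegModel(ArchitectureConfig(**cfgd), seed=manifest.get("seed", 0))
    with np.load(f"{path_prefix}.npz") as data:
        arrays = [data[k] for k in sorted(data.files)]
    model.set_weights(arrays)
    return model
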