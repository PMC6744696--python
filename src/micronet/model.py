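"""The fully convolutional regression network (MicroNet).

A U-Net-like residual architecture with four paths:

* **downsampling** — an input transition (one 3x3 convolution) followed by
  ``depth`` residual blocks; a stride-2 convolution sits between adjacent
  blocks and the filter count doubles at every halving except the last
  residual block;
* **upsampling** — ``depth`` residual blocks in the converse direction,
  connected by stride-2 transposed convolutions;
* **concatenation** — each downsampled feature map is copied and
  concatenated with its upsampling counterpart; because downsampling uses
  the floor convention (75 -> 37) while upsampling doubles exactly
  (37 -> 74), upsampled maps are zero-padded on the bottom/right edges to
  match (74 -> 75);
* **multi-context aggregation** — the output of every downsampling residual
  block is brought back to full resolution by a single transposed
  convolution and summed into one multi-context feature map, which the
  output transition (two convolutions) turns into the predicted proximity
  map.

Batch normalization follows every (strided/transposed) convolution and an
ELU follows every normalization and every element-wise addition.  Dropout
is applied after the convolutions of the last two residual blocks of the
downsampling path.

Blocks are labeled 1..(2*depth + 2) from input to output — with the default
``depth = 4`` that is 1 = input transition, 2-5 = downsampling residual
blocks, 6-9 = upsampling residual blocks, 10 = output transition — and the
first k blocks can be frozen for fine-tuning experiments.  The stride-2
convolution entering a residual block belongs to that block's index; the
multi-context projections feed the output directly and are assigned to the
output transition block.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from typing import Iterator, Optional

import numpy as np

from . import _autograd as ag
from ._autograd import Parameter, Tensor

__all__ = [
    "NetworkSpec",
    "MicroNet",
    "build_network",
    "freeze_blocks",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    base_width   : channel count of the input transition block
    depth        : residual blocks per path; block indices run 1..2*depth+2
    dropout_rate : dropout after the convolutions of the last two
                   downsampling residual blocks
    elu_alpha    : ELU saturation hyperparameter
    output_scale : value a center pixel regresses to; must match the
                   proximity-encoding scale
    sigmoid_head : replace the linear output with sigmoid(z) * output_scale
                   (gradient-oracle configuration; not used for detection)
    """

    base_width: int = 32
    depth: int = 4
    dropout_rate: float = 0.5
    elu_alpha: float = 1.0
    output_scale: float = 5.0
    sigmoid_head: bool = False

    def __post_init__(self):
        if self.base_width < 4:
            raise ValueError(f"base_width must be >= 4, got {self.base_width}")
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.min_input_size > 4096:
            raise ValueError("depth produces an unusable minimum input size")

    @property
    def n_blocks(self) -> int:
        return 2 * self.depth + 2

    @property
    def min_input_size(self) -> int:
        # every downsampling halves with floor(); sizes must stay positive
        return 2 ** self.depth

    def down_channels(self) -> list[int]:
        """Channel counts of the downsampling residual blocks: double at each
        halving, except no doubling into the last block."""
        w = self.base_width
        return [w * 2 ** min(k, self.depth - 1) for k in range(1, self.depth + 1)]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv:
    def __init__(self, rng, ci, co, k, stride=1, pad=0):
        fan_in = ci * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, std, (co, ci, k, k)).astype(np.float32))
        self.b = Parameter(np.zeros(co, dtype=np.float32))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, self.stride, self.pad)

    def params(self):
        return [self.w, self.b]


class _ConvT:
    """Transposed convolution with kernel == stride (exact x``stride``
    upsampling, floor-inverse of the stride-2 downsampling)."""

    def __init__(self, rng, ci, co, stride):
        fan_in = ci * stride * stride
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, std, (ci, co, stride, stride)).astype(np.float32))
        self.b = Parameter(np.zeros(co, dtype=np.float32))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.w, self.b, self.stride)

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    def __init__(self, ch, eps=1e-5, momentum=0.1):
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self.frozen = False  # frozen blocks keep their statistics fixed

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train and not self.frozen:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (m / (m - 1)) if m > 1 else var
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            return ag.batch_norm(x, self.gamma, self.beta, mean, var, self.eps, True)
        return ag.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, self.eps, False
        )

    def params(self):
        return [self.gamma, self.beta]


class _ResBlock:
    """Two 3x3 convolutions (BN + ELU after the first, BN after the second),
    an identity shortcut — projected by a 1x1 convolution + BN when channel
    counts differ — element-wise addition, then ELU."""

    def __init__(self, rng, ci, co, elu_alpha, dropout_rate=0.0):
        self.conv1 = _Conv(rng, ci, co, 3, 1, 1)
        self.bn1 = _BatchNorm(co)
        self.conv2 = _Conv(rng, co, co, 3, 1, 1)
        self.bn2 = _BatchNorm(co)
        self.proj = _Conv(rng, ci, co, 1) if ci != co else None
        self.proj_bn = _BatchNorm(co) if ci != co else None
        self.alpha = elu_alpha
        self.dropout_rate = dropout_rate

    def __call__(self, x: Tensor, train: bool, rng) -> Tensor:
        h = ag.elu(self.bn1(self.conv1(x), train), self.alpha)
        if train and self.dropout_rate > 0:
            h = ag.dropout(h, self.dropout_rate, rng)
        h = self.bn2(self.conv2(h), train)
        if train and self.dropout_rate > 0:
            h = ag.dropout(h, self.dropout_rate, rng)
        s = x if self.proj is None else self.proj_bn(self.proj(x), train)
        return ag.elu(ag.add(h, s), self.alpha)

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def batch_norms(self):
        out = [self.bn1, self.bn2]
        if self.proj_bn is not None:
            out.append(self.proj_bn)
        return out


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class MicroNet:
    """Pixel-to-pixel proximity-map regressor.

    Accepts any input whose height and width are at least
    ``spec.min_input_size`` and returns a map of identical spatial size.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.frozen_upto = 0
        rng = np.random.default_rng(seed)
        w, depth = spec.base_width, spec.depth
        chans = [w] + spec.down_channels()  # index 0 = input transition

        # block 1: input transition (one convolution)
        self.in_conv = _Conv(rng, 3, w, 3, 1, 1)
        self.in_bn = _BatchNorm(w)

        # blocks 2 .. depth+1: downsampling path
        self.down_trans: list[tuple[_Conv, _BatchNorm]] = []
        self.down_blocks: list[_ResBlock] = []
        for k in range(1, depth + 1):
            self.down_trans.append((_Conv(rng, chans[k - 1], chans[k], 2, 2, 0), _BatchNorm(chans[k])))
            drop = spec.dropout_rate if k >= depth - 1 else 0.0
            self.down_blocks.append(_ResBlock(rng, chans[k], chans[k], spec.elu_alpha, drop))

        # blocks depth+2 .. 2*depth+1: upsampling path
        self.up_trans: list[tuple[_ConvT, _BatchNorm]] = []
        self.up_blocks: list[_ResBlock] = []
        prev = chans[depth]
        for j in range(1, depth + 1):
            uj = chans[depth - j]  # channel count of the matching skip
            self.up_trans.append((_ConvT(rng, prev, uj, 2), _BatchNorm(uj)))
            self.up_blocks.append(_ResBlock(rng, 2 * uj, uj, spec.elu_alpha))
            prev = uj

        # multi-context aggregation: one transposed convolution per
        # downsampling residual block output, back to full resolution
        self.mc_trans: list[tuple[_ConvT, _BatchNorm]] = []
        for k in range(1, depth + 1):
            self.mc_trans.append((_ConvT(rng, chans[k], w, 2 ** k), _BatchNorm(w)))

        # block 2*depth+2: output transition (two convolutions)
        self.out_conv1 = _Conv(rng, w, w, 3, 1, 1)
        self.out_bn = _BatchNorm(w)
        self.out_conv2 = _Conv(rng, w, 1, 1)

    # -- block bookkeeping ---------------------------------------------------

    def blocks(self) -> list[list]:
        """Layer groups by block index (element i = block i+1)."""
        depth = self.spec.depth
        groups: list[list] = [[self.in_conv, self.in_bn]]
        for k in range(depth):
            groups.append([*self.down_trans[k], self.down_blocks[k]])
        for j in range(depth):
            groups.append([*self.up_trans[j], self.up_blocks[j]])
        out_block = [self.out_conv1, self.out_bn, self.out_conv2]
        for ct, bn in self.mc_trans:
            out_block += [ct, bn]
        groups.append(out_block)
        return groups

    @staticmethod
    def _layer_params(layer):
        return layer.params() if hasattr(layer, "params") else []

    def parameters(self, trainable_only: bool = False) -> Iterator[Parameter]:
        for group in self.blocks():
            for layer in group:
                for p in self._layer_params(layer):
                    if not trainable_only or p.requires_grad:
                        yield p

    def batch_norms(self):
        for group in self.blocks():
            for layer in group:
                if isinstance(layer, _BatchNorm):
                    yield layer
                elif isinstance(layer, _ResBlock):
                    yield from layer.batch_norms()

    # -- forward -------------------------------------------------------------

    def forward(
        self, x: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None
    ) -> Tensor:
        """Map an NCHW float batch to an (N, 1, H, W) proximity-map batch."""
        n, c, h, w0 = x.shape
        if c != 3:
            raise ValueError(f"expected 3 input channels, got {c}")
        if h < self.spec.min_input_size or w0 < self.spec.min_input_size:
            raise ValueError(
                f"input {h}x{w0} below the network minimum "
                f"{self.spec.min_input_size}x{self.spec.min_input_size}"
            )
        if train and rng is None and self.spec.dropout_rate > 0:
            raise ValueError("training forward pass with dropout needs an rng")
        a = self.spec.elu_alpha

        t = ag.elu(self.in_bn(self.in_conv(Tensor(x)), train), a)
        skips = [t]  # full-resolution skip is the input transition output
        down_outs = []
        for (conv, bn), block in zip(self.down_trans, self.down_blocks):
            hcur, wcur = t.data.shape[2], t.data.shape[3]
            # 2x2 stride-2 convolution: exact floor(H/2) downsampling
            t = ag.elu(bn(conv(t), train), a)
            t = block(t, train, rng)
            down_outs.append(t)
            skips.append(t)
        skips = skips[:-1]  # the deepest output is the bottleneck itself

        u = t
        for (convt, bn), block, skip in zip(self.up_trans, self.up_blocks, reversed(skips)):
            u = convt(u)
            sh, sw = skip.data.shape[2], skip.data.shape[3]
            u = ag.pad_bottom_right(u, sh - u.data.shape[2], sw - u.data.shape[3])
            u = ag.elu(bn(u, train), a)
            u = block(ag.concat_channels(u, skip), train, rng)

        mc = u
        for (convt, bn), d in zip(self.mc_trans, down_outs):
            z = convt(d)
            z = ag.pad_bottom_right(z, h - z.data.shape[2], w0 - z.data.shape[3])
            mc = ag.add(mc, ag.elu(bn(z, train), a))

        out = ag.elu(self.out_bn(self.out_conv1(mc), train), a)
        out = self.out_conv2(out)
        if self.spec.sigmoid_head:
            out = ag.mul_const(ag.sigmoid(out), self.spec.output_scale)
        return out


def build_network(spec: NetworkSpec, seed: int = 0) -> MicroNet:
    """Construct a network with freshly initialized weights."""
    return MicroNet(spec, seed=seed)


def freeze_blocks(network: MicroNet, k: int) -> MicroNet:
    """Freeze blocks 1..k: their parameters are excluded from gradient
    updates and their normalization statistics are held fixed.  ``k = 0``
    makes every parameter trainable again."""
    groups = network.blocks()
    if not 0 <= k <= len(groups):
        raise ValueError(f"k must be in [0, {len(groups)}], got {k}")
    for i, group in enumerate(groups):
        frozen = i < k
        for layer in group:
            for p in MicroNet._layer_params(layer):
                p.requires_grad = not frozen
            bns = (
                [layer]
                if isinstance(layer, _BatchNorm)
                else layer.batch_norms()
                if isinstance(layer, _ResBlock)
                else []
            )
            for bn in bns:
                bn.frozen = frozen
    network.frozen_upto = k
    return network


def count_parameters(network: MicroNet, trainable_only: bool = False) -> int:
    return int(sum(p.data.size for p in network.parameters(trainable_only=trainable_only)))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(network: MicroNet, path, encoding=None, train_seed=None, extra=None) -> None:
    """Write a versioned checkpoint archive (weights + normalization
    statistics + the architecture and encoding hyperparameters)."""
    arrays = {}
    for i, p in enumerate(network.parameters()):
        arrays[f"param_{i}"] = p.data
    for i, bn in enumerate(network.batch_norms()):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    meta = {
        "version": CHECKPOINT_VERSION,
        "spec": asdict(network.spec),
        "frozen_upto": network.frozen_upto,
        "train_seed": train_seed,
        "extra": extra or {},
    }
    if encoding is not None:
        meta["encoding"] = asdict(encoding)
    arrays["meta"] = np.frombuffer(
        zlib.compress(json.dumps(meta).encode()), dtype=np.uint8
    ).copy()
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path, expected_spec: Optional[NetworkSpec] = None):
    """Rebuild a network from a checkpoint.  Returns (network, meta dict)."""
    with np.load(path) as data:
        meta = json.loads(zlib.decompress(data["meta"].tobytes()).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        spec = NetworkSpec(**meta["spec"])
        if expected_spec is not None and spec != expected_spec:
            raise ValueError(
                f"checkpoint spec {spec} does not match the expected spec {expected_spec}"
            )
        net = MicroNet(spec, seed=0)
        for i, p in enumerate(net.parameters()):
            p.data = data[f"param_{i}"].copy()
        for i, bn in enumerate(net.batch_norms()):
            bn.running_mean = data[f"bn_{i}_mean"].copy()
            bn.running_var = data[f"bn_{i}_var"].copy()
    freeze_blocks(net, meta.get("frozen_upto", 0))
    return net, meta
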