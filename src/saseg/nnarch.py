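"""The segmentation network family: SegUnet, its recurrent variant, the
prior-shape feature extractor (PSFE) and the full shape-aware assembly.

Architecture
------------
The per-slice unit is an encoder-decoder with four resolution steps.
Each encoder level applies two 3x3 convolutions (each followed by batch
normalization and ReLU); levels are separated by 2x2 max pooling.  Each
decoder step upsamples 2x (nearest neighbour), concatenates the
equal-resolution encoder feature map, and applies two 2x2 convolutions
(BN + ReLU; the even kernel keeps spatial size via asymmetric padding).
A final 1x1 convolution with sigmoid produces the per-pixel foreground
probability.

The recurrent variant feeds the previous slice's predicted probability
map as a second input channel, so the unit sees ``[slice, prev_prob]``
while sweeping the volume in ascending z; the map is all zeros at the
first slice.

PSFE is an auxiliary encoder for the voxelized mean mandible shape: one
strided 3x3 conv block (BN, ReLU) followed by two residual blocks, each
built from two depthwise separable convolutions (DSConv) with BN/ReLU, a
1x1 projection skip, and 2x2 max pooling.  A final extra max pooling
brings its output to the encoder-bottleneck resolution (/16).  The prior
features are concatenated onto the bottleneck: the bottleneck's second
3x3 convolution consumes the widened stack and fuses prior and image
features before decoding.

Channel calibration
-------------------
Published descriptions of this architecture state its size but not its
per-stage widths, so the default schedule was calibrated once, by exact
parameter counting, against three size anchors: PSFE = 149,440 trainable
parameters, full shape-aware network = 3.80 M, plain SegUnet = 3.35 M
(hence a prior-path increment of ~0.45 M).  The frozen result is encoder
``(24, 48, 96, 188, 380)`` and PSFE ``(107, 220, 87)``.  The compressing
final PSFE stage gives the auxiliary path a compact 87-channel shape
embedding next to the 380-channel image bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .nn import BatchNorm2d, Conv2d, DSConv2d, Module, ReLU, Tensor, concat

__all__ = [
    "DEFAULT_ENC_CHANNELS",
    "DEFAULT_PSFE_CHANNELS",
    "NetworkSpec",
    "dsconv_param_count",
    "dsconv_mac_ratio",
    "build_psfe",
    "build_segunet",
    "assemble_saseg",
    "count_parameters",
]

#: Frozen calibrated schedules (see module docstring).
DEFAULT_ENC_CHANNELS: tuple[int, ...] = (24, 48, 96, 188, 380)
DEFAULT_PSFE_CHANNELS: tuple[int, ...] = (107, 220, 87)

#: Small schedules for desk-scale training experiments.
SMALL_ENC_CHANNELS: tuple[int, ...] = (8, 16, 24, 32, 48)
SMALL_PSFE_CHANNELS: tuple[int, ...] = (8, 16, 16)

_VARIANTS = ("unet", "segunet", "rsegunet", "saseg")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of one member of the network family.

    ``segunet`` is the plain single-slice unit; ``rsegunet`` adds the
    previous-probability-map input channel; ``saseg`` additionally wires
    in the PSFE prior path.  ``unroll`` is the truncated-backpropagation
    window length used during training.
    """

    variant: str = "saseg"
    enc_channels: tuple[int, ...] = DEFAULT_ENC_CHANNELS
    psfe_channels: tuple[int, ...] = DEFAULT_PSFE_CHANNELS
    unroll: int = 4

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if len(self.enc_channels) != 5 or any(c < 1 for c in self.enc_channels):
            raise ValueError("enc_channels must be 5 positive stage widths")
        if self.has_psfe and (len(self.psfe_channels) != 3 or any(c < 1 for c in self.psfe_channels)):
            raise ValueError("psfe_channels must be 3 positive stage widths")

    @property
    def recurrent(self) -> bool:
        return self.variant in ("rsegunet", "saseg")

    @property
    def has_psfe(self) -> bool:
        return self.variant == "saseg"

    @property
    def in_channels(self) -> int:
        return 2 if self.recurrent else 1

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "enc_channels": list(self.enc_channels),
            "psfe_channels": list(self.psfe_channels),
            "unroll": self.unroll,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            variant=d["variant"],
            enc_channels=tuple(d["enc_channels"]),
            psfe_channels=tuple(d["psfe_channels"]),
            unroll=int(d.get("unroll", 4)),
        )


# ---------------------------------------------------------------------------
# analytic parameter / MAC accounting for DSConv

def dsconv_param_count(c_in: int, c_out: int, with_bias: bool = False) -> int:
    """Parameters of one depthwise separable convolution.

    The depthwise stage convolves each of the ``c_in`` channels with its
    own 3x3 kernel (``9 * c_in`` weights); the pointwise stage fuses the
    channels with a 1x1 kernel (``c_in * c_out`` weights).
    """
    if c_in < 1 or c_out < 1:
        raise ValueError("channel counts must be >= 1")
    n = 9 * c_in + c_in * c_out
    if with_bias:
        n += c_in + c_out
    return n


def dsconv_mac_ratio(c_out: int) -> Fraction:
    """DSConv multiply-accumulate cost relative to a standard 3x3 conv.

    For any feature-map size and input width the ratio is
    ``1/c_out + 1/9``: the depthwise stage costs ``9*c_in*H*W`` and the
    pointwise stage ``c_in*c_out*H*W`` against ``9*c_in*c_out*H*W``.
    """
    if c_out < 1:
        raise ValueError("c_out must be >= 1")
    return Fraction(1, c_out) + Fraction(1, 9)


# ---------------------------------------------------------------------------
# network components

class _EncoderLevel(Module):
    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class _Bottleneck(Module):
    """Deepest encoder level; optionally fuses prior features between its
    two convolutions (the second conv consumes the widened stack)."""

    def __init__(self, c_in: int, c_out: int, prior_ch: int, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out + prior_ch, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.prior_ch = prior_ch

    def forward(self, x: Tensor, prior: Tensor | None = None) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        if self.prior_ch:
            if prior is None:
                raise ValueError("this network requires the mean-shape prior input")
            x = concat([x, prior], axis=1)
        elif prior is not None:
            raise ValueError("prior features supplied to a network without PSFE")
        return self.bn2(self.conv2(x)).relu()


class _DecoderLevel(Module):
    def __init__(self, c_up: int, c_skip: int, c_out: int, rng):
        super().__init__()
        self.conv1 = Conv2d(c_up + c_skip, c_out, 2, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 2, rng=rng)
        self.bn2 = BatchNorm2d(c_out)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = concat([x.upsample2x(), skip], axis=1)
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class _PSFEResBlock(Module):
    """Two DSConvs with BN/ReLU, 1x1 projection skip, then 2x2 max pool."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.ds1 = DSConv2d(c_in, c_out, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.ds2 = DSConv2d(c_out, c_out, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.proj = Conv2d(c_in, c_out, 1, rng=rng) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.ds1(x)).relu()
        h = self.bn2(self.ds2(h))
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu().maxpool2x2()


class PSFE(Module):
    """Prior shape feature extractor.

    Input: a 1-channel mean-shape slice at the network input resolution.
    Output: a feature map at 1/16 resolution (stride-2 conv, one max pool
    per residual block, and one final max pool to match the encoder
    bottleneck's spatial dims).
    """

    def __init__(self, channels: tuple[int, ...] = DEFAULT_PSFE_CHANNELS, rng=None):
        super().__init__()
        if len(channels) != 3:
            raise ValueError(f"PSFE schedule needs 3 stages, got {len(channels)}")
        rng = rng or np.random.default_rng(0)
        c1, c2, c3 = channels
        self.conv = Conv2d(1, c1, 3, stride=2, rng=rng)
        self.bn = BatchNorm2d(c1)
        self.block1 = _PSFEResBlock(c1, c2, rng)
        self.block2 = _PSFEResBlock(c2, c3, rng)
        self.out_channels = c3

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.conv(x)).relu()
        x = self.block1(x)
        x = self.block2(x)
        return x.maxpool2x2()  # align to the /16 bottleneck resolution


class SegUnetUnit(Module):
    """One encoder-decoder slice unit, optionally with a prior-feature
    fusion slot at the bottleneck."""

    def __init__(self, spec: NetworkSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        C = spec.enc_channels
        prior_ch = spec.psfe_channels[-1] if spec.has_psfe else 0
        self.enc1 = _EncoderLevel(spec.in_channels, C[0], rng)
        self.enc2 = _EncoderLevel(C[0], C[1], rng)
        self.enc3 = _EncoderLevel(C[1], C[2], rng)
        self.enc4 = _EncoderLevel(C[2], C[3], rng)
        self.bottleneck = _Bottleneck(C[3], C[4], prior_ch, rng)
        self.dec4 = _DecoderLevel(C[4], C[3], C[3], rng)
        self.dec3 = _DecoderLevel(C[3], C[2], C[2], rng)
        self.dec2 = _DecoderLevel(C[2], C[1], C[1], rng)
        self.dec1 = _DecoderLevel(C[1], C[0], C[0], rng)
        self.head = Conv2d(C[0], 1, 1, bias=True, rng=rng)
        self.spec = spec

    def forward(self, x: Tensor, prior: Tensor | None = None) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims must be divisible by 16, got {h}x{w}")
        e1 = self.enc1(x)
        e2 = self.enc2(e1.maxpool2x2())
        e3 = self.enc3(e2.maxpool2x2())
        e4 = self.enc4(e3.maxpool2x2())
        b = self.bottleneck(e4.maxpool2x2(), prior)
        d = self.dec4(b, e4)
        d = self.dec3(d, e3)
        d = self.dec2(d, e2)
        d = self.dec1(d, e1)
        return self.head(d).sigmoid()


class SASeg(Module):
    """Recurrent assembly: shared-weight slice unit swept over a stack in
    ascending z, fed ``[slice, previous probability map]``, with PSFE
    prior features injected at the bottleneck when present."""

    def __init__(self, spec: NetworkSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.psfe = PSFE(spec.psfe_channels, rng=rng) if spec.has_psfe else None
        self.unit = SegUnetUnit(spec, rng=rng)

    def forward_slice(self, x: Tensor, prev_prob: Tensor | None, prior_slice: Tensor | None) -> Tensor:
        """One recurrence step.  ``prev_prob=None`` means the zero map
        (start of sweep); ``prior_slice`` is the mean-shape slice for the
        current relative depth (required iff the spec has PSFE)."""
        if self.spec.recurrent:
            if prev_prob is None:
                prev_prob = Tensor(np.zeros_like(x.data))
            x = concat([x, prev_prob], axis=1)
        prior_feat = None
        if self.psfe is not None:
            if prior_slice is None:
                raise ValueError("SASeg forward requires the mean-shape prior slice")
            prior_feat = self.psfe(prior_slice)
        return self.unit(x, prior_feat)

    def forward(self, stack: np.ndarray, prior_stack: np.ndarray | None = None) -> list[Tensor]:
        """Unroll over a (N, U, 1, H, W) window; returns U probability maps.

        Gradient flows through the recurrence within the window
        (truncated backpropagation through the unroll)."""
        u = stack.shape[1]
        probs: list[Tensor] = []
        prev: Tensor | None = None
        for t in range(u):
            x = Tensor(stack[:, t])
            prior = Tensor(prior_stack[:, t]) if prior_stack is not None else None
            p = self.forward_slice(x, prev, prior)
            probs.append(p)
            prev = p
        return probs


# ---------------------------------------------------------------------------
# builders + counting

def build_psfe(channels: tuple[int, ...] = DEFAULT_PSFE_CHANNELS, seed: int = 0) -> PSFE:
    return PSFE(tuple(channels), rng=np.random.default_rng(seed))


def build_segunet(spec: NetworkSpec | None = None, seed: int = 0) -> SegUnetUnit:
    spec = spec or NetworkSpec(variant="segunet")
    return SegUnetUnit(spec, rng=np.random.default_rng(seed))


def assemble_saseg(spec: NetworkSpec | None = None, seed: int = 0) -> SASeg:
    spec = spec or NetworkSpec(variant="saseg")
    return SASeg(spec, rng=np.random.default_rng(seed))


def count_parameters(network: Module) -> int:
    """Exact number of trainable scalars (conv kernels, biases, BN affine)."""
    return int(sum(p.size for p in network.parameters()))
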