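"""Spatial-attention CSR-U-Net for dural hemorrhage segmentation + classification.

The model is a U-shaped encoder-decoder.  Each encoder stage is a double
Conv-BN-ReLU whose output is recalibrated by a CSR block (convolution +
squeeze-and-excitation channel gating + a direct additive skip); separate
CSR blocks sit on the skip paths to the decoder.  Every decoder stage
upsamples (2x2 transposed convolution, channels halved), concatenates the
CSR-processed encoder features of the matching scale, gates the fused map
with a spatial-attention module (channel-wise max/mean maps -> 7x7 conv ->
sigmoid), and applies a double convolution.  Two heads: a 1x1-conv sigmoid
segmentation head at full resolution, and a classification branch from the
bottleneck (Conv-BN-LeakyReLU, a convolution, global average pooling and a
fully connected layer over the two dural classes, SDH vs EDH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autograd as ag
from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Linear, Module, Tensor


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``base_filters`` sets the first-encoder width; deeper stages double it
    (64 -> 128/256/512 with a 1024-channel bottleneck at the default), so a
    smaller base scales the whole network down uniformly.
    """

    in_channels: int = 1
    base_filters: int = 64
    se_reduction: int = 16
    leaky_slope: float = 0.001
    attention_kernel: int = 7
    num_classes: int = 2
    seg_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.base_filters < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.attention_kernel % 2 == 0:
            raise ValueError("attention_kernel must be odd")

    @property
    def encoder_filters(self):
        b = self.base_filters
        return (b, 2 * b, 4 * b, 8 * b)

    @property
    def bottleneck_filters(self):
        return 16 * self.base_filters


class ConvBNReLU(Module):
    """3x3 stride-1 convolution -> batch norm -> ReLU (spatial size preserved)."""

    def __init__(self, in_ch, out_ch, rng, kernel=3):
        super().__init__()
        if out_ch <= 0:
            raise ValueError("filters must be positive")
        self.conv = Conv2d(in_ch, out_ch, kernel=kernel, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return ag.relu(self.bn(self.conv(x)))


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration.

    Global average pool -> bottleneck FC (C -> C/r) with ReLU -> expand FC
    (C/r -> C) with sigmoid -> per-channel gates in (0,1) multiplying the
    input channel-wise.
    """

    def __init__(self, channels, reduction=16, rng=None):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be >= 1")
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.channels = channels

    def gates(self, x):
        b = x.shape[0]
        squeezed = ag.reshape(ag.tmean(x, axis=(2, 3)), (b, self.channels))
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(squeezed))))

    def forward(self, x):
        g = self.gates(x)
        return x * ag.reshape(g, (x.shape[0], self.channels, 1, 1))


class ResidualUnit(Module):
    """Full pre-activation residual unit.

    Residual branch: BN -> ReLU -> conv -> BN -> ReLU -> conv.  Shortcut is
    the identity when channel counts match, otherwise a 1x1 convolution
    followed by batch norm to raise the dimension.
    """

    def __init__(self, in_ch, out_ch=None, rng=None):
        super().__init__()
        out_ch = out_ch or in_ch
        self.bn1 = BatchNorm2d(in_ch)
        self.conv1 = Conv2d(in_ch, out_ch, kernel=3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, kernel=3, rng=rng)
        if in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, kernel=1, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x):
        h = self.conv1(ag.relu(self.bn1(x)))
        h = self.conv2(ag.relu(self.bn2(h)))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return shortcut + h


class CSRBlock(Module):
    """Convolution + squeeze-excitation + residual composite block.

    Conv-BN-ReLU, SE recalibration of its output, plus the direct additive
    skip from block input to output (1x1 projection when channels differ).
    """

    def __init__(self, in_ch, out_ch, se_reduction=16, rng=None):
        super().__init__()
        self.cbr = ConvBNReLU(in_ch, out_ch, rng)
        self.se = SEBlock(out_ch, reduction=se_reduction, rng=rng)
        self.proj = Conv2d(in_ch, out_ch, kernel=1, rng=rng) if in_ch != out_ch else None

    def forward(self, x):
        y = self.se(self.cbr(x))
        skip = x if self.proj is None else self.proj(x)
        return skip + y


class SpatialAttention(Module):
    """Per-pixel gate from channel-wise max and mean maps.

    The two (B,1,H,W) descriptor maps are concatenated, passed through a
    wide (default 7x7) convolution to one channel and a sigmoid, and the
    resulting map multiplies the input, broadcast over channels.
    """

    def __init__(self, kernel=7, rng=None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel=kernel, rng=rng)

    def attention_map(self, x):
        mx = ag.tmax(x, axis=1, keepdims=True)
        avg = ag.tmean(x, axis=1, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([mx, avg], axis=1)))

    def forward(self, x):
        return x * self.attention_map(x)


class _DoubleConv(Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.c1 = ConvBNReLU(in_ch, out_ch, rng)
        self.c2 = ConvBNReLU(out_ch, out_ch, rng)

    def forward(self, x):
        return self.c2(self.c1(x))


class CSRUNet(Module):
    """The full spatial-attention CSR-U-Net with segmentation and class heads."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.encoder_filters
        r = cfg.se_reduction

        enc, skips = [], []
        in_ch = cfg.in_channels
        for fi in f:
            enc.append(_DoubleConv(in_ch, fi, rng))
            skips.append(CSRBlock(fi, fi, se_reduction=r, rng=rng))
            in_ch = fi
        self.encoders = enc
        self.skip_csr = skips

        fb = cfg.bottleneck_filters
        self.bottleneck = _DoubleConv(f[-1], fb, rng)
        self.bottleneck_res = ResidualUnit(fb, rng=rng)

        ups, atts, decs = [], [], []
        ch = fb
        for fi in reversed(f):
            ups.append(ConvTranspose2x2(ch, fi, rng=rng))
            atts.append(SpatialAttention(kernel=cfg.attention_kernel, rng=rng))
            decs.append(_DoubleConv(2 * fi, fi, rng))
            ch = fi
        self.ups = ups
        self.attentions = atts
        self.decoders = decs

        self.seg_head = Conv2d(f[0], cfg.seg_channels, kernel=1, rng=rng)

        # classification branch: CBL -> conv -> global pool -> FC
        self.cls_conv1 = Conv2d(fb, f[-1], kernel=3, rng=rng)
        self.cls_bn1 = BatchNorm2d(f[-1])
        self.cls_conv2 = Conv2d(f[-1], f[-1], kernel=3, rng=rng)
        self.cls_fc = Linear(f[-1], cfg.num_classes, rng=rng)

    def forward(self, x):
        """Run the network.

        Parameters
        ----------
        x : Tensor or ndarray, shape (B, in_channels, H, W)
            H and W must be divisible by 16 (four pooling steps).

        Returns
        -------
        seg : Tensor, shape (B, 1, H, W) of per-pixel lesion probabilities.
        logits : Tensor, shape (B, num_classes) of unnormalized class scores.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial size ({h}, {w}) must be divisible by 16")

        feats = []
        cur = x
        for enc, skip in zip(self.encoders, self.skip_csr):
            cur = enc(cur)
            feats.append(skip(cur))
            cur = ag.maxpool2x2(cur)

        cur = self.bottleneck_res(self.bottleneck(cur))
        bottleneck = cur

        for up, att, dec, feat in zip(self.ups, self.attentions, self.decoders,
                                      reversed(feats)):
            cur = up(cur)
            cur = att(ag.concat([feat, cur], axis=1))
            cur = dec(cur)

        seg = ag.sigmoid(self.seg_head(cur))

        c = ag.leaky_relu(self.cls_bn1(self.cls_conv1(bottleneck)),
                          slope=self.config.leaky_slope)
        c = self.cls_conv2(c)
        pooled = ag.reshape(ag.tmean(c, axis=(2, 3)), (x.shape[0], -1))
        logits = self.cls_fc(pooled)
        return seg, logits

    def predict(self, images):
        """Eval-mode forward on a (B, H, W) or (B, 1, H, W) float array.

        Returns (seg probability maps (B, H, W), class probabilities (B, K)).
        """
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        was_training = self.training
        self.eval()
        try:
            seg, logits = self.forward(Tensor(arr))
        finally:
            if was_training:
                self.train()
        return seg.data[:, 0], softmax(logits.data)


def leaky_relu(q, slope=0.001):
    """Leaky rectifier: q for q >= 0, slope*q otherwise (elementwise)."""
    if slope < 0:
        raise ValueError("slope must be >= 0")
    q = np.asarray(q)
    return np.where(q >= 0, q, slope * q)


def softmax(logits, axis=-1):
    """Numerically stable softmax (max-subtracted exponentials, normalized)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_model(config: ModelConfig | None = None) -> CSRUNet:
    """Construct a seeded CSRUNet from a :class:`ModelConfig`."""
    return CSRUNet(config)
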