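"""Multi-scale hypercolumn processing.

Each tapped encoder map Y is (1) reduced to a quarter of its channels by a
1×1 convolution, (2) passed through four parallel dilated convolutions —
(1×1, d=1), (3×3, d=1), (3×3, d=2), (3×3, d=3) — whose outputs are
concatenated back to the original width, aggregated by a 1×1 convolution
and residually added to Y, (3) re-weighted per channel by a sigmoid gate
driven by global average pooling, and (4) projected to the decoder width
by a stride-2 transposed convolution followed by a 3×3 convolution,
doubling the spatial resolution.  Batch normalisation follows every
convolution except the attention gate and carries no activation before
the concatenation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import MhpmConfig
from .nn import Tensor
from .nn.functional import global_avg_pool


class ChannelAttention(nn.Module):
    """Gate g = sigmoid(Conv1x1(GAP(h))); returns h * (1 + g).

    The gate lies in (0, 1) per channel, so every output entry lies
    strictly between h and 2h.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.gate = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, h: Tensor) -> Tensor:
        g = self.gate(global_avg_pool(h)).sigmoid()
        return h * g + h


class DilatedBranches(nn.Module):
    """Four channel-preserving dilated branches, concatenation, aggregation,
    and the residual add of the un-reduced input."""

    def __init__(self, cfg: MhpmConfig, rng: np.random.Generator):
        super().__init__()
        c4 = cfg.in_channels // 4
        branches = []
        for k, d in zip(cfg.kernels, cfg.dilations):
            pad = d * (k - 1) // 2          # zero padding preserving spatial shape
            branches.append(nn.Conv2d(c4, c4, k, rng, padding=pad, dilation=d))
        self.branches = nn.ModuleList(branches)
        self.branch_bns = nn.ModuleList(nn.BatchNorm2d(c4) for _ in branches)
        self.aggregate = nn.Conv2d(cfg.in_channels, cfg.in_channels, 1, rng)
        self.agg_bn = nn.BatchNorm2d(cfg.in_channels)

    def forward(self, h_bar: Tensor, y: Tensor) -> Tensor:
        outs = [bn(conv(h_bar)) for conv, bn in zip(self.branches, self.branch_bns)]
        shapes = {o.shape for o in outs}
        if len(shapes) > 1:
            raise RuntimeError(f"branch outputs drifted in shape: {shapes}")
        h = nn.concat(outs, axis=1)
        return y + self.agg_bn(self.aggregate(h))


class Mhpm(nn.Module):
    def __init__(self, cfg: MhpmConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, c4 = cfg.in_channels, cfg.in_channels // 4
        self.reduce = nn.Conv2d(c, c4, 1, rng)
        self.reduce_bn = nn.BatchNorm2d(c4)
        self.dilated = DilatedBranches(cfg, rng)
        self.attention = ChannelAttention(c, rng)
        self.deconv = nn.ConvTranspose2d(c, cfg.out_channels, cfg.deconv_stride, rng,
                                         stride=cfg.deconv_stride)
        self.refine = nn.Conv2d(cfg.out_channels, cfg.out_channels, 3, rng, padding=1)
        self.refine_bn = nn.BatchNorm2d(cfg.out_channels)

    def reduce_channels(self, y: Tensor) -> Tensor:
        if y.shape[1] % 4:
            raise ValueError(f"channel count {y.shape[1]} not divisible by 4")
        return self.reduce_bn(self.reduce(y))

    def hypermap(self, h_att: Tensor) -> Tensor:
        """Transposed-conv upsampling (×stride) then 3×3 refinement + BN."""
        return self.refine_bn(self.refine(self.deconv(h_att)))

    def forward(self, y: Tensor) -> Tensor:
        h_bar = self.reduce_channels(y)
        h = self.dilated(h_bar, y)
        return self.hypermap(self.attention(h))
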