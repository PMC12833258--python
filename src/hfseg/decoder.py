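"""Progressive hierarchical fusion decoder.

Stages run deepest-tap-first.  The first stage refines a 1×1-projected
hypermap of the deepest tap; every later stage concatenates its tap's
hypermap with the previous stage's output, compresses with a 1×1
convolution and refines through the Hierarchical Fusion Module (HFM).
The HFM fuses three parallel views of its input d:

* global   — d gated by sigmoid(Conv1x1(GAP(d))) plus d,
* regional — d split into k channel groups, each gated the same way by
  its own 1×1 convolution and re-concatenated in order,
* local    — a per-pixel (1×1) linear projection,

joined by a final 1×1 convolution.  Each stage carries a 1×1-conv
classification head whose logits are bilinearly upsampled to image
resolution; a last 1×1 convolution fuses the four per-stage logit maps
into the final prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import HfmConfig
from .nn import Tensor
from .nn.functional import global_avg_pool, upsample_bilinear


def _gate(x: Tensor, conv: nn.Conv2d) -> Tensor:
    return x * conv(global_avg_pool(x)).sigmoid() + x


class Hfm(nn.Module):
    """Hierarchical fusion: global gate + k regional group gates + local MLP."""

    def __init__(self, cfg: HfmConfig, rng: np.random.Generator):
        super().__init__()
        c, k = cfg.channels, cfg.groups
        self.groups = k
        self.global_gate = nn.Conv2d(c, c, 1, rng)
        self.region_gates = nn.ModuleList(nn.Conv2d(c // k, c // k, 1, rng)
                                          for _ in range(k))
        self.local = nn.Conv2d(c, c, 1, rng)     # per-pixel linear projection
        self.fuse = nn.Conv2d(3 * c, c, 1, rng)

    def forward(self, d: Tensor) -> Tensor:
        c = d.shape[1]
        if c % self.groups:
            raise ValueError(f"{c} channels not divisible by {self.groups} groups")
        f_global = _gate(d, self.global_gate)
        gs = c // self.groups
        regions = [_gate(d[:, i * gs:(i + 1) * gs], conv)
                   for i, conv in enumerate(self.region_gates)]
        f_region = nn.concat(regions, axis=1)
        f_local = self.local(d)
        return self.fuse(nn.concat([f_global, f_region, f_local], axis=1))


class ConvRefine(nn.Module):
    """Bottleneck 3×3 refinement block used when the HFM is ablated away."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        mid = max(channels // 4, 1)
        self.conv1 = nn.Conv2d(channels, mid, 3, rng, padding=1)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, channels, 1, rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, d: Tensor) -> Tensor:
        return self.bn2(self.conv2(self.bn1(self.conv1(d)).relu()))


class FuseStage(nn.Module):
    """Concatenate a hypermap with the previous stage, compress, refine."""

    def __init__(self, in_ch: int, channels: int, refine: nn.Module,
                 rng: np.random.Generator, first: bool = False):
        super().__init__()
        self.compress = nn.Conv2d(in_ch if first else in_ch + channels,
                                  channels, 1, rng)
        self.refine = refine
        self.first = first

    def forward(self, m: Tensor, f_prev: Tensor | None) -> Tensor:
        if self.first:
            return self.refine(self.compress(m))
        if f_prev is None:
            raise ValueError("non-first stage needs the previous stage's output")
        if m.shape[2:] != f_prev.shape[2:]:
            raise ValueError(
                f"hypermap {m.shape[2:]} and previous stage {f_prev.shape[2:]} "
                "disagree in spatial shape; fix the resolution schedule "
                "(stages never resample)")
        return self.refine(self.compress(nn.concat([m, f_prev], axis=1)))


@dataclass
class StageOutputs:
    """Per-stage decoder features and logits plus the fused final logits.

    ``stage_features``/``stage_logits`` are ordered deepest tap first;
    all logit maps share the class count and image resolution.
    """
    stage_features: list[Tensor]
    stage_logits: list[Tensor]
    fused_logits: Tensor


class Phfd(nn.Module):
    """The full pyramid over the tapped encoder maps."""

    def __init__(self, tap_depths, in_channels: int, hfm_cfg: HfmConfig,
                 num_classes: int, rng: np.random.Generator, use_hfm: bool = True):
        super().__init__()
        self.tap_depths = tuple(tap_depths)
        c = hfm_cfg.channels
        n = len(self.tap_depths)

        def refine():
            return Hfm(hfm_cfg, rng) if use_hfm else ConvRefine(c, rng)

        self.stages = nn.ModuleList(
            FuseStage(in_channels, c, refine(), rng, first=(i == 0)) for i in range(n))
        # classification heads start near zero so initial logits are small
        # and the cross-entropy starts close to its uniform-prediction value
        self.heads = nn.ModuleList(nn.Conv2d(c, num_classes, 1, rng) for _ in range(n))
        self.final_fuse = nn.Conv2d(n * num_classes, num_classes, 1, rng)
        for head in list(self.heads) + [self.final_fuse]:
            head.weight.data *= 0.01

    def forward(self, hypermaps: dict[int, Tensor],
                out_size: tuple[int, int]) -> StageOutputs:
        return self.decode(hypermaps, out_size)

    def decode(self, hypermaps: dict[int, Tensor],
               out_size: tuple[int, int]) -> StageOutputs:
        """Run stages deepest-tap-first and fuse the per-stage predictions."""
        missing = set(self.tap_depths) - set(hypermaps)
        if missing:
            raise ValueError(f"missing hypermaps for taps {sorted(missing)}")
        order = sorted(self.tap_depths, reverse=True)
        feats: list[Tensor] = []
        logits: list[Tensor] = []
        f_prev: Tensor | None = None
        for stage, head, depth in zip(self.stages, self.heads, order):
            f_prev = stage(hypermaps[depth], f_prev)
            feats.append(f_prev)
            logits.append(upsample_bilinear(head(f_prev), out_size))
        fused = self.fuse_final(logits)
        return StageOutputs(stage_features=feats, stage_logits=logits,
                            fused_logits=fused)

    def fuse_final(self, stage_logits: list[Tensor]) -> Tensor:
        sizes = {tuple(l.shape[2:]) for l in stage_logits}
        if len(sizes) > 1:
            raise ValueError(f"stage logits disagree in resolution: {sizes}")
        return self.final_fuse(nn.concat(stage_logits, axis=1))


def predict(final_logits: Tensor | np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the class axis; ties go to the lowest index."""
    data = final_logits.data if isinstance(final_logits, Tensor) else final_logits
    return np.argmax(data, axis=-3)
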