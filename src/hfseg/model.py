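"""End-to-end segmentation model and the ablation-variant builder.

The full model chains the frozen ViT encoder (LoRA + adapters), one
multi-scale hypercolumn processor per tapped depth, and the hierarchical
fusion pyramid decoder with per-stage prediction heads.  The variant
builder reconstructs the ablation ladder: from a frozen backbone with a
bare 1×1-conv head up to the full architecture, switching one component
on per rung.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import nn
from .config import AblationConfig, ModelConfig, _to_plain
from .decoder import Phfd, StageOutputs
from .encoder import ViTEncoder
from .mhpm import Mhpm
from .nn import Tensor
from .nn.functional import upsample_bilinear


class TapProjection(nn.Module):
    """Plain 1×1 projection of a tap to decoder width (MHPM ablated away)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, y: Tensor) -> Tensor:
        return self.proj(y)


class SegModel(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = ViTEncoder(cfg.encoder, rng)
        taps = cfg.encoder.tap_depths
        if cfg.use_decoder:
            if cfg.use_mhpm:
                self.mhpms = nn.ModuleList(Mhpm(cfg.mhpm, rng) for _ in taps)
            else:
                self.mhpms = nn.ModuleList(
                    TapProjection(cfg.encoder.embed_dim, cfg.hfm.channels, rng)
                    for _ in taps)
            hyper_ch = cfg.mhpm.out_channels if cfg.use_mhpm else cfg.hfm.channels
            self.decoder = Phfd(taps, hyper_ch, cfg.hfm, cfg.num_classes, rng,
                                use_hfm=cfg.use_hfm)
        else:
            # minimal head: logits straight from the deepest tap
            self.head = nn.Conv2d(cfg.encoder.embed_dim, cfg.num_classes, 1, rng)
            self.head.weight.data *= 0.01

    def forward(self, images: np.ndarray | Tensor) -> StageOutputs:
        if not isinstance(images, Tensor):
            images = Tensor(images)
        out_size = (images.shape[2], images.shape[3])
        taps = self.encoder.encode(images)
        if not self.cfg.use_decoder:
            deepest = taps[max(taps.depths)]
            logits = upsample_bilinear(self.head(deepest), out_size)
            return StageOutputs(stage_features=[], stage_logits=[],
                                fused_logits=logits)
        hypermaps = {d: m(taps[d]) for d, m in zip(taps.depths, self.mhpms)}
        return self.decoder.decode(hypermaps, out_size)


def build_model(cfg: ModelConfig, seed: int = 0) -> SegModel:
    return SegModel(cfg, np.random.default_rng(seed))


def build_variant(ablation: AblationConfig, cfg: ModelConfig,
                  seed: int = 0) -> SegModel:
    """Instantiate one rung of the ablation ladder from a base config."""
    enc = replace(cfg.encoder, use_lora=ablation.lora, use_adapter=ablation.adapter)
    variant_cfg = replace(cfg, encoder=enc, use_decoder=ablation.decoder,
                          use_hfm=ablation.hfm, use_mhpm=ablation.mhpm)
    return build_model(variant_cfg, seed=seed)


# -- parameter accounting ---------------------------------------------------

@dataclasses.dataclass
class ParamReport:
    per_module: dict[str, tuple[int, int]]     # name -> (frozen, trainable)

    @property
    def frozen(self) -> int:
        return sum(f for f, _ in self.per_module.values())

    @property
    def trainable(self) -> int:
        return sum(t for _, t in self.per_module.values())

    @property
    def total(self) -> int:
        return self.frozen + self.trainable

    def to_text(self) -> str:
        lines = ["module\tfrozen\ttrainable"]
        for name, (f, t) in self.per_module.items():
            lines.append(f"{name}\t{f}\t{t}")
        lines.append(f"total\t{self.frozen}\t{self.trainable}")
        lines.append(f"total_millions\t{self.frozen / 1e6:.2f}\t"
                     f"{self.trainable / 1e6:.2f}")
        return "\n".join(lines)


def count_params(model: nn.Module) -> ParamReport:
    """Exhaustive walk over parameter arrays, split frozen vs trainable."""
    per: dict[str, list[int]] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        slot = per.setdefault(top, [0, 0])
        slot[1 if p.requires_grad else 0] += p.size
    return ParamReport({k: (f, t) for k, (f, t) in per.items()})


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: SegModel, path: str | Path):
    """Single archive: weight arrays keyed by module path + config snapshot."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(_to_plain(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def _config_from_plain(d: dict) -> ModelConfig:
    from .config import BlockConfig, HfmConfig, MhpmConfig, _tupled
    return ModelConfig(
        encoder=_tupled(BlockConfig, d["encoder"]),
        mhpm=_tupled(MhpmConfig, d["mhpm"]),
        hfm=_tupled(HfmConfig, d["hfm"]),
        **{k: v for k, v in d.items() if k not in ("encoder", "mhpm", "hfm")})


def load_checkpoint(path: str | Path) -> SegModel:
    """Rebuild the model from the stored config and verify every shape."""
    archive = np.load(path)
    cfg = _config_from_plain(json.loads(bytes(archive["__config__"]).decode()))
    model = build_model(cfg, seed=0)
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
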