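"""Deep-supervision segmentation loss.

Every decoder stage's logits and the fused logits are supervised with a
per-pixel cross-entropy against the integer label mask.  For two classes
this is exactly the sigmoid binary cross-entropy of the logit margin; for
more classes it is the softmax generalisation.  Losses are means over
pixels, so values are comparable across image resolutions.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .decoder import StageOutputs
from .nn import Tensor
from .nn.functional import softmax_cross_entropy


def pixel_ce_loss(logits: Tensor, gt: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy; accepts (C,H,W) or (N,C,H,W) logits."""
    single = logits.ndim == 3
    if single:
        logits = logits.reshape(1, *logits.shape)
        gt = np.asarray(gt)[None]
    if logits.shape[0] != np.asarray(gt).shape[0] or logits.shape[2:] != np.asarray(gt).shape[1:]:
        raise ValueError(
            f"logits {logits.shape} and labels {np.asarray(gt).shape} disagree")
    return softmax_cross_entropy(logits, gt)


def deep_supervision_loss(stages: StageOutputs, gt: np.ndarray,
                          weights: Sequence[float] | None = None) -> Tensor:
    """Weighted sum of per-stage losses plus the fused-output loss.

    `weights` has one entry per decoder stage followed by one for the
    fused logits; the default weighs them all equally (1.0 each).
    Setting all stage weights to zero recovers single-point supervision
    on the fused output alone.
    """
    maps = list(stages.stage_logits) + [stages.fused_logits]
    if weights is None:
        weights = [1.0] * len(maps)
    if len(weights) != len(maps):
        raise ValueError(
            f"expected {len(maps)} loss weights (stages + fused), got {len(weights)}")
    total: Tensor | None = None
    for w, logit in zip(weights, maps):
        if w == 0.0:
            continue
        term = pixel_ce_loss(logit, gt) * float(w)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("all loss weights are zero")
    return total
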