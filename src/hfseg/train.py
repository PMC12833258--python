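"""Training and evaluation loops.

AdamW over the trainable parameters only, with the learning rate dropped
by a factor of 10 every 20 epochs (defaults: lr 1e-3, weight decay 0.1,
50 epochs, batch 16).  One master seed fans out through
``numpy.random.SeedSequence.spawn`` into independent streams for data
order and augmentation, so runs are exactly reproducible.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np

from .config import TrainConfig
from .losses import deep_supervision_loss, pixel_ce_loss
from .metrics import MetricsReport, average_reports, dice_iou
from .model import SegModel
from .nn import AdamW, step_decay_lr
from .phantoms import PhantomSample, augment, to_model_input


@dataclass
class EpochLog:
    epoch: int
    lr: float
    loss: float
    steps: int


def _batch_arrays(samples: list[PhantomSample]):
    images = np.stack([to_model_input(s) for s in samples])
    masks = np.stack([s.mask.astype(np.int64) for s in samples])
    return images, masks


def _loss_for(model: SegModel, out, masks, multi_scale: bool):
    if out.stage_logits and multi_scale:
        return deep_supervision_loss(out, masks)
    return pixel_ce_loss(out.fused_logits, masks)


def train(model: SegModel, train_cfg: TrainConfig,
          samples: list[PhantomSample], log_stream=None) -> list[EpochLog]:
    """Optimise the trainable parameters; returns the per-epoch log."""
    if not samples:
        raise ValueError("training dataset is empty")
    ss = np.random.SeedSequence(train_cfg.seed)
    order_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    params = model.trainable_parameters()
    opt = AdamW(params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    model.train()
    logs: list[EpochLog] = []
    total_steps = 0
    for epoch in range(train_cfg.epochs):
        lr = step_decay_lr(train_cfg.lr, epoch, train_cfg.lr_drop_every,
                           train_cfg.lr_drop_factor)
        opt.lr = lr
        idx = order_rng.permutation(len(samples))
        losses = []
        for start in range(0, len(idx), train_cfg.batch_size):
            if train_cfg.max_steps is not None and total_steps >= train_cfg.max_steps:
                break
            batch = [samples[i] for i in idx[start:start + train_cfg.batch_size]]
            if train_cfg.augment:
                batch = [augment(s, int(aug_rng.integers(2 ** 31))) for s in batch]
            images, masks = _batch_arrays(batch)
            out = model(images)
            loss = _loss_for(model, out, masks, train_cfg.multi_scale_loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {total_steps}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            total_steps += 1
        log = EpochLog(epoch=epoch, lr=lr,
                       loss=float(np.mean(losses)) if losses else float("nan"),
                       steps=total_steps)
        logs.append(log)
        if log_stream is not None:
            print(f"epoch={log.epoch} lr={log.lr:.6g} loss={log.loss:.6f} "
                  f"steps={log.steps}", file=log_stream, flush=True)
        if train_cfg.max_steps is not None and total_steps >= train_cfg.max_steps:
            break
    return logs


def evaluate(model: SegModel, samples: list[PhantomSample],
             include_background: bool = False,
             batch_size: int = 8) -> tuple[MetricsReport, list[MetricsReport]]:
    """Per-image Dice/IoU, macro-averaged over the evaluation set."""
    if not samples:
        raise ValueError("evaluation dataset is empty")
    model.eval()
    num_classes = model.cfg.num_classes
    if max(int(s.mask.max()) for s in samples) >= num_classes:
        raise ValueError("dataset contains labels beyond the model's class count")
    reports = []
    for start in range(0, len(samples), batch_size):
        batch = samples[start:start + batch_size]
        images, masks = _batch_arrays(batch)
        out = model(images)
        preds = np.argmax(out.fused_logits.data, axis=1)
        for pred, gt in zip(preds, masks):
            reports.append(dice_iou(pred, gt, num_classes=num_classes,
                                    include_background=include_background))
    return average_reports(reports), reports


def log_to_stderr(msg: str):
    print(msg, file=sys.stderr, flush=True)
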