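"""Train the tiny preset on a handful of phantoms and evaluate it.

This mirrors the library's overfit-recovery check: with a frozen
backbone and only the low-rank/adapter/decoder parameters trainable, the
model should memorise eight 64x64 phantoms within 200 optimisation
steps. On one CPU core this takes about two minutes.

Run:  python examples/02_train_and_evaluate.py
"""

from pathlib import Path

from hfseg import (PhantomSpec, TrainConfig, build_model, count_params,
                   evaluate, generate_phantom, save_checkpoint,
                   tiny_model_config, train)

phantoms = [generate_phantom(PhantomSpec(size=64), 100 + i) for i in range(8)]

model = build_model(tiny_model_config(), seed=0)
print(count_params(model).to_text())

# A constant learning rate suits a 200-step memorisation run; the
# default 10x drop every 20 epochs is meant for long schedules.
cfg = TrainConfig(epochs=200, batch_size=8, seed=0, augment=False,
                  max_steps=200, lr_drop_every=200)
logs = train(model, cfg, phantoms)
print(f"loss: {logs[0].loss:.3f} -> {logs[-1].loss:.3f} "
      f"over {logs[-1].steps} steps")

report, per_image = evaluate(model, phantoms)
print(report.to_text())
print(f"mDice {report.mdice:.3f}  mIoU {report.miou:.3f}")

out = Path("scratch/example_checkpoint.npz")
out.parent.mkdir(parents=True, exist_ok=True)
save_checkpoint(model, out)
print(f"checkpoint written to {out}")
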