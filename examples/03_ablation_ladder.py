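"""Walk the component ladder A-G and compare parameter budgets.

Each preset enables one more component on top of the previous one:

    A  frozen encoder + 1x1 head
    B  + low-rank (LoRA) updates on the Q/V projections
    C  + bottleneck adapters after each MLP
    D  + hierarchical fusion decoder (with a plain conv bottleneck)
    E  + hierarchical fusion module (HFM) gating inside the decoder
    F  + multi-scale hypercolumn processing (MHPM) on each tap
    G  + deep supervision at every decoder stage (no new parameters)

This script only builds the variants and prints the trainable-parameter
ladder; training each rung is a matter of passing the variant model to
``hfseg.train`` (see example 02), or running ``hfseg ablate`` from the
command line.

Run:  python examples/03_ablation_ladder.py
"""

from hfseg import (AblationConfig, build_variant, count_params,
                   tiny_model_config)

cfg = tiny_model_config()
print(f"{'preset':<8}{'trainable':>12}{'frozen':>12}{'total':>12}")
for name in "ABCDEFG":
    model = build_variant(AblationConfig.preset(name), cfg, seed=0)
    rep = count_params(model)
    print(f"{name:<8}{rep.trainable:>12}{rep.frozen:>12}{rep.total:>12}")
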