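"""Encoder behaviour: LoRA algebra, attention, adapters, taps, freezing."""

import numpy as np
import pytest

from hfseg import BlockConfig, ViTEncoder, set_freeze_policy
from hfseg.encoder import Adapter, EncoderBlock, LoraLinear
from hfseg.nn import AdamW, Tensor

from oracles import naive_attention, vanilla_vit_block


def small_block_cfg(**kw):
    defaults = dict(depth=2, embed_dim=8, num_heads=2, patch_size=2,
                    lora_rank=2, adapter_bottleneck=4, input_size=8,
                    tap_depths=(1, 2))
    defaults.update(kw)
    return BlockConfig(**defaults)


# -- LoRA -------------------------------------------------------------------

def test_lora_zero_up_weight_is_base_projection(rng):
    layer = LoraLinear(6, 6, rank=2, rng=rng)
    x = Tensor(rng.normal(size=(3, 6)))
    assert layer.lora_up.data.sum() == 0.0
    expected = x.data @ layer.base.weight.data.T + layer.base.bias.data
    np.testing.assert_allclose(layer(x).data, expected, atol=1e-12)


def test_full_rank_identity_down_reduces_to_sum_of_linear_maps(rng):
    layer = LoraLinear(4, 4, rank=4, rng=rng)
    layer.lora_down.data = np.eye(4)
    w_prime = rng.normal(size=(4, 4))
    layer.lora_up.data = w_prime
    x = Tensor(rng.normal(size=(5, 4)))
    expected = x.data @ (layer.base.weight.data + w_prime).T + layer.base.bias.data
    np.testing.assert_allclose(layer(x).data, expected, atol=1e-12)


def test_lora_matches_explicit_dense_composition(rng):
    layer = LoraLinear(6, 5, rank=2, rng=rng)
    layer.lora_up.data = rng.normal(size=(5, 2))
    x = Tensor(rng.normal(size=(7, 6)))
    dense = layer.base.weight.data + layer.lora_up.data @ layer.lora_down.data
    np.testing.assert_allclose(layer(x).data, x.data @ dense.T + layer.base.bias.data,
                               atol=1e-12)


def test_lora_dimension_mismatch_names_axis(rng):
    layer = LoraLinear(6, 6, rank=2, rng=rng)
    with pytest.raises(ValueError, match="last axis"):
        layer(Tensor(np.zeros((3, 5))))


def test_lora_gradient_reaches_low_rank_path_not_base(rng):
    layer = LoraLinear(4, 4, rank=2, rng=rng)
    layer.base.weight.requires_grad = False
    layer.base.bias.requires_grad = False
    out = layer(Tensor(rng.normal(size=(3, 4)))).sum()
    out.backward()
    assert layer.base.weight.grad is None
    assert layer.lora_down.grad is not None and layer.lora_up.grad is not None


# -- attention --------------------------------------------------------------

def test_single_token_attention_is_value_plus_residual(rng):
    cfg = small_block_cfg(num_heads=1)
    block = EncoderBlock(cfg, rng)
    x = rng.normal(size=(1, 1, 8))
    out = block.attention(Tensor(x))
    # softmax over one token is exactly 1 -> context = V(LN(x))
    h = _ln(x[0], block.ln1)
    v = h @ block.v_proj.base.weight.data.T + block.v_proj.base.bias.data
    expected = v @ block.out_proj.weight.data.T + block.out_proj.bias.data + x[0]
    np.testing.assert_allclose(out.data[0], expected, atol=1e-10)


def _ln(x, ln):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + 1e-6) * ln.gamma.data + ln.beta.data


def test_single_head_attention_matches_dense_oracle(rng):
    cfg = small_block_cfg(num_heads=1)
    block = EncoderBlock(cfg, rng)
    x = rng.normal(size=(1, 4, 8))
    h = _ln(x[0], block.ln1)
    ctx = naive_attention(h, block.q_proj.base.weight.data,
                          block.k_proj.weight.data,
                          block.v_proj.base.weight.data,
                          scale=8 ** -0.5)
    # the oracle omits biases; zero them for the comparison
    for lin in (block.q_proj.base, block.k_proj, block.v_proj.base):
        lin.bias.data[:] = 0.0
    expected = ctx @ block.out_proj.weight.data.T + block.out_proj.bias.data + x[0]
    np.testing.assert_allclose(block.attention(Tensor(x)).data[0], expected,
                               atol=1e-5)


def test_nonfinite_attention_logits_raise(rng):
    block = EncoderBlock(small_block_cfg(), rng)
    x = np.zeros((1, 4, 8))
    x[0, 0, 0] = np.inf
    with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
        block.attention(Tensor(x))


# -- adapter ----------------------------------------------------------------

def test_adapter_matches_two_matrix_relu_oracle(rng):
    adapter = Adapter(8, 4, rng)
    adapter.adapter_up.weight.data = rng.normal(size=(8, 4))
    x = rng.normal(size=(3, 8))
    hidden = np.maximum(x @ adapter.adapter_down.weight.data.T
                        + adapter.adapter_down.bias.data, 0.0)
    expected = hidden @ adapter.adapter_up.weight.data.T + adapter.adapter_up.bias.data
    np.testing.assert_allclose(adapter(Tensor(x)).data, expected, atol=1e-12)


@pytest.mark.parametrize("variant,expects_mlp", [("mlp_residual", True),
                                                 ("serial_adapter", False)])
def test_zeroed_adapter_variants(rng, variant, expects_mlp):
    """With a zero adapter, mlp_residual keeps the MLP path; the literal
    equation form drops it and returns the attention output unchanged."""
    cfg = small_block_cfg(adapter_variant=variant)
    block = EncoderBlock(cfg, rng)
    x = Tensor(rng.normal(size=(1, 4, 8)))
    x_bar = block.attention(x)
    out = block(x)
    if expects_mlp:
        x_hat = block.fc2(block.fc1(block.ln2(x_bar)).gelu())
        np.testing.assert_allclose(out.data, (x_bar + x_hat).data, atol=1e-12)
    else:
        np.testing.assert_allclose(out.data, x_bar.data, atol=1e-12)


def test_unknown_adapter_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        small_block_cfg(adapter_variant="bogus")


# -- identity at init vs an independent vanilla ViT ------------------------

def _block_param_dict(block):
    return {
        "ln1_g": block.ln1.gamma.data, "ln1_b": block.ln1.beta.data,
        "wq": block.q_proj.base.weight.data, "bq": block.q_proj.base.bias.data,
        "wk": block.k_proj.weight.data, "bk": block.k_proj.bias.data,
        "wv": block.v_proj.base.weight.data, "bv": block.v_proj.base.bias.data,
        "wo": block.out_proj.weight.data, "bo": block.out_proj.bias.data,
        "ln2_g": block.ln2.gamma.data, "ln2_b": block.ln2.beta.data,
        "w1": block.fc1.weight.data, "b1": block.fc1.bias.data,
        "w2": block.fc2.weight.data, "b2": block.fc2.bias.data,
    }


def test_identity_at_init_block_by_block(rng, tiny_cfg):
    """Freshly built blocks (zero LoRA/adapter up-weights, mlp_residual)
    compute the same function as an independently coded vanilla ViT block."""
    enc = ViTEncoder(tiny_cfg.encoder, rng)
    x = rng.normal(size=(1, 16, 96))
    for block in list(enc.blocks)[:4]:
        ours = block(Tensor(x)).data[0]
        ref = vanilla_vit_block(x[0], _block_param_dict(block),
                                tiny_cfg.encoder.num_heads)
        assert np.abs(ours - ref).max() <= 1e-5
        x = ours[None]


# -- encode / taps ----------------------------------------------------------

def test_tap_shapes_and_shared_resolution(rng):
    cfg = small_block_cfg(depth=4, tap_depths=(1, 2, 4), input_size=8)
    enc = ViTEncoder(cfg, rng)
    taps = enc.encode(rng.normal(size=(2, 1, 8, 8)))
    assert taps.depths == (1, 2, 4)
    for d in taps.depths:
        assert taps[d].shape == (2, 8, 4, 4)
    assert taps.spatial == (4, 4)


def test_encode_64px_tiny_grid(rng, tiny_cfg):
    enc = ViTEncoder(tiny_cfg.encoder, rng)
    taps = enc.encode(rng.normal(size=(1, 1, 64, 64)))
    assert all(taps[d].shape == (1, 96, 4, 4) for d in (3, 6, 9, 12))


def test_encode_is_deterministic(rng, tiny_cfg):
    enc = ViTEncoder(tiny_cfg.encoder, rng)
    img = rng.normal(size=(1, 1, 64, 64))
    a = enc.encode(img)
    b = enc.encode(img)
    for d in a.depths:
        np.testing.assert_array_equal(a[d].data, b[d].data)


def test_tap_depth_beyond_block_count_rejected():
    with pytest.raises(ValueError, match="tap depths"):
        small_block_cfg(depth=2, tap_depths=(1, 3))


def test_patch_shift_moves_token_content(rng):
    """Shifting the image by one patch column shifts patch-token rows
    (checked before the positional embedding is added)."""
    cfg = small_block_cfg(input_size=8)
    enc = ViTEncoder(cfg, rng)
    img = rng.normal(size=(1, 1, 8, 8))
    shifted = np.roll(img, cfg.patch_size, axis=3)
    t0 = enc.patch_embed(Tensor(img)).data.reshape(4, 4, -1)
    t1 = enc.patch_embed(Tensor(shifted)).data.reshape(4, 4, -1)
    np.testing.assert_allclose(np.roll(t0, 1, axis=1), t1, atol=1e-12)


# -- freeze policy ----------------------------------------------------------

def test_freeze_policy_partitions_parameters(rng, tiny_cfg):
    enc = ViTEncoder(tiny_cfg.encoder, rng)
    report = set_freeze_policy(enc)
    trainable_names = {n for n, p in enc.named_parameters() if p.requires_grad}
    assert trainable_names, "LoRA/adapter parameters must be trainable"
    assert all(("lora" in n) or ("adapter" in n) for n in trainable_names)
    total = sum(p.size for p in enc.parameters())
    assert report.frozen + report.trainable == total


def test_frozen_weights_unchanged_by_optimizer_step(rng):
    enc = ViTEncoder(small_block_cfg(), rng)
    frozen_before = {n: p.data.copy() for n, p in enc.named_parameters()
                     if not p.requires_grad}
    opt = AdamW(enc.trainable_parameters(), lr=0.1)
    taps = enc.encode(rng.normal(size=(1, 1, 8, 8)))
    loss = sum((taps[d] ** 2.0).sum() for d in taps.depths)
    loss.backward()
    opt.step()
    for n, p in enc.named_parameters():
        if not p.requires_grad:
            np.testing.assert_array_equal(p.data, frozen_before[n])


def test_gradient_partition_after_backward(rng):
    enc = ViTEncoder(small_block_cfg(), rng)
    taps = enc.encode(rng.normal(size=(1, 1, 8, 8)))
    loss = sum((taps[d] ** 2.0).sum() for d in taps.depths)
    loss.backward()
    for n, p in enc.named_parameters():
        if p.requires_grad:
            assert p.grad is not None, f"trainable {n} missing gradient"
        else:
            assert p.grad is None, f"frozen {n} accumulated gradient"
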