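"""Fusion decoder: HFM branches, stage recurrence, final fusion, argmax."""

import numpy as np
import pytest

from hfseg import HfmConfig, Hfm, predict
from hfseg.decoder import FuseStage, Phfd
from hfseg.nn import Tensor


def _zero_gates(hfm):
    for conv in [hfm.global_gate] + list(hfm.region_gates):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0


# -- HFM ---------------------------------------------------------------------

def test_single_group_regional_equals_global_with_shared_weights(rng):
    hfm = Hfm(HfmConfig(channels=8, groups=1), rng)
    hfm.region_gates[0].weight.data = hfm.global_gate.weight.data.copy()
    hfm.region_gates[0].bias.data = hfm.global_gate.bias.data.copy()
    d = rng.normal(size=(1, 8, 4, 4))
    from hfseg.decoder import _gate
    g = _gate(Tensor(d), hfm.global_gate).data
    r = _gate(Tensor(d), hfm.region_gates[0]).data
    np.testing.assert_allclose(g, r, atol=1e-12)


def test_zero_gates_give_1_5x_on_global_and_regional(rng):
    hfm = Hfm(HfmConfig(channels=8, groups=4), rng)
    _zero_gates(hfm)
    d = rng.normal(size=(1, 8, 3, 3))
    from hfseg.decoder import _gate
    np.testing.assert_allclose(_gate(Tensor(d), hfm.global_gate).data, 1.5 * d,
                               atol=1e-12)
    for i, conv in enumerate(hfm.region_gates):
        part = d[:, 2 * i:2 * i + 2]
        np.testing.assert_allclose(_gate(Tensor(part), conv).data, 1.5 * part,
                                   atol=1e-12)


def test_regional_branch_is_order_preserving_partition(rng):
    """Slicing the concatenated regional output recovers each group's
    independently computed gate result (group-loop oracle)."""
    cfg = HfmConfig(channels=8, groups=4)
    hfm = Hfm(cfg, rng)
    d = rng.normal(size=(1, 8, 4, 4))
    regions = []
    for i, conv in enumerate(hfm.region_gates):
        part = d[0, 2 * i:2 * i + 2]
        means = part.mean(axis=(1, 2))
        z = conv.weight.data.reshape(2, 2) @ means + conv.bias.data
        g = 1.0 / (1.0 + np.exp(-z))
        regions.append(part * (1.0 + g)[:, None, None])
    ref = np.concatenate(regions, axis=0)

    from hfseg.decoder import _gate
    from hfseg.nn import concat
    t = Tensor(d)
    ours = concat([_gate(t[:, 2 * i:2 * i + 2], conv)
                   for i, conv in enumerate(hfm.region_gates)], axis=1)
    np.testing.assert_allclose(ours.data[0], ref, atol=1e-10)


def test_hfm_channel_count_must_divide_groups():
    with pytest.raises(ValueError, match="divisible"):
        HfmConfig(channels=10, groups=4)


def test_hfm_output_shape_preserved(rng):
    hfm = Hfm(HfmConfig(channels=8, groups=2), rng)
    out = hfm(Tensor(rng.normal(size=(2, 8, 5, 5))))
    assert out.shape == (2, 8, 5, 5)


# -- fuse_stage --------------------------------------------------------------

def test_fuse_stage_duplicate_concat_under_averaging_conv(rng):
    """With f_prev = m and the 1x1 compression averaging duplicated
    channels, the refine input equals a linear map of m alone."""
    hfm = Hfm(HfmConfig(channels=4, groups=2), rng)
    stage = FuseStage(4, 4, hfm, rng, first=False)
    stage.compress.weight.data[:] = 0.0
    for c in range(4):
        stage.compress.weight.data[c, c, 0, 0] = 0.5
        stage.compress.weight.data[c, c + 4, 0, 0] = 0.5
    stage.compress.bias.data[:] = 0.0
    m = Tensor(rng.normal(size=(1, 4, 4, 4)))
    out = stage(m, m)
    np.testing.assert_allclose(out.data, hfm(m).data, atol=1e-12)


def test_fuse_stage_shape_contract_and_mismatch_error(rng):
    hfm = Hfm(HfmConfig(channels=8, groups=4), rng)
    stage = FuseStage(8, 8, hfm, rng, first=False)
    m = Tensor(np.zeros((1, 8, 6, 6)))
    assert stage(m, Tensor(np.zeros((1, 8, 6, 6)))).shape == (1, 8, 6, 6)
    with pytest.raises(ValueError, match="resolution schedule"):
        stage(m, Tensor(np.zeros((1, 8, 3, 3))))


# -- decode ------------------------------------------------------------------

def _small_phfd(rng, n_classes=3):
    return Phfd((1, 2, 3, 4), 4, HfmConfig(channels=4, groups=2), n_classes, rng)


def test_decode_produces_stage_and_fused_logits(rng):
    phfd = _small_phfd(rng)
    maps = {d: Tensor(rng.normal(size=(2, 4, 4, 4))) for d in (1, 2, 3, 4)}
    out = phfd.decode(maps, (16, 16))
    assert len(out.stage_features) == 4 and len(out.stage_logits) == 4
    assert all(l.shape == (2, 3, 16, 16) for l in out.stage_logits)
    assert out.fused_logits.shape == (2, 3, 16, 16)


def test_decode_missing_tap_rejected(rng):
    phfd = _small_phfd(rng)
    maps = {d: Tensor(np.zeros((1, 4, 4, 4))) for d in (1, 2)}
    with pytest.raises(ValueError, match="missing hypermaps"):
        phfd.decode(maps, (16, 16))


def test_decode_keyed_by_depth_not_insertion_order(rng):
    phfd = _small_phfd(rng)
    arrays = {d: rng.normal(size=(1, 4, 4, 4)) for d in (1, 2, 3, 4)}
    a = phfd.decode({d: Tensor(arrays[d]) for d in (1, 2, 3, 4)}, (8, 8))
    b = phfd.decode({d: Tensor(arrays[d]) for d in (4, 3, 1, 2)}, (8, 8))
    np.testing.assert_array_equal(a.fused_logits.data, b.fused_logits.data)


def test_gradient_reaches_every_stage_and_head(rng):
    phfd = _small_phfd(rng)
    maps = {d: Tensor(rng.normal(size=(1, 4, 4, 4))) for d in (1, 2, 3, 4)}
    out = phfd.decode(maps, (8, 8))
    (out.fused_logits ** 2.0).sum().backward()
    for name, p in phfd.named_parameters():
        assert p.grad is not None, f"{name} received no gradient"


# -- fuse_final --------------------------------------------------------------

def test_identical_stage_logits_with_averaging_conv_are_identity(rng):
    phfd = _small_phfd(rng)
    phfd.final_fuse.weight.data[:] = 0.0
    for c in range(3):
        for s in range(4):
            phfd.final_fuse.weight.data[c, s * 3 + c, 0, 0] = 0.25
    phfd.final_fuse.bias.data[:] = 0.0
    logit = Tensor(rng.normal(size=(1, 3, 8, 8)))
    fused = phfd.fuse_final([logit] * 4)
    np.testing.assert_allclose(fused.data, logit.data, atol=1e-12)


def test_fuse_final_matches_weighted_sum_oracle(rng):
    phfd = _small_phfd(rng)
    logits = [rng.normal(size=(1, 3, 4, 4)) for _ in range(4)]
    fused = phfd.fuse_final([Tensor(l) for l in logits]).data
    stacked = np.concatenate(logits, axis=1)[0]          # (12, 4, 4)
    wmat = phfd.final_fuse.weight.data.reshape(3, 12)
    ref = np.einsum("ck,khw->chw", wmat, stacked) + \
        phfd.final_fuse.bias.data[:, None, None]
    np.testing.assert_allclose(fused[0], ref, atol=1e-10)


def test_fuse_final_resolution_mismatch_rejected(rng):
    phfd = _small_phfd(rng)
    with pytest.raises(ValueError, match="resolution"):
        phfd.fuse_final([Tensor(np.zeros((1, 3, 8, 8)))] * 3
                        + [Tensor(np.zeros((1, 3, 4, 4)))])


# -- predict -----------------------------------------------------------------

def test_predict_argmax_and_tie_break():
    logits = np.zeros((3, 2, 2))
    logits[2] = 5.0
    assert (predict(logits) == 2).all()
    tie = np.zeros((3, 1, 1))
    tie[0, 0, 0] = tie[1, 0, 0] = 7.0
    assert predict(tie)[0, 0] == 0       # ties break toward the lowest class


def test_predict_one_hot_recovers_index_map(rng):
    idx = rng.integers(0, 3, size=(5, 5))
    onehot = np.stack([(idx == c).astype(float) for c in range(3)])
    np.testing.assert_array_equal(predict(onehot), idx)
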