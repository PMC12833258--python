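"""Independent brute-force reference implementations.

Everything here is written with explicit Python loops over pixels,
channels, heads and kernel taps, deliberately sharing no code with the
package's vectorised implementations, so agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def naive_conv2d(x, w, b=None, padding=0, dilation=1):
    """Per-pixel sliding-window cross-correlation. x: (C,H,W), w: (O,C,kh,kw)."""
    c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - dilation * (kh - 1)
    ow = wd + 2 * padding - dilation * (kw - 1)
    out = np.zeros((o, oh, ow))
    for oc in range(o):
        for i in range(oh):
            for j in range(ow):
                acc = 0.0
                for ic in range(c):
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += w[oc, ic, ki, kj] * xp[ic, i + ki * dilation,
                                                          j + kj * dilation]
                out[oc, i, j] = acc + (b[oc] if b is not None else 0.0)
    return out


def naive_conv_transpose2d(x, w, b=None, stride=2):
    """Zero-interleave scattering. x: (C,H,W), w: (C,O,kh,kw)."""
    c, h, wd = x.shape
    _, o, kh, kw = w.shape
    out = np.zeros((o, (h - 1) * stride + kh, (wd - 1) * stride + kw))
    for ic in range(c):
        for oc in range(o):
            for i in range(h):
                for j in range(wd):
                    for ki in range(kh):
                        for kj in range(kw):
                            out[oc, i * stride + ki, j * stride + kj] += (
                                x[ic, i, j] * w[ic, oc, ki, kj])
    if b is not None:
        out += b[:, None, None]
    return out


def naive_channel_gate(h, gate_w, gate_b):
    """Per-channel loop: mean -> 1x1 conv as a matrix -> sigmoid -> h*(1+g)."""
    c = h.shape[0]
    means = np.array([h[i].mean() for i in range(c)])
    z = gate_w.reshape(c, c) @ means + gate_b
    g = 1.0 / (1.0 + np.exp(-z))
    out = np.empty_like(h)
    for i in range(c):
        out[i] = h[i] * (1.0 + g[i])
    return out


def naive_attention(x, wq, wk, wv, scale):
    """Single-head dense softmax attention over a token matrix x (N,D)."""
    q, k, v = x @ wq.T, x @ wk.T, x @ wv.T
    n = x.shape[0]
    out = np.zeros_like(v)
    for i in range(n):
        logits = np.array([q[i] @ k[j] * scale for j in range(n)])
        logits -= logits.max()
        a = np.exp(logits)
        a /= a.sum()
        for j in range(n):
            out[i] += a[j] * v[j]
    return out


def _ln(x, g, b, eps=1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def _gelu(x):
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def vanilla_vit_block(x, p, num_heads):
    """Pre-norm ViT block forward from a flat parameter dict.

    p holds: ln1_g, ln1_b, wq, bq, wk, bk, wv, bv, wo, bo, ln2_g, ln2_b,
    w1, b1, w2, b2.  x: (N, D).
    """
    n, d = x.shape
    hd = d // num_heads
    h = _ln(x, p["ln1_g"], p["ln1_b"])
    q = h @ p["wq"].T + p["bq"]
    k = h @ p["wk"].T + p["bk"]
    v = h @ p["wv"].T + p["bv"]
    ctx = np.zeros((n, d))
    for head in range(num_heads):
        sl = slice(head * hd, (head + 1) * hd)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        for i in range(n):
            logits = qh[i] @ kh.T / np.sqrt(hd)
            logits -= logits.max()
            a = np.exp(logits)
            a /= a.sum()
            ctx[i, sl] = a @ vh
    x_bar = ctx @ p["wo"].T + p["bo"] + x
    hh = _ln(x_bar, p["ln2_g"], p["ln2_b"])
    x_hat = _gelu(hh @ p["w1"].T + p["b1"]) @ p["w2"].T + p["b2"]
    return x_bar + x_hat


def eq_binary_ce(p_logit, gt):
    """Direct per-pixel binary cross-entropy of sigmoid(p_logit) vs gt in {0,1}."""
    total = 0.0
    h, w = gt.shape
    for i in range(h):
        for j in range(w):
            p = 1.0 / (1.0 + np.exp(-p_logit[i, j]))
            total -= gt[i, j] * np.log(p) + (1 - gt[i, j]) * np.log(1 - p)
    return total / (h * w)


def count_dice_iou(pred, gt, cls):
    """Pixel-count Dice and IoU for one class via explicit set cardinalities."""
    a = {tuple(p) for p in np.argwhere(gt == cls)}
    b = {tuple(p) for p in np.argwhere(pred == cls)}
    inter = len(a & b)
    union = len(a | b)
    if len(a) + len(b) == 0:
        return 1.0, 1.0
    return 2 * inter / (len(a) + len(b)), inter / union
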