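"""Structured operations: convolutions, upsampling, normalisation, losses.

All spatial tensors follow the (N, C, H, W) layout.  Convolutions are
implemented as a short sum over kernel offsets, each offset handled by a
fully vectorised einsum; this keeps the code transparent enough to test
against naive sliding-window oracles while remaining fast at the spatial
sizes the network operates on.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _node


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, stride 1.

    x: (N, C_in, H, W); w: (C_out, C_in, kh, kw); b: (C_out,) or None.
    `padding` is symmetric zero padding; `dilation` spaces the kernel taps.
    """
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels but weight expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - dilation * (kh - 1)
    ow = wd + 2 * padding - dilation * (kw - 1)
    if oh <= 0 or ow <= 0:
        raise ValueError("conv2d: kernel larger than padded input")
    out_data = np.zeros((n, cout, oh, ow))
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i * dilation:i * dilation + oh, j * dilation:j * dilation + ow]
            out_data += np.einsum("nchw,oc->nohw", patch, w.data[:, :, i, j])
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)
    if out.requires_grad:
        def _bw(g):
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i * dilation:i * dilation + oh,
                            j * dilation:j * dilation + ow] += np.einsum(
                                "nohw,oc->nchw", g, w.data[:, :, i, j])
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(gxp)
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        patch = xp[:, :, i * dilation:i * dilation + oh,
                                   j * dilation:j * dilation + ow]
                        gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, patch)
                w._accumulate(gw)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
        out._backward = _bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution (learnable upsampling).

    x: (N, C_in, H, W); w: (C_in, C_out, kh, kw).  Output spatial size is
    (H-1)*stride + kh.  With kh == stride this is exact zero-interleaved
    scattering with no overlap.
    """
    n, cin, h, wd = x.shape
    cin_w, cout, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d: input has {cin} channels, weight expects {cin_w}")
    oh = (h - 1) * stride + kh
    ow = (wd - 1) * stride + kw
    out_data = np.zeros((n, cout, oh, ow))
    for i in range(kh):
        for j in range(kw):
            out_data[:, :, i:i + stride * h:stride, j:j + stride * wd:stride] += np.einsum(
                "nchw,co->nohw", x.data, w.data[:, :, i, j])
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)
    if out.requires_grad:
        def _bw(g):
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                for i in range(kh):
                    for j in range(kw):
                        gx += np.einsum(
                            "nohw,co->nchw",
                            g[:, :, i:i + stride * h:stride, j:j + stride * wd:stride],
                            w.data[:, :, i, j])
                x._accumulate(gx)
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        gw[:, :, i, j] = np.einsum(
                            "nohw,nchw->co",
                            g[:, :, i:i + stride * h:stride, j:j + stride * wd:stride],
                            x.data)
                w._accumulate(gw)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
        out._backward = _bw
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, half-pixel-centre convention."""
    m = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[o, lo] += 1.0 - frac
        m[o, hi] += frac
    return m


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear upsampling of (N, C, H, W) to spatial `size` (separable)."""
    oh, ow = size
    mh = _interp_matrix(oh, x.shape[2])
    mw = _interp_matrix(ow, x.shape[3])
    out = _node(np.einsum("ph,nchw,qw->ncpq", mh, x.data, mw, optimize=True), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(
            np.einsum("ph,ncpq,qw->nchw", mh, g, mw, optimize=True))
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel, keeping singleton spatial dims."""
    return x.mean(axis=(2, 3), keepdims=True)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode, batch statistics are used and the running buffers
    updated in place (unbiased variance for the running estimate); in
    inference mode the running buffers are used.
    """
    if training:
        mean = x.mean(axis=(0, 2, 3), keepdims=True)
        var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
        n = x.shape[0] * x.shape[2] * x.shape[3]
        unbias = n / max(n - 1, 1)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean.data.reshape(-1)
        running_var *= (1 - momentum)
        running_var += momentum * var.data.reshape(-1) * unbias
        xhat = (x - mean) * (var + eps) ** -0.5
    else:
        mean = running_mean[None, :, None, None]
        var = running_var[None, :, None, None]
        xhat = (x - Tensor(mean)) * Tensor(1.0 / np.sqrt(var + eps))
    return xhat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalisation over the last axis (token embeddings)."""
    mean = x.mean(axis=-1, keepdims=True)
    var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
    return (x - mean) * (var + eps) ** -0.5 * gamma + beta


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy between C-channel logits and integer labels.

    logits: (N, C, H, W); labels: (N, H, W) integers in [0, C).  For C == 2
    this equals the per-pixel binary cross-entropy of the sigmoid of the
    logit difference z1 - z0.  Computed in log-space (log-sum-exp) for
    stability; returns the mean over all pixels.
    """
    z = logits.data
    labels = np.asarray(labels)
    c = z.shape[1]
    if labels.min() < 0 or labels.max() >= c:
        bad = np.argwhere((labels < 0) | (labels >= c))[0]
        raise ValueError(
            f"label out of range [0,{c}) at pixel {tuple(bad)}: {labels[tuple(bad)]}")
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    onehot_idx = (np.arange(z.shape[0])[:, None, None],
                  labels,
                  np.arange(z.shape[2])[None, :, None],
                  np.arange(z.shape[3])[None, None, :])
    logp_true = z[onehot_idx] - lse[:, 0]
    npix = labels.size
    out = _node(np.array(-logp_true.sum() / npix), (logits,))
    if out.requires_grad:
        def _bw(g):
            p = np.exp(z - lse)
            p[onehot_idx] -= 1.0
            logits._accumulate(g * p / npix)
        out._backward = _bw
    return out
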