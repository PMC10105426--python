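"""Hand-differentiated neural-network primitives on :class:`~thyroseg.nn.tensor.Tensor`.

All convolutions are stride-1 (downsampling in the networks is done by
pooling, matching the split-attention block design); dilation, channel
groups and arbitrary zero padding are supported.  The convolution forward
and its input-gradient both reduce to a single correlation helper built on
``sliding_window_view`` + BLAS matmul, chunked over output rows to bound
peak memory.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _unbroadcast  # noqa: F401  (re-export site)

_COL_CHUNK_BYTES = 256 * 1024 * 1024


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int, dilation: int, groups: int) -> np.ndarray:
    """Stride-1 cross-correlation. x:(B,Cin,H,W), w:(Cout,Cin/g,kh,kw)."""
    B, Cin, H, W = x.shape
    Cout, cg, kh, kw = w.shape
    if Cin != cg * groups:
        raise ValueError(f"channel mismatch: input {Cin}, weight expects {cg * groups}")
    d = dilation
    eh, ew = (kh - 1) * d + 1, (kw - 1) * d + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = x.shape[2] - eh + 1, x.shape[3] - ew + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"input {H}x{W} too small for kernel extent {eh}x{ew} at pad {pad}")
    cog = Cout // groups
    out = np.empty((B, Cout, Ho, Wo), dtype=np.float32)
    # windows: (B, Cin, Ho, Wo, kh, kw) as a view
    win = sliding_window_view(x, (eh, ew), axis=(2, 3))[..., ::d, ::d]
    rows_per_chunk = max(1, _COL_CHUNK_BYTES // max(1, B * Wo * Cin * kh * kw * 4))
    for g in range(groups):
        wg = w[g * cog:(g + 1) * cog].reshape(cog, cg * kh * kw)
        for r0 in range(0, Ho, rows_per_chunk):
            r1 = min(r0 + rows_per_chunk, Ho)
            cols = np.ascontiguousarray(
                win[:, g * cg:(g + 1) * cg, r0:r1].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(B * (r1 - r0) * Wo, cg * kh * kw)
            out[:, g * cog:(g + 1) * cog, r0:r1] = (
                (cols @ wg.T).reshape(B, r1 - r0, Wo, cog).transpose(0, 3, 1, 2)
            )
    return out


def _corr2d_wgrad(
    x: np.ndarray, gout: np.ndarray, kh: int, kw: int, pad: int, dilation: int, groups: int
) -> np.ndarray:
    """Gradient of _corr2d w.r.t. the weight."""
    B, Cin, H, W = x.shape
    _, Cout, Ho, Wo = gout.shape
    d = dilation
    eh, ew = (kh - 1) * d + 1, (kw - 1) * d + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cg = Cin // groups
    cog = Cout // groups
    win = sliding_window_view(x, (eh, ew), axis=(2, 3))[..., ::d, ::d]
    gw = np.empty((Cout, cg, kh, kw), dtype=np.float32)
    rows_per_chunk = max(1, _COL_CHUNK_BYTES // max(1, B * Wo * Cin * kh * kw * 4))
    for g in range(groups):
        acc = np.zeros((cog, cg * kh * kw), dtype=np.float32)
        for r0 in range(0, Ho, rows_per_chunk):
            r1 = min(r0 + rows_per_chunk, Ho)
            cols = np.ascontiguousarray(
                win[:, g * cg:(g + 1) * cg, r0:r1].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(B * (r1 - r0) * Wo, cg * kh * kw)
            gg = np.ascontiguousarray(
                gout[:, g * cog:(g + 1) * cog, r0:r1].transpose(0, 2, 3, 1)
            ).reshape(B * (r1 - r0) * Wo, cog)
            acc += gg.T @ cols
        gw[g * cog:(g + 1) * cog] = acc.reshape(cog, cg, kh, kw)
    return gw


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    padding: int | str = "same",
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """2-D stride-1 convolution (correlation convention, as in deep learning)."""
    Cout, cg, kh, kw = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"kernel must be odd, got {kh}x{kw}")
    pad = (kh - 1) * dilation // 2 if padding == "same" else int(padding)
    data = _corr2d(x.data, w.data, pad, dilation, groups)
    if b is not None:
        data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        if x.requires_grad:
            cog = Cout // groups
            # full correlation with spatially flipped, channel-transposed weights
            wf = w.data[:, :, ::-1, ::-1]
            wt = np.concatenate(
                [
                    np.ascontiguousarray(
                        wf[gi * cog:(gi + 1) * cog].transpose(1, 0, 2, 3)
                    )
                    for gi in range(groups)
                ],
                axis=0,
            )  # (Cin, Cout/g, kh, kw)
            gx = _corr2d(g, wt, (kh - 1) * dilation - pad, dilation, groups)
            x._accum(gx)
        if w.requires_grad:
            w._accum(_corr2d_wgrad(x.data, g, kh, kw, pad, dilation, groups))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(data, parents, backward)


def _pool_prep(x: np.ndarray, fill: float):
    """Zero/neg-inf pad H,W up to even (ceil-mode 2x2 pooling)."""
    B, C, H, W = x.shape
    ph, pw = H % 2, W % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=fill)
    return x, ph, pw


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling, ceil mode (odd edges padded with -inf)."""
    xd, ph, pw = _pool_prep(x.data, -np.inf)
    B, C, H, W = xd.shape
    win = xd.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, H // 2, W // 2, 4
    )
    amax = win.argmax(axis=-1)
    data = np.take_along_axis(win, amax[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros_like(win)
        np.put_along_axis(gw, amax[..., None], g[..., None], axis=-1)
        gx = gw.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )
        if ph or pw:
            gx = gx[:, :, : H - ph, : W - pw]
        x._accum(np.ascontiguousarray(gx))

    return Tensor._make(data, (x,), backward)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 stride-2 average pooling, ceil mode (edge windows average real pixels only)."""
    xd, ph, pw = _pool_prep(x.data, 0.0)
    B, C, H, W = xd.shape
    s = xd.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
    cnt = np.full((H // 2, W // 2), 4.0, dtype=np.float32)
    if ph:
        cnt[-1, :] /= 2
    if pw:
        cnt[:, -1] /= 2
    data = s / cnt

    def backward(g):
        gs = (g / cnt)[:, :, :, None, :, None]
        gx = np.broadcast_to(gs, (B, C, H // 2, 2, W // 2, 2)).reshape(B, C, H, W)
        if ph or pw:
            gx = gx[:, :, : H - ph, : W - pw]
        x._accum(np.ascontiguousarray(gx))

    return Tensor._make(data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def _resize_axes(in_hw, out_hw):
    """Half-pixel-centre source indices and lerp weights per axis."""
    idx = []
    for n_in, n_out in zip(in_hw, out_hw):
        src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(np.int64)
        i1 = np.minimum(i0 + 1, n_in - 1)
        t = (src - i0).astype(np.float32)
        idx.append((i0, i1, t))
    return idx


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resampling to ``out_hw`` (half-pixel centres, edges clamped)."""
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return x * 1.0
    (y0, y1, ty), (x0, x1, tx) = _resize_axes((H, W), (Ho, Wo))
    tyc = ty[None, None, :, None]
    txc = tx[None, None, None, :]

    rows = x.data[:, :, y0, :] * (1 - tyc) + x.data[:, :, y1, :] * tyc
    data = rows[:, :, :, x0] * (1 - txc) + rows[:, :, :, x1] * txc

    def backward(g):
        grows = np.zeros((B, C, Ho, W), dtype=np.float32)
        np.add.at(grows, (slice(None), slice(None), slice(None), x0), g * (1 - txc))
        np.add.at(grows, (slice(None), slice(None), slice(None), x1), g * txc)
        gx = np.zeros((B, C, H, W), dtype=np.float32)
        np.add.at(gx, (slice(None), slice(None), y0), grows * (1 - tyc))
        np.add.at(gx, (slice(None), slice(None), y1), grows * tyc)
        x._accum(gx)

    return Tensor._make(data, (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        x._accum(data * (g - (g * data).sum(axis=axis, keepdims=True)))

    return Tensor._make(data, (x,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    s = x.data - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    data = s - lse

    def backward(g):
        x._accum(g - np.exp(data) * g.sum(axis=axis, keepdims=True))

    return Tensor._make(data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accum(np.ascontiguousarray(g[tuple(sl)]))

    return Tensor._make(data, tuple(tensors), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)


def batch_norm_train(
    x: Tensor, gamma: Tensor, beta: Tensor, eps: float
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batch normalization over (B,H,W) per channel; returns (y, batch_mean, batch_var)."""
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gam = gamma.data.reshape(1, -1, 1, 1)
    data = gam * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * gam
            x._accum(
                inv
                * (
                    gh
                    - gh.mean(axis=axes, keepdims=True)
                    - xhat * (gh * xhat).sum(axis=axes, keepdims=True) / n
                )
            )

    out = Tensor._make(data, (x, gamma, beta), backward)
    return out, mu.reshape(-1), var.reshape(-1) * (n / max(n - 1, 1))


def _kernel_grid(k: int, dilation: int) -> tuple[np.ndarray, np.ndarray]:
    half = (k - 1) // 2 * dilation
    dy, dx = np.meshgrid(
        np.arange(-half, half + 1, dilation), np.arange(-half, half + 1, dilation), indexing="ij"
    )
    return dy.ravel().astype(np.float32), dx.ravel().astype(np.float32)


def deform_sample(x: Tensor, offsets: Tensor, kernel: int = 3, dilation: int = 1) -> Tensor:
    """Bilinear sampling of ``x`` at the K = kernel**2 deformed grid points.

    offsets: (B, 2K, H, W) ordered (dy_0, dx_0, dy_1, dx_1, ...); samples
    falling outside the image read 0.  Returns (B, K, C, H, W).
    """
    B, C, H, W = x.shape
    K = kernel * kernel
    if offsets.shape != (B, 2 * K, H, W):
        raise ValueError(f"offsets must be (B,{2 * K},H,W), got {offsets.shape}")
    gdy, gdx = _kernel_grid(kernel, dilation)
    off = offsets.data.reshape(B, K, 2, H, W)
    ys = np.arange(H, dtype=np.float32)[None, None, :, None] + gdy[None, :, None, None] + off[:, :, 0]
    xs = np.arange(W, dtype=np.float32)[None, None, None, :] + gdx[None, :, None, None] + off[:, :, 1]

    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    ty = ys - y0
    tx = xs - x0

    xf = x.data.reshape(B, C, H * W)
    bidx = np.arange(B)[:, None, None, None]

    def corner(yc, xc):
        valid = ((yc >= 0) & (yc < H) & (xc >= 0) & (xc < W)).astype(np.float32)
        flat = np.clip(yc, 0, H - 1) * W + np.clip(xc, 0, W - 1)
        v = xf[bidx, :, flat]  # (B, K, H, W, C)
        return v * valid[..., None], valid, flat

    wts = [(1 - ty) * (1 - tx), (1 - ty) * tx, ty * (1 - tx), ty * tx]
    corners = [(y0, x0), (y0, x0 + 1), (y0 + 1, x0), (y0 + 1, x0 + 1)]
    vals = []
    data5 = np.zeros((B, K, H, W, C), dtype=np.float32)
    for (yc, xc), w in zip(corners, wts):
        v, valid, flat = corner(yc, xc)
        vals.append((v, valid, flat, w))
        data5 += v * w[..., None]
    data = np.ascontiguousarray(data5.transpose(0, 1, 4, 2, 3))  # (B,K,C,H,W)

    def backward(g):
        g5 = np.ascontiguousarray(g.transpose(0, 1, 3, 4, 2))  # (B,K,H,W,C)
        if x.requires_grad:
            gxf = np.zeros((B, C, H * W), dtype=np.float32)
            for (v, valid, flat, w) in vals:
                contrib = g5 * (w * valid)[..., None]  # (B,K,H,W,C)
                for b in range(B):
                    np.add.at(
                        gxf[b],
                        (slice(None), flat[b].ravel()),
                        contrib[b].reshape(-1, C).T,
                    )
            x._accum(gxf.reshape(B, C, H, W))
        if offsets.requires_grad:
            (v00, _, _, _), (v01, _, _, _), (v10, _, _, _), (v11, _, _, _) = vals
            dy_val = ((v10 - v00) * (1 - tx)[..., None] + (v11 - v01) * tx[..., None])
            dx_val = ((v01 - v00) * (1 - ty)[..., None] + (v11 - v10) * ty[..., None])
            gy = (g5 * dy_val).sum(axis=-1)
            gx_ = (g5 * dx_val).sum(axis=-1)
            goff = np.stack([gy, gx_], axis=2).reshape(B, 2 * K, H, W)
            offsets._accum(goff)

    return Tensor._make(data, (x, offsets), backward)
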