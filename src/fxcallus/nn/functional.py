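"""Structured autodiff operations: 2-D convolution and the selective scan.

Both are single graph nodes with analytic backward passes, rather than
compositions of elementwise primitives, so the sequential state-space
recurrence stays cheap to differentiate.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "selective_scan", "upsample_nearest"]


def _conv_geometry(H, W, kh, kw, stride, dilation, padding):
    eff_kh = dilation * (kh - 1) + 1
    eff_kw = dilation * (kw - 1) + 1
    Ho = (H + 2 * padding - eff_kh) // stride + 1
    Wo = (W + 2 * padding - eff_kw) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"convolution output would be empty for input {(H, W)} and kernel {(kh, kw)}")
    i0 = np.repeat(np.arange(kh) * dilation, kw)  # (kh*kw,)
    j0 = np.tile(np.arange(kw) * dilation, kh)
    i1 = stride * np.repeat(np.arange(Ho), Wo)  # (Ho*Wo,)
    j1 = stride * np.tile(np.arange(Wo), Ho)
    ii = i0[:, None] + i1[None, :]  # (kh*kw, Ho*Wo)
    jj = j0[:, None] + j1[None, :]
    return Ho, Wo, ii, jj


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    depthwise: bool = False,
) -> Tensor:
    """2-D convolution on (B, C, H, W) via gather + matmul.

    ``depthwise=True`` convolves each channel with its own (1, kh, kw) filter,
    with ``w`` shaped (C, 1, kh, kw).
    """
    B, C, H, W = x.shape
    if depthwise:
        Cw, one, kh, kw = w.shape
        if Cw != C or one != 1:
            raise ValueError(f"depthwise weight must be ({C}, 1, kh, kw), got {w.shape}")
    else:
        Co, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"weight expects {Ci} input channels, input has {C}")
    Ho, Wo, ii, jj = _conv_geometry(H, W, kh, kw, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols = xp[:, :, ii, jj]  # (B, C, kh*kw, Ho*Wo)

    if depthwise:
        w2 = w.data.reshape(C, kh * kw)
        out_data = np.einsum("bckl,ck->bcl", cols, w2).reshape(B, C, Ho, Wo)
        Co = C
    else:
        w2 = w.data.reshape(Co, C * kh * kw)
        out_data = (w2 @ cols.reshape(B, C * kh * kw, -1)).reshape(B, Co, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        gmat = g.reshape(B, Co, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=(0, 2)))
        if depthwise:
            if w.requires_grad:
                gw = np.einsum("bcl,bckl->ck", gmat, cols)
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                dcols = gmat[:, :, None, :] * w.data.reshape(1, C, kh * kw, 1)
                _scatter_cols(x, dcols, ii, jj, padding, H, W)
        else:
            if w.requires_grad:
                gw = np.einsum("bol,bkl->ok", gmat, cols.reshape(B, C * kh * kw, -1))
                w._accumulate(gw.reshape(w.shape))
            if x.requires_grad:
                dcols = (w2.T @ gmat).reshape(B, C, kh * kw, Ho * Wo)
                _scatter_cols(x, dcols, ii, jj, padding, H, W)

    out._backward = _bw
    return out


def _scatter_cols(x: Tensor, dcols: np.ndarray, ii, jj, padding: int, H: int, W: int) -> None:
    B, C = x.shape[:2]
    gxp = np.zeros((B, C, H + 2 * padding, W + 2 * padding))
    np.add.at(gxp, (slice(None), slice(None), ii, jj), dcols)
    if padding:
        gxp = gxp[:, :, padding:-padding, padding:-padding]
    x._accumulate(gxp)


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    """Nearest-neighbour upsampling of (B, C, H, W) by an integer factor."""
    B, C, H, W = x.shape
    out_data = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)
    out = Tensor(out_data, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            g = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
            x._accumulate(g)

    out._backward = _bw
    return out


def selective_scan(u: Tensor, delta: Tensor, A: Tensor, Bm: Tensor, Cm: Tensor, D: Tensor) -> Tensor:
    """Input-dependent linear state-space recurrence along the last axis.

    Shapes: ``u``, ``delta``: (G, Dm, L); ``A``: (Dm, N); ``Bm``, ``Cm``:
    (G, N, L); ``D``: (Dm,). The recurrence, discretized per step by
    zero-order hold, is::

        h_t = exp(delta_t * A) . h_{t-1} + delta_t * B_t * u_t
        y_t = <C_t, h_t> + D * u_t

    The backward pass replays the recurrence in reverse with analytic
    gradients for every input.
    """
    G, Dm, L = u.shape
    N = A.shape[1]
    ud, dd, Ad, Bd, Cd, Dd = u.data, delta.data, A.data, Bm.data, Cm.data, D.data

    hs = np.empty((L, G, Dm, N))
    h = np.zeros((G, Dm, N))
    y = np.empty((G, Dm, L))
    for t in range(L):
        dA = np.exp(dd[:, :, t, None] * Ad[None])  # (G, Dm, N)
        h = dA * h + dd[:, :, t, None] * Bd[:, None, :, t] * ud[:, :, t, None]
        hs[t] = h
        y[:, :, t] = np.einsum("gdn,gn->gd", h, Cd[:, :, t])
    y = y + Dd[None, :, None] * ud

    out = Tensor(y, _prev=(u, delta, A, Bm, Cm, D))

    def _bw(g):
        du = g * Dd[None, :, None]
        ddelta = np.zeros_like(dd)
        dA_acc = np.zeros_like(Ad)
        dB = np.zeros_like(Bd)
        dC = np.zeros_like(Cd)
        dD = np.einsum("gdl,gdl->d", g, ud)
        dh = np.zeros((G, Dm, N))
        for t in range(L - 1, -1, -1):
            gy = g[:, :, t]  # (G, Dm)
            dC[:, :, t] = np.einsum("gd,gdn->gn", gy, hs[t])
            dh = dh + gy[:, :, None] * Cd[:, None, :, t]
            h_prev = hs[t - 1] if t > 0 else np.zeros((G, Dm, N))
            dA_t = np.exp(dd[:, :, t, None] * Ad[None])
            ddelta[:, :, t] = np.einsum(
                "gdn,gdn->gd",
                dh,
                dA_t * Ad[None] * h_prev + Bd[:, None, :, t] * ud[:, :, t, None],
            )
            dA_acc += np.einsum("gdn,gdn->dn", dh, dA_t * dd[:, :, t, None] * h_prev)
            dB[:, :, t] = np.einsum("gdn,gd->gn", dh, dd[:, :, t] * ud[:, :, t])
            du[:, :, t] += np.einsum("gdn,gn->gd", dh * dd[:, :, t, None], Bd[:, None, :, t].reshape(G, N))
            dh = dh * dA_t
        if u.requires_grad:
            u._accumulate(du)
        if delta.requires_grad:
            delta._accumulate(ddelta)
        if A.requires_grad:
            A._accumulate(dA_acc)
        if Bm.requires_grad:
            Bm._accumulate(dB)
        if Cm.requires_grad:
            Cm._accumulate(dC)
        if D.requires_grad:
            D._accumulate(dD)

    out._backward = _bw
    return out
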