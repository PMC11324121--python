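"""Fused elementwise kernels for the transformer hot loops.

Row-wise softmax and layer normalisation dominate memory traffic in the
attention blocks when done as separate NumPy passes; these numba
versions make one pass per row.  If numba is unavailable the NumPy
fallbacks keep everything working (slower, numerically equivalent).
"""

from __future__ import annotations

import numpy as np
from math import erf as math_erf

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False, fastmath=True)
def _softmax_rows(x):
    n, s = x.shape
    for i in range(n):
        m = x[i, 0]
        for j in range(1, s):
            if x[i, j] > m:
                m = x[i, j]
        total = 0.0
        for j in range(s):
            v = np.exp(x[i, j] - m)
            x[i, j] = v
            total += v
        inv = 1.0 / total
        for j in range(s):
            x[i, j] *= inv


@njit(cache=False, fastmath=True)
def _softmax_backward_rows(p, gp, scale):
    n, s = p.shape
    for i in range(n):
        dot = 0.0
        for j in range(s):
            dot += gp[i, j] * p[i, j]
        for j in range(s):
            gp[i, j] = scale * p[i, j] * (gp[i, j] - dot)


@njit(cache=False, fastmath=True)
def _layernorm_rows(x, gamma, beta, out, xhat, inv, eps):
    n, d = x.shape
    for i in range(n):
        mu = 0.0
        for j in range(d):
            mu += x[i, j]
        mu /= d
        var = 0.0
        for j in range(d):
            c = x[i, j] - mu
            var += c * c
        var /= d
        iv = 1.0 / np.sqrt(var + eps)
        inv[i] = iv
        for j in range(d):
            h = (x[i, j] - mu) * iv
            xhat[i, j] = h
            out[i, j] = h * gamma[j] + beta[j]


@njit(cache=False, fastmath=True)
def _layernorm_backward_rows(g, gamma, xhat, inv, ggamma, gbeta, gx):
    n, d = g.shape
    for i in range(n):
        m1 = 0.0
        m2 = 0.0
        for j in range(d):
            v = g[i, j] * gamma[j]
            m1 += v
            m2 += v * xhat[i, j]
        m1 /= d
        m2 /= d
        iv = inv[i]
        for j in range(d):
            v = g[i, j] * gamma[j]
            ggamma[j] += g[i, j] * xhat[i, j]
            gbeta[j] += g[i, j]
            gx[i, j] = iv * (v - m1 - xhat[i, j] * m2)


@njit(cache=False, fastmath=True)
def _gelu_rows(x, out, phi):
    n = x.size
    xf = x.reshape(n)
    of = out.reshape(n)
    pf = phi.reshape(n)
    c = 0.7071067811865476
    for i in range(n):
        p = 0.5 * (1.0 + math_erf(xf[i] * c))
        pf[i] = p
        of[i] = xf[i] * p


@njit(cache=False, fastmath=True)
def _gelu_backward_rows(x, phi, g, out):
    n = x.size
    xf = x.reshape(n)
    pf = phi.reshape(n)
    gf = g.reshape(n)
    of = out.reshape(n)
    c = 0.3989422804014327  # 1/sqrt(2 pi)
    for i in range(n):
        pdf = np.exp(-0.5 * xf[i] * xf[i]) * c
        of[i] = gf[i] * (pf[i] + xf[i] * pdf)


def gelu_forward(x):
    """Returns (out, phi) where phi = Phi(x) is cached for backward."""
    if HAVE_NUMBA:
        xc = np.ascontiguousarray(x)
        out = np.empty_like(xc)
        phi = np.empty_like(xc)
        _gelu_rows(xc, out, phi)
        return out, phi
    from scipy.special import erf

    phi = 0.5 * (1.0 + erf(x * 0.7071067811865476))
    return x * phi, phi


def gelu_backward(x, phi, g):
    if HAVE_NUMBA:
        out = np.empty_like(np.ascontiguousarray(g))
        _gelu_backward_rows(np.ascontiguousarray(x), phi,
                            np.ascontiguousarray(g), out)
        return out
    pdf = np.exp(-0.5 * x * x) * 0.3989422804014327
    return g * (phi + x * pdf)


def softmax_inplace(x: np.ndarray) -> None:
    """Row softmax over the last axis, in place."""
    x2 = x.reshape(-1, x.shape[-1])
    if HAVE_NUMBA:
        _softmax_rows(x2)
    else:
        x2 -= x2.max(axis=-1, keepdims=True)
        np.exp(x2, out=x2)
        x2 /= x2.sum(axis=-1, keepdims=True)


def softmax_backward_inplace(p: np.ndarray, gp: np.ndarray, scale: float) -> None:
    """Overwrite ``gp`` with ``scale * p * (gp - sum(gp * p))`` row-wise."""
    p2 = p.reshape(-1, p.shape[-1])
    g2 = gp.reshape(-1, gp.shape[-1])
    if HAVE_NUMBA:
        _softmax_backward_rows(p2, g2, scale)
    else:
        dot = (g2 * p2).sum(axis=-1, keepdims=True)
        g2 -= dot
        g2 *= p2
        g2 *= scale


def layernorm_forward(x, gamma, beta, eps):
    """Returns (out, xhat, inv_std) with xhat/inv cached for backward."""
    x2 = np.ascontiguousarray(x.reshape(-1, x.shape[-1]))
    if HAVE_NUMBA:
        out = np.empty_like(x2)
        xhat = np.empty_like(x2)
        inv = np.empty(x2.shape[0], dtype=x2.dtype)
        _layernorm_rows(x2, gamma, beta, out, xhat, inv, eps)
        return out.reshape(x.shape), xhat, inv
    mu = x2.mean(axis=-1, keepdims=True)
    xc = x2 - mu
    var = np.mean(xc * xc, axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma + beta
    return out.reshape(x.shape), xhat, inv[:, 0]


def layernorm_backward(g, gamma, xhat, inv, ggamma, gbeta):
    """Returns input grad; accumulates ggamma/gbeta in place."""
    g2 = np.ascontiguousarray(g.reshape(-1, g.shape[-1]))
    if HAVE_NUMBA:
        gx = np.empty_like(g2)
        _layernorm_backward_rows(g2, gamma, xhat, inv, ggamma, gbeta, gx)
        return gx.reshape(g.shape)
    gxh = g2 * gamma
    ggamma += (g2 * xhat).sum(axis=0)
    gbeta += g2.sum(axis=0)
    m1 = gxh.mean(axis=-1, keepdims=True)
    m2 = (gxh * xhat).mean(axis=-1, keepdims=True)
    gx = inv[:, None] * (gxh - m1 - xhat * m2)
    return gx.reshape(g.shape)
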