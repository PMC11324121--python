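"""Minimal reverse-mode neural-network layers on NumPy.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in-place during ``backward``.  All
parameters are float32 by default (``DTYPE``); gradient-check tests swap
``DTYPE`` to float64 before building layers.

The layer set is exactly what a pre-norm transformer needs: linear maps,
layer normalisation, GELU, multi-head self-attention and the residual
block, plus AdamW and global-norm gradient clipping.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

from . import _kernels

DTYPE = np.float32

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Param:
    """A trainable array with an accumulated gradient.

    ``decay`` marks whether AdamW applies weight decay to it (biases,
    normalisation affines and learned tokens are conventionally exempt).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value, decay=True, name=""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name

    @property
    def size(self):
        return self.value.size


def trunc_normal(rng: np.random.Generator, shape, std=0.02):
    """Truncated-normal init: N(0, std) resampled into [-2 std, 2 std]."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(DTYPE)


class Module:
    """Base class: parameter collection and train/eval bookkeeping."""

    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state_dict(self, prefix=""):
        state = {}
        i = 0
        for p in self.params():
            state[f"{prefix}p{i:04d}"] = p.value
            i += 1
        return state

    def load_state_dict(self, state, prefix=""):
        for i, p in enumerate(self.params()):
            v = np.asarray(state[f"{prefix}p{i:04d}"])
            if v.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint shape {v.shape} != parameter shape {p.value.shape}"
                )
            p.value = v.astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)

    def copy_values(self):
        return [p.value.copy() for p in self.params()]

    def set_values(self, values):
        for p, v in zip(self.params(), values, strict=True):
            p.value = v.copy()

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class Linear(Module):
    def __init__(self, d_in, d_out, rng, std=0.02, bias=True):
        self.w = Param(trunc_normal(rng, (d_in, d_out), std=std))
        self.b = Param(np.zeros(d_out), decay=False) if bias else None
        self._x = None

    def forward(self, x):
        self._x = x
        y = x @ self.w.value
        if self.b is not None:
            y += self.b.value
        return y

    def backward(self, g):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.w.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return g @ self.w.value.T


class LayerNorm(Module):
    def __init__(self, d, eps=1e-6):
        self.gamma = Param(np.ones(d), decay=False)
        self.beta = Param(np.zeros(d), decay=False)
        self.eps = eps
        self._xhat = None
        self._inv = None

    def forward(self, x):
        out, self._xhat, self._inv = _kernels.layernorm_forward(
            x, self.gamma.value, self.beta.value, self.eps
        )
        return out

    def backward(self, g):
        return _kernels.layernorm_backward(
            g, self.gamma.value, self._xhat, self._inv,
            self.gamma.grad, self.beta.grad,
        )


class GELU(Module):
    """Exact (erf) Gaussian error linear unit."""

    def __init__(self):
        self._x = None
        self._phi = None

    def forward(self, x):
        self._x = x
        out, self._phi = _kernels.gelu_forward(x)
        return out

    def backward(self, g):
        return _kernels.gelu_backward(self._x, self._phi, g)


class MultiHeadSelfAttention(Module):
    def __init__(self, d, n_heads, rng):
        if d % n_heads != 0:
            raise ValueError(f"embed dim {d} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.scale = 1.0 / math.sqrt(self.d_head)
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)
        self._cache = None

    def forward(self, x):
        b, s, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv.forward(x).reshape(b, s, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]           # each (b, h, s, dh)
        att = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        _kernels.softmax_inplace(att)
        out = att @ v                              # (b, h, s, dh)
        self._cache = (q, k, v, att)
        y = out.transpose(0, 2, 1, 3).reshape(b, s, d)
        return self.proj.forward(y)

    def backward(self, g):
        q, k, v, att = self._cache
        b, h, s, dh = q.shape
        gy = self.proj.backward(g)
        gout = gy.reshape(b, s, h, dh).transpose(0, 2, 1, 3)
        gatt = gout @ v.transpose(0, 1, 3, 2)
        gv = att.transpose(0, 1, 3, 2) @ gout
        _kernels.softmax_backward_inplace(att, gatt, self.scale)
        gs = gatt
        gq = gs @ k
        gk = gs.transpose(0, 1, 3, 2) @ q
        gqkv = np.stack([gq, gk, gv])              # (3, b, h, s, dh)
        gqkv = gqkv.transpose(1, 3, 0, 2, 4).reshape(b, s, 3 * h * dh)
        return self.qkv.backward(gqkv)


class MLP(Module):
    def __init__(self, d, hidden, rng):
        self.fc1 = Linear(d, hidden, rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, d, rng)

    def forward(self, x):
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, g):
        return self.fc1.backward(self.act.backward(self.fc2.backward(g)))


class TransformerBlock(Module):
    """Pre-norm residual block: x + attn(ln(x)), then x + mlp(ln(x))."""

    def __init__(self, d, n_heads, rng, mlp_ratio=4):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.mlp = MLP(d, int(d * mlp_ratio), rng)

    def forward(self, x):
        x = x + self.attn.forward(self.ln1.forward(x))
        return x + self.mlp.forward(self.ln2.forward(x))

    def backward(self, g):
        g = g + self.ln2.backward(self.mlp.backward(g))
        return g + self.ln1.backward(self.attn.backward(g))


class Sequential(Module):
    def __init__(self, blocks):
        self.blocks = list(blocks)

    def forward(self, x):
        for blk in self.blocks:
            x = blk.forward(x)
        return x

    def backward(self, g):
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return g


def clip_grad_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            p.grad *= scale
    return norm


class AdamW:
    """Decoupled-weight-decay Adam.  ``weight_decay=0`` gives plain Adam."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def sincos_1d(dim: int, positions: np.ndarray) -> np.ndarray:
    """Standard fixed sine/cosine embedding for integer positions."""
    if dim % 2 != 0:
        raise ValueError("sincos embedding dim must be even")
    omega = 1.0 / (10000 ** (np.arange(dim // 2, dtype=np.float64) / (dim / 2)))
    angles = np.asarray(positions, dtype=np.float64)[:, None] * omega[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)


def sincos_2d_grid(dim: int, n_rows: int, n_cols: int) -> np.ndarray:
    """2-D sine/cosine embedding over a (rows, cols) grid, row-major order.

    Half the channels encode the row coordinate (lead index), half the
    column coordinate (time index) — the grid analogue of the image MAE's
    positional code.
    """
    if dim % 4 != 0:
        raise ValueError("2-D sincos embedding dim must be divisible by 4")
    rows = np.repeat(np.arange(n_rows), n_cols)
    cols = np.tile(np.arange(n_cols), n_rows)
    emb = np.concatenate(
        [sincos_1d(dim // 2, rows), sincos_1d(dim // 2, cols)], axis=1
    )
    return emb.astype(DTYPE)
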