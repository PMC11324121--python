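"""ViT encoder, MAE decoder and the masked-reconstruction objective.

The encoder embeds each visible 1x250 patch, adds fixed 2-D sinusoidal
positional codes over the (12 leads, 20 windows) grid, prepends a
classification token and runs pre-norm transformer blocks.  Only visible
patches ever enter the encoder; the decoder receives the full 240-token
sequence after mask tokens are inserted at the hidden positions and the
sequence is restored to canonical order.  The reconstruction loss is the
mean squared error over masked patches only.

Size presets follow the standard ViT family (Tiny for desk-scale tests,
Base/Large/Huge as published); the decoder default is the lightweight
512-dim, 8-block design of the original masked autoencoder.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .patching import MaskSpec, N_PATCHES, PATCH_LENGTH, N_LEADS, PATCHES_PER_LEAD


@dataclass(frozen=True)
class EncoderConfig:
    name: str = "tiny"
    embed_dim: int = 192
    depth: int = 4
    n_heads: int = 3
    mlp_ratio: int = 4
    patch_input_dim: int = PATCH_LENGTH

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by {self.n_heads} heads"
            )


ENCODER_PRESETS = {
    "tiny": EncoderConfig("tiny", 192, 4, 3),
    "base": EncoderConfig("base", 768, 12, 12),
    "large": EncoderConfig("large", 1024, 24, 16),
    "huge": EncoderConfig("huge", 1280, 32, 16),
}


@dataclass(frozen=True)
class DecoderConfig:
    embed_dim: int = 512
    depth: int = 8
    n_heads: int = 16
    output_dim: int = PATCH_LENGTH

    def __post_init__(self):
        if self.output_dim != PATCH_LENGTH:
            raise ValueError("decoder output_dim must equal the patch length")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("decoder embed_dim not divisible by n_heads")


DECODER_PRESETS = {
    "default": DecoderConfig(),
    "tiny": DecoderConfig(embed_dim=64, depth=2, n_heads=4),
}


def encoder_config(preset: str | EncoderConfig) -> EncoderConfig:
    if isinstance(preset, EncoderConfig):
        return preset
    try:
        return ENCODER_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown encoder preset {preset!r}") from None


class ViTEncoder(nn.Module):
    """Patch-token transformer with a classification token.

    Positional embeddings are fixed (untrained) 2-D sinusoids over the
    lead/time grid; the classification token carries a zero positional
    code.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        d = cfg.embed_dim
        self.embed = nn.Linear(cfg.patch_input_dim, d, rng)
        self.cls_token = nn.Param(nn.trunc_normal(rng, (d,)), decay=False)
        self.pos = nn.sincos_2d_grid(d, N_LEADS, PATCHES_PER_LEAD)  # fixed
        self.blocks = nn.Sequential(
            [nn.TransformerBlock(d, cfg.n_heads, rng, cfg.mlp_ratio)
             for _ in range(cfg.depth)]
        )
        self.norm = nn.LayerNorm(d)

    def forward_tokens(self, patches: np.ndarray, patch_idx: np.ndarray
                       ) -> np.ndarray:
        """Encode patches at grid positions ``patch_idx``.

        ``patches`` is (batch, n, 250); ``patch_idx`` is (n,) or
        (batch, n).  Returns (batch, n + 1, embed_dim) with the
        classification token first.
        """
        b = patches.shape[0]
        x = self.embed.forward(patches.astype(self.embed.w.value.dtype))
        x = x + self.pos[patch_idx]
        cls = np.broadcast_to(self.cls_token.value, (b, 1, x.shape[-1]))
        x = np.concatenate([cls, x], axis=1)
        x = self.blocks.forward(x)
        return self.norm.forward(x)

    def backward_tokens(self, g_tokens: np.ndarray) -> np.ndarray:
        """Backprop through :meth:`forward_tokens`; returns patch grads."""
        g = self.norm.backward(g_tokens)
        g = self.blocks.backward(g)
        self.cls_token.grad += g[:, 0].sum(axis=0)
        return self.embed.backward(g[:, 1:])


class MAEDecoder(nn.Module):
    def __init__(self, enc_dim: int, cfg: DecoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        dd = cfg.embed_dim
        self.embed = nn.Linear(enc_dim, dd, rng)
        self.mask_token = nn.Param(nn.trunc_normal(rng, (dd,)), decay=False)
        grid_pos = nn.sincos_2d_grid(dd, N_LEADS, PATCHES_PER_LEAD)
        self.pos = np.concatenate(
            [np.zeros((1, dd), dtype=grid_pos.dtype), grid_pos]
        )  # cls slot first, fixed
        self.blocks = nn.Sequential(
            [nn.TransformerBlock(dd, cfg.n_heads, rng) for _ in range(cfg.depth)]
        )
        self.norm = nn.LayerNorm(dd)
        self.head = nn.Linear(dd, cfg.output_dim, rng)


class MAEModel(nn.Module):
    """Encoder–decoder pair for masked ECG reconstruction."""

    def __init__(self, enc_cfg: EncoderConfig, dec_cfg: DecoderConfig,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = ViTEncoder(enc_cfg, rng)
        self.decoder = MAEDecoder(enc_cfg.embed_dim, dec_cfg, rng)
        self._cache = None

    # -- inference-style API -------------------------------------------

    def encode_visible(self, visible_patches: np.ndarray, mask: MaskSpec
                       ) -> np.ndarray:
        """Encode only the visible patches of one record (or a batch).

        Output is (batch, n_visible + 1, embed_dim) and depends solely on
        the visible patches, their grid positions and the parameters —
        masked patch contents cannot influence it.
        """
        patches = np.asarray(visible_patches)
        squeeze = patches.ndim == 2
        if squeeze:
            patches = patches[None]
        if patches.shape[1] != mask.n_visible:
            raise ValueError(
                f"{patches.shape[1]} patches given but mask has "
                f"{mask.n_visible} visible positions"
            )
        tokens = self.encoder.forward_tokens(patches, mask.visible_indices)
        return tokens[0] if squeeze else tokens

    def decode_full(self, tokens: np.ndarray, mask: MaskSpec) -> np.ndarray:
        """Decode encoder tokens into one 250-vector per grid position.

        Mask tokens are inserted at masked positions, the sequence is
        restored to canonical (lead-major) order, decoded, and the
        classification slot dropped: output (batch, 240, 250).
        """
        squeeze = tokens.ndim == 2
        if squeeze:
            tokens = tokens[None]
        if tokens.shape[1] != mask.n_visible + 1:
            raise ValueError("token count does not match mask")
        pred = self._decode(tokens, mask.visible_indices[None].repeat(
            tokens.shape[0], axis=0))
        return pred[0] if squeeze else pred

    def reconstruct(self, patch_set, mask: MaskSpec) -> np.ndarray:
        """Convenience: encode-then-decode a full record's patches."""
        patches = patch_set.patches if hasattr(patch_set, "patches") else patch_set
        visible = patches[mask.visible_indices]
        tokens = self.encode_visible(visible, mask)
        return self.decode_full(tokens, mask)

    # -- training path --------------------------------------------------

    def _decode(self, tokens: np.ndarray, visible_idx: np.ndarray) -> np.ndarray:
        dec = self.decoder
        b, nv1, _ = tokens.shape
        y = dec.embed.forward(tokens)
        dd = y.shape[-1]
        full = np.broadcast_to(dec.mask_token.value,
                               (b, N_PATCHES + 1, dd)).copy()
        full[:, 0] = y[:, 0]
        rows = np.arange(b)[:, None]
        full[rows, 1 + visible_idx] = y[:, 1:]
        full += dec.pos
        z = dec.blocks.forward(full)
        z = dec.norm.forward(z)
        z = dec.head.forward(z)
        self._cache = (visible_idx, b, nv1)
        return z[:, 1:, :]

    def forward_batch(self, patches: np.ndarray, visible_idx: np.ndarray
                      ) -> np.ndarray:
        """Training forward: per-record visible sets, batched.

        ``patches`` is (batch, 240, 250); ``visible_idx`` is
        (batch, n_visible).  Returns predictions (batch, 240, 250).
        """
        rows = np.arange(patches.shape[0])[:, None]
        visible = patches[rows, visible_idx]
        tokens = self.encoder.forward_tokens(visible, visible_idx)
        return self._decode(tokens, visible_idx)

    def backward_batch(self, g_pred: np.ndarray) -> None:
        visible_idx, b, nv1 = self._cache
        dec = self.decoder
        gz = np.concatenate(
            [np.zeros_like(g_pred[:, :1]), g_pred], axis=1
        )
        g = dec.head.backward(gz)
        g = dec.norm.backward(g)
        g_full = dec.blocks.backward(g)
        rows = np.arange(b)[:, None]
        gy = np.empty((b, nv1, g_full.shape[-1]), dtype=g_full.dtype)
        gy[:, 0] = g_full[:, 0]
        gy[:, 1:] = g_full[rows, 1 + visible_idx]
        # everything not routed to an encoded token flowed into the mask token
        dec.mask_token.grad += (
            g_full[:, 1:].sum(axis=(0, 1)) - gy[:, 1:].sum(axis=(0, 1))
        )
        g_tokens = dec.embed.backward(gy)
        self.encoder.backward_tokens(g_tokens)


def build_model(enc: str | EncoderConfig = "tiny",
                dec: str | DecoderConfig = "default",
                seed: int = 0) -> MAEModel:
    """Construct an MAE with deterministic, seeded initialisation."""
    enc_cfg = encoder_config(enc)
    dec_cfg = DECODER_PRESETS[dec] if isinstance(dec, str) else dec
    return MAEModel(enc_cfg, dec_cfg, seed=seed)


def count_params(obj, scope: str = "encoder") -> int:
    """Trainable parameter count.

    For an :class:`EncoderConfig` the count is computed in closed form
    from the layer shapes; for built models the parameter arrays are
    summed.  ``scope`` selects ``encoder`` or ``full`` (encoder plus
    decoder) on model objects.
    """
    if isinstance(obj, (str, EncoderConfig)):
        cfg = encoder_config(obj)
        d, r = cfg.embed_dim, cfg.mlp_ratio
        patch_embed = cfg.patch_input_dim * d + d
        cls = d
        block = (
            2 * d                      # ln1
            + d * 3 * d + 3 * d        # qkv
            + d * d + d                # attention projection
            + 2 * d                    # ln2
            + d * r * d + r * d        # mlp in
            + r * d * d + d            # mlp out
        )
        return patch_embed + cls + cfg.depth * block + 2 * d
    if isinstance(obj, MAEModel):
        enc = obj.encoder.n_params()
        if scope == "encoder":
            return enc
        return enc + obj.decoder.n_params()
    if isinstance(obj, nn.Module):
        return obj.n_params()
    raise TypeError(f"cannot count parameters of {type(obj)}")


def mae_loss(pred: np.ndarray, target, mask, normalize_per_patch: bool = False,
             return_grad: bool = False):
    """Mean squared error over masked patches only.

    ``pred`` and ``target`` are (..., 240, 250); ``mask`` is a
    :class:`MaskSpec` or a boolean masked-position array broadcastable to
    the patch axis.  With ``normalize_per_patch`` each target patch is
    centered and scaled by its own mean/SD before comparison.
    """
    target = target.patches if hasattr(target, "patches") else np.asarray(target)
    pred = np.asarray(pred)
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")
    if isinstance(mask, MaskSpec):
        maskb = mask.bool_mask()
    else:
        maskb = np.asarray(mask, dtype=bool)
    n_masked = int(maskb.sum()) if maskb.ndim == 1 else int(maskb.sum())
    if n_masked == 0:
        raise ValueError("loss undefined with an empty masked set")
    if pred.ndim == 3 and maskb.ndim == 1:
        maskb = np.broadcast_to(maskb, pred.shape[:2])
        n_masked = int(maskb.sum())
    elif pred.ndim == 3:
        n_masked = int(maskb.sum())
    if normalize_per_patch:
        mu = target.mean(axis=-1, keepdims=True)
        sd = target.std(axis=-1, keepdims=True)
        target = (target - mu) / np.maximum(sd, 1e-6)
    diff = pred - target
    w = maskb[..., None]
    denom = n_masked * pred.shape[-1]
    loss = float(np.sum((diff * diff) * w, dtype=np.float64) / denom)
    if return_grad:
        grad = ((2.0 / denom) * (diff * w)).astype(pred.dtype)
        return loss, grad
    return loss


class ECGClassifier(nn.Module):
    """Encoder plus a two-layer sigmoid head for (multi-)label tasks.

    The record representation is the mean over patch tokens after the
    encoder's final layer normalisation (``pool='cls'`` uses the
    classification token instead), followed by
    ``Linear(d, hidden) -> GELU -> Linear(hidden, n_outputs) -> sigmoid``.
    """

    def __init__(self, encoder: ViTEncoder, n_outputs: int, hidden: int = 128,
                 pool: str = "mean", seed: int = 0):
        if n_outputs < 1:
            raise ValueError("n_outputs must be at least 1")
        if pool not in ("mean", "cls"):
            raise ValueError(f"unknown pooling {pool!r}")
        rng = np.random.default_rng(seed)
        self.encoder = encoder
        self.pool = pool
        self.fc1 = nn.Linear(encoder.cfg.embed_dim, hidden, rng)
        self.act = nn.GELU()
        self.fc2 = nn.Linear(hidden, n_outputs, rng)
        self.n_outputs = n_outputs
        self._cache = None

    def forward_logits(self, patches: np.ndarray) -> np.ndarray:
        """``patches``: (batch, 240, 250) -> logits (batch, n_outputs)."""
        tokens = self.encoder.forward_tokens(patches, np.arange(N_PATCHES))
        if self.pool == "mean":
            pooled = tokens[:, 1:].mean(axis=1)
        else:
            pooled = tokens[:, 0]
        self._cache = tokens.shape
        return self.fc2.forward(self.act.forward(self.fc1.forward(pooled)))

    def backward_logits(self, g_logits: np.ndarray) -> None:
        g = self.fc1.backward(self.act.backward(self.fc2.backward(g_logits)))
        b, s, d = self._cache
        g_tokens = np.zeros((b, s, d), dtype=g.dtype)
        if self.pool == "mean":
            g_tokens[:, 1:] = g[:, None, :] / (s - 1)
        else:
            g_tokens[:, 0] = g
        self.encoder.backward_tokens(g_tokens)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 64
                      ) -> np.ndarray:
        """Sigmoid probabilities, batched for memory friendliness."""
        outs = []
        for i in range(0, patches.shape[0], batch_size):
            z = self.forward_logits(patches[i : i + batch_size])
            outs.append(_sigmoid(z))
        return np.concatenate(outs, axis=0)

    def bce_loss_and_grad(self, patches: np.ndarray, labels: np.ndarray
                          ) -> float:
        """Mean binary cross-entropy; accumulates parameter gradients."""
        z = self.forward_logits(patches)
        y = np.asarray(labels, dtype=np.float64).reshape(z.shape)
        z64 = z.astype(np.float64)
        # stable softplus(z) - y z
        loss = float(np.mean(np.logaddexp(0.0, z64) - y * z64))
        p = _sigmoid(z64)
        g = ((p - y) / y.size).astype(z.dtype)
        self.backward_logits(g)
        return loss

    def bce_loss(self, patches: np.ndarray, labels: np.ndarray,
                 batch_size: int = 64) -> float:
        total, n = 0.0, 0
        for i in range(0, patches.shape[0], batch_size):
            z = self.forward_logits(patches[i : i + batch_size]).astype(np.float64)
            y = np.asarray(labels[i : i + batch_size],
                           dtype=np.float64).reshape(z.shape)
            total += float(np.sum(np.logaddexp(0.0, z) - y * z))
            n += z.size
        return total / n


def _sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def attach_head(encoder_or_model, n_outputs: int, hidden: int = 128,
                pool: str = "mean", seed: int = 0, copy: bool = False
                ) -> ECGClassifier:
    """Build a classifier on top of a (pretrained or fresh) encoder.

    With ``copy=True`` the encoder weights are deep-copied so fine-tuning
    leaves the original untouched.
    """
    import copy as _copy

    encoder = (encoder_or_model.encoder
               if isinstance(encoder_or_model, MAEModel) else encoder_or_model)
    if copy:
        encoder = _copy.deepcopy(encoder)
    return ECGClassifier(encoder, n_outputs, hidden=hidden, pool=pool, seed=seed)


# -- checkpoints --------------------------------------------------------

def save_checkpoint(model: nn.Module, path, config: dict | None = None) -> None:
    """Single-file archive: parameter arrays plus an embedded config JSON."""
    state = model.state_dict()
    meta = dict(config or {})
    if isinstance(model, MAEModel):
        meta.setdefault("encoder", asdict(model.encoder.cfg))
        meta.setdefault("decoder", asdict(model.decoder.cfg))
        meta.setdefault("kind", "mae")
    np.savez(Path(path), __config__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[MAEModel, dict]:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appended it
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__config__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    enc_cfg = EncoderConfig(**meta["encoder"])
    dec_cfg = DecoderConfig(**meta["decoder"])
    model = MAEModel(enc_cfg, dec_cfg, seed=0)
    model.load_state_dict(state)
    return model, meta
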