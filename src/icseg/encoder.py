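"""Shared ViT encoder with window attention and the information-bottleneck neck.

Images and binary masks pass through the *same* encoder weights: a mask enters
as a {0,1}-intensity image.  Window attention (non-overlapping spatial windows
with zero padding masked out of the softmax) replaces global attention at the
configured layers; whenever one window covers the whole token grid, the global
code path is taken so the two are bit-identical.  The neck compresses the
high-dimensional ViT embedding to a compact per-image feature map via a 1x1
convolution, layer norm, 3x3 same-padding convolution, and a second layer norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor

__all__ = [
    "ModelConfig",
    "patchify",
    "unpatchify",
    "window_partition",
    "window_unpartition",
    "Linear",
    "LayerNorm",
    "SelfAttention",
    "TransformerBlock",
    "ViTEncoder",
    "Neck",
]

NEG_INF = -1e9  # additive mask value; exp underflows to exactly 0 after shift


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 256x256 inputs, 16x16
    patches, a 12-layer ViT-Base encoder with 7x7 window attention at layers
    2, 5, 8, 11 (1-based), a 256-wide bottleneck neck, and a 12-layer
    GPT-2-small-shaped decoder supporting up to n_max = 7 prompt pairs.
    """

    image_size: int = 256
    patch_size: int = 16
    channels: int = 1
    enc_layers: int = 12
    enc_dim: int = 768
    enc_heads: int = 12
    window_size: int = 7
    window_layers: tuple = (2, 5, 8, 11)  # 1-based layer indices
    neck_dim: int = 256
    dec_layers: int = 12
    dec_dim: int = 768
    dec_heads: int = 12
    n_max: int = 7
    mlp_ratio: float = 4.0
    # expected foreground fraction; the head's foreground logit is initialized
    # at its log-odds so training starts at the class-prior equilibrium
    # instead of traversing a collapse-to-background transient
    fg_prior: float = 0.1

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size={self.image_size} not divisible by patch_size={self.patch_size}"
            )
        bad = [i for i in self.window_layers if not (1 <= i <= self.enc_layers)]
        if bad:
            raise ValueError(f"window_layers {bad} outside 1..{self.enc_layers}")
        if self.enc_dim % self.enc_heads or self.dec_dim % self.dec_heads:
            raise ValueError("embedding widths must be divisible by head counts")
        if self.window_size < 1 or self.n_max < 1:
            raise ValueError("window_size and n_max must be >= 1")
        if not (0 < self.fg_prior < 1):
            raise ValueError("fg_prior must be in (0, 1)")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def tokens_per_image(self) -> int:
        return self.grid_size**2

    @classmethod
    def miniature(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: 64px images, 4+4 layers, width 128, n_max 3."""
        base = dict(
            image_size=64, patch_size=8, enc_layers=4, enc_dim=128, enc_heads=4,
            window_size=8, window_layers=(2, 4), neck_dim=128, dec_layers=4,
            dec_dim=128, dec_heads=4, n_max=3,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Smallest testable preset: 32px images, 2+2 layers, width 64."""
        base = dict(
            image_size=32, patch_size=8, enc_layers=2, enc_dim=64, enc_heads=2,
            window_size=4, window_layers=(2,), neck_dim=64, dec_layers=2,
            dec_dim=64, dec_heads=2, n_max=3,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# patch and window bookkeeping (pure numpy)
# ---------------------------------------------------------------------------

def patchify(arr: np.ndarray, patch_size: int) -> np.ndarray:
    """(H, W) -> (h, w, patch_size^2) non-overlapping patches, row-major."""
    H, W = arr.shape[-2:]
    if H % patch_size or W % patch_size:
        raise ValueError(f"shape {(H, W)} not divisible by patch size {patch_size}")
    h, w = H // patch_size, W // patch_size
    lead = arr.shape[:-2]
    x = arr.reshape(*lead, h, patch_size, w, patch_size)
    x = np.moveaxis(x, -3, -2)  # (..., h, w, p, p)
    return x.reshape(*lead, h, w, patch_size * patch_size)


def unpatchify(tokens: np.ndarray, patch_size: int) -> np.ndarray:
    """Inverse of patchify: (..., h, w, p^2) -> (..., h*p, w*p)."""
    *lead, h, w, pp = tokens.shape
    if pp != patch_size * patch_size:
        raise ValueError("token width does not match patch_size^2")
    x = tokens.reshape(*lead, h, w, patch_size, patch_size)
    x = np.moveaxis(x, -2, -3)  # (..., h, p, w, p)
    return x.reshape(*lead, h * patch_size, w * patch_size)


def window_partition(grid: np.ndarray, window_size: int):
    """Split an (h, w, c) token grid into non-overlapping windows.

    Zero-pads to the next window multiple; returns (windows, pad_record) with
    windows of shape (n_windows, window_size, window_size, c) and pad_record
    = (h, w, pad_h, pad_w) for exact inversion.
    """
    h, w, c = grid.shape
    ws = window_size
    pad_h = (-h) % ws
    pad_w = (-w) % ws
    padded = np.pad(grid, ((0, pad_h), (0, pad_w), (0, 0)))
    hh, ww = h + pad_h, w + pad_w
    x = padded.reshape(hh // ws, ws, ww // ws, ws, c).transpose(0, 2, 1, 3, 4)
    return x.reshape(-1, ws, ws, c), (h, w, pad_h, pad_w)


def window_unpartition(windows: np.ndarray, window_size: int, pad_record) -> np.ndarray:
    """Inverse of window_partition; crops the padding exactly."""
    h, w, pad_h, pad_w = pad_record
    ws = window_size
    hh, ww = h + pad_h, w + pad_w
    c = windows.shape[-1]
    x = windows.reshape(hh // ws, ww // ws, ws, ws, c).transpose(0, 2, 1, 3, 4)
    return x.reshape(hh, ww, c)[:h, :w]


def window_pad_bias(h: int, w: int, window_size: int, dtype=np.float32) -> np.ndarray | None:
    """Additive key bias masking padded tokens, per window: (n_windows, ws*ws)."""
    ws = window_size
    pad_h = (-h) % ws
    pad_w = (-w) % ws
    if pad_h == 0 and pad_w == 0:
        return None
    real = np.ones((h, w, 1), dtype=dtype)
    win, _ = window_partition(real, ws)
    flat = win.reshape(win.shape[0], ws * ws)
    return np.where(flat > 0, 0.0, NEG_INF).astype(dtype)


# ---------------------------------------------------------------------------
# neural building blocks
# ---------------------------------------------------------------------------

def _init_weight(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, std: float = 0.02):
        self.weight = Parameter(_init_weight(rng, (d_in, d_out), std))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gain, self.bias, eps=self.eps)


class SelfAttention(Module):
    """Multi-head scaled dot-product self-attention with an additive bias mask."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, bias: np.ndarray | None = None) -> Tensor:
        B, S, d = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x)  # (B, S, 3d)
        qkv = ad.reshape(qkv, (B, S, 3, h, hd))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, h, S, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scale = Tensor(np.asarray(1.0 / math.sqrt(hd), dtype=x.dtype))
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * scale  # (B, h, S, S)
        if bias is not None:
            scores = scores + Tensor(bias.astype(x.dtype, copy=False))
        attn = ad.softmax(scores, axis=-1)
        out = ad.matmul(attn, v)  # (B, h, S, hd)
        out = ad.transpose(out, (0, 2, 1, 3))
        out = ad.reshape(out, (B, S, d))
        return self.proj(out)


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-norm block: x + Attn(LN(x)), then x + MLP(LN(x)).

    With ``window_size`` set (and a grid given) attention is restricted to
    non-overlapping spatial windows; padding tokens are masked out of the
    softmax and cropped on exit.  When one window covers the grid the global
    path runs unchanged.
    """

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng)

    def __call__(
        self,
        x: Tensor,
        grid: tuple[int, int] | None = None,
        window_size: int | None = None,
        attn_bias: np.ndarray | None = None,
    ) -> Tensor:
        normed = self.norm1(x)
        if window_size is not None and grid is not None:
            h, w = grid
            if window_size >= h and window_size >= w:
                attended = self.attn(normed, bias=attn_bias)
            else:
                attended = self._windowed(normed, h, w, window_size)
        else:
            attended = self.attn(normed, bias=attn_bias)
        x = x + attended
        return x + self.mlp(self.norm2(x))

    def _windowed(self, x: Tensor, h: int, w: int, ws: int) -> Tensor:
        B, S, d = x.shape
        pad_h = (-h) % ws
        pad_w = (-w) % ws
        hh, ww = h + pad_h, w + pad_w
        g = ad.reshape(x, (B, h, w, d))
        if pad_h or pad_w:
            g = ad.pad(g, [(0, 0), (0, pad_h), (0, pad_w), (0, 0)])
        nh, nw = hh // ws, ww // ws
        g = ad.reshape(g, (B, nh, ws, nw, ws, d))
        g = ad.transpose(g, (0, 1, 3, 2, 4, 5))  # (B, nh, nw, ws, ws, d)
        g = ad.reshape(g, (B * nh * nw, ws * ws, d))
        bias = window_pad_bias(h, w, ws, dtype=x.data.dtype)
        if bias is not None:
            # key-padding bias per window, tiled over the batch and heads
            bias = np.tile(bias[:, None, None, :], (B, 1, 1, 1))
        out = self.attn(g, bias=bias)
        out = ad.reshape(out, (B, nh, nw, ws, ws, d))
        out = ad.transpose(out, (0, 1, 3, 2, 4, 5))
        out = ad.reshape(out, (B, hh, ww, d))
        out = out[:, :h, :w, :]
        return ad.reshape(out, (B, S, d))


# ---------------------------------------------------------------------------
# encoder and neck
# ---------------------------------------------------------------------------

class ViTEncoder(Module):
    """Patch embedding + 2D positional embeddings + pre-norm transformer stack."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        g = config.grid_size
        self.patch_embed = Linear(config.patch_size**2 * config.channels, config.enc_dim, rng)
        self.pos_embed = Parameter(_init_weight(rng, (g * g, config.enc_dim)))
        self.blocks = [
            TransformerBlock(config.enc_dim, config.enc_heads, config.mlp_ratio, rng)
            for _ in range(config.enc_layers)
        ]
        self.windowed = {i - 1 for i in config.window_layers}  # 0-based internally

    def __call__(self, images: np.ndarray) -> Tensor:
        """Encode (B, H, W) images (or masks as {0,1} intensities) to (B, h, w, enc_dim)."""
        images = np.asarray(images, dtype=np.float32)
        single = images.ndim == 2
        if single:
            images = images[None]
        cfg = self.config
        if images.shape[-2:] != (cfg.image_size, cfg.image_size):
            raise ValueError(
                f"expected {cfg.image_size}x{cfg.image_size} inputs, got {images.shape[-2:]}"
            )
        g = cfg.grid_size
        tokens = patchify(images, cfg.patch_size)  # (B, h, w, p^2)
        B = tokens.shape[0]
        x = Tensor(tokens.reshape(B, g * g, cfg.patch_size**2))
        x = self.patch_embed(x) + self.pos_embed
        for i, block in enumerate(self.blocks):
            ws = cfg.window_size if i in self.windowed else None
            x = block(x, grid=(g, g), window_size=ws)
            if not np.isfinite(x.data).all():
                raise FloatingPointError(f"non-finite activations at encoder layer {i + 1}")
        out = ad.reshape(x, (B, g, g, cfg.enc_dim))
        return out if not single else ad.reshape(out, (g, g, cfg.enc_dim))


class Neck(Module):
    """Information bottleneck: 1x1 conv -> LN -> 3x3 conv (same pad) -> LN."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.proj = Linear(config.enc_dim, config.neck_dim, rng)
        self.norm1 = LayerNorm(config.neck_dim)
        self.conv3 = Linear(9 * config.neck_dim, config.neck_dim, rng)
        self.norm2 = LayerNorm(config.neck_dim)

    def __call__(self, features: Tensor) -> Tensor:
        """(..., h, w, enc_dim) -> (..., h, w, neck_dim); spatial shape preserved."""
        x = self.norm1(self.proj(features))
        x = self.norm2(self.conv3(ad.unfold3x3(x)))
        return x
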