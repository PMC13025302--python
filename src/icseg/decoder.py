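"""Image-level autoregressive decoder and the composite segmentation model.

An episode's images and masks are encoded by the shared ViT+neck, flattened
row-major to s = h·w tokens each, and concatenated in interleaved order
[x1, y1, x2, y2, …, (q)].  A decoder-only transformer attends under an
*image-level* causal mask: token i sees every token of its own image and of
all earlier images, never later ones.  Visibility is therefore block-lower-
triangular at image granularity with full diagonal blocks, which preserves
bidirectional spatial context inside each image while keeping the sequence
autoregressive across images.  A linear patch-expansion head maps the decoder
features at an image's token positions to a two-class per-pixel softmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .datamodel import BinaryMask, EpisodeSequence
from .encoder import (
    NEG_INF,
    LayerNorm,
    Linear,
    ModelConfig,
    Neck,
    TransformerBlock,
    ViTEncoder,
)
from .seeding import substream

__all__ = [
    "ImageLevelMask",
    "TokenSequence",
    "ProbabilityMap",
    "AttentionTensors",
    "build_image_level_mask",
    "build_token_level_mask",
    "mask_to_bias",
    "masked_attention",
    "binarize",
    "SegmentationModel",
]


# ---------------------------------------------------------------------------
# attention masks
# ---------------------------------------------------------------------------

@dataclass
class ImageLevelMask:
    """S×S {0,1} visibility matrix, causal at whole-image granularity."""

    M: np.ndarray
    s: int
    image_count: int

    def __post_init__(self):
        S = self.s * self.image_count
        if self.M.shape != (S, S):
            raise ValueError(f"mask shape {self.M.shape} != ({S},{S})")


def build_image_level_mask(image_count: int, s: int) -> ImageLevelMask:
    """Visibility M[i,j] = 1 iff token j belongs to token i's image or earlier.

    Equivalent to the 1-based rule "j ≤ ⌈i/s⌉·s": with 0-based indices,
    M[i,j] = 1 iff ⌊j/s⌋ ≤ ⌊i/s⌋.  For s = 1 this is the standard causal
    lower triangle.
    """
    if image_count < 1 or s < 1:
        raise ValueError("image_count and s must be >= 1")
    img = np.arange(image_count * s) // s
    M = (img[None, :] <= img[:, None]).astype(np.uint8)
    return ImageLevelMask(M=M, s=s, image_count=image_count)


def build_token_level_mask(length: int) -> np.ndarray:
    """Strict token-causal lower triangle (diagonal included) — the contrast
    mask that removes within-image bidirectional visibility."""
    return np.tril(np.ones((length, length), dtype=np.uint8))


def mask_to_bias(M: np.ndarray, dtype=np.float32) -> np.ndarray:
    """{0,1} visibility -> additive pre-softmax bias (0 where visible, -1e9 else)."""
    return np.where(M > 0, 0.0, NEG_INF).astype(dtype)


@dataclass
class AttentionTensors:
    """Per-head query/key/value projections of a token sequence."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray

    @property
    def head_dim(self) -> int:
        return self.Q.shape[-1]


def masked_attention(
    Q: np.ndarray | AttentionTensors,
    K: np.ndarray | None = None,
    V: np.ndarray | None = None,
    mask: ImageLevelMask | np.ndarray | None = None,
) -> np.ndarray:
    """Scaled dot-product attention with additive mask (numpy reference path).

    Masked positions receive -1e9 *before* the softmax so they carry exactly
    zero attention weight; a multiplicative zero on the logits would not
    (softmax(0) ≠ 0).  Output row i is a convex combination of the V rows
    visible to i.  Accepts either (Q, K, V, mask) arrays or an
    AttentionTensors bundle as the first argument.
    """
    if isinstance(Q, AttentionTensors):
        if mask is None:
            mask = K  # masked_attention(tensors, mask) call form
        Q, K, V = Q.Q, Q.K, Q.V
    if K is None or V is None or mask is None:
        raise TypeError("masked_attention requires Q, K, V and a mask")
    M = mask.M if isinstance(mask, ImageLevelMask) else mask
    d = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d) + mask_to_bias(M, Q.dtype)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V


# ---------------------------------------------------------------------------
# sequence and output containers
# ---------------------------------------------------------------------------

@dataclass
class TokenSequence:
    """Flattened per-image features in interleaved order, S = s · image_count."""

    tokens: Tensor  # (1, S, dec_dim)
    s: int
    image_count: int

    @property
    def S(self) -> int:
        return self.s * self.image_count


@dataclass
class ProbabilityMap:
    """Per-pixel foreground probability (two-class softmax, background implied)."""

    fg_prob: np.ndarray

    def __post_init__(self):
        self.fg_prob = np.asarray(self.fg_prob, dtype=np.float32)
        if self.fg_prob.min() < -1e-6 or self.fg_prob.max() > 1 + 1e-6:
            raise ValueError("probabilities outside [0,1]")


def binarize(p: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold the foreground probability; ties (= threshold) go foreground."""
    return BinaryMask((p.fg_prob >= threshold).astype(np.uint8))


# ---------------------------------------------------------------------------
# composite model
# ---------------------------------------------------------------------------

class SegmentationModel(Module):
    """Shared encoder + neck + image-level autoregressive decoder + head.

    The decoder uses learned absolute positional embeddings of length
    s·2·(n_max+1); a shorter sequence (fewer prompt pairs at inference) uses
    the *leading* embeddings, so a k-pair query occupies exactly the slot of
    the (k+1)-th training image — the position whose prediction is supervised
    during training.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = substream(seed, "init")
        self.encoder = ViTEncoder(config, rng)
        self.neck = Neck(config, rng)
        self.dec_in = Linear(config.neck_dim, config.dec_dim, rng)
        s = config.tokens_per_image
        # factorized decoder positions: a per-slot embedding (which image of
        # the sequence, up to 2*(n_max+1) slots) plus a within-image grid
        # embedding shared across slots — the same pixel location carries the
        # same code in every image, which is what lets attention bind a
        # prompt-image token to its mask token at the same location; they are
        # initialized at content-comparable scale (std 0.5 against unit-scale
        # layer-normed features) so position-based attention is expressible
        # from the first step rather than having to be amplified 25x first
        self.dec_pos_slot = Parameter(
            (rng.standard_normal((2 * (config.n_max + 1), config.dec_dim)) * 0.5
             ).astype(np.float32)
        )
        self.dec_pos_grid = Parameter(
            (rng.standard_normal((s, config.dec_dim)) * 0.5).astype(np.float32)
        )
        self.dec_blocks = [
            TransformerBlock(config.dec_dim, config.dec_heads, config.mlp_ratio, rng)
            for _ in range(config.dec_layers)
        ]
        self.dec_norm = LayerNorm(config.dec_dim)
        self.head = Linear(config.dec_dim, config.patch_size**2 * 2, rng)
        # class-prior head init: foreground logits start at the prior's
        # log-odds so the initial prediction is the base rate everywhere
        fg_bias = self.head.bias.data.reshape(-1, 2)
        fg_bias[:, 1] = math.log(config.fg_prior / (1.0 - config.fg_prior))

    # -- encoding ------------------------------------------------------------
    def encode_images(self, images: np.ndarray) -> Tensor:
        """(B, H, W) -> (B, s, dec_dim) via the shared encoder, neck, and entry projection."""
        feats = self.encoder(images)  # (B, h, w, enc_dim)
        feats = self.neck(feats)  # (B, h, w, neck_dim)
        B = feats.shape[0]
        s = self.config.tokens_per_image
        flat = ad.reshape(feats, (B, s, self.config.neck_dim))
        return self.dec_in(flat)

    def _positions(self, m: int) -> Tensor:
        """Decoder positional embeddings for an m-image sequence: (1, m*s, d).

        Shorter sequences use the leading slots, so a k-pair query occupies
        the slot of the (k+1)-th training image."""
        s = self.config.tokens_per_image
        d = self.config.dec_dim
        slot = ad.reshape(self.dec_pos_slot[:m], (m, 1, d))
        grid = ad.reshape(self.dec_pos_grid, (1, s, d))
        return ad.reshape(slot + grid, (1, m * s, d))

    def _episode_images(self, episode: EpisodeSequence) -> np.ndarray:
        arrs = []
        for img, msk in episode.pairs:
            arrs.append(img.pixels)
            arrs.append(msk.labels.astype(np.float32))
        if episode.query is not None:
            arrs.append(episode.query.pixels)
        return np.stack(arrs)

    def assemble_token_sequence(self, episode: EpisodeSequence) -> TokenSequence:
        """Encode every episode member and concatenate in interleaved order."""
        cfg = self.config
        limit = cfg.n_max + 1 if episode.mode == "train" else cfg.n_max
        if episode.n_pairs > limit:
            raise ValueError(
                f"{episode.n_pairs} pairs exceed the positional budget (n_max={cfg.n_max})"
            )
        images = self._episode_images(episode)
        per_image = self.encode_images(images)  # (m, s, dec_dim)
        m = per_image.shape[0]
        s = cfg.tokens_per_image
        seq = ad.reshape(per_image, (1, m * s, cfg.dec_dim))
        seq = seq + self._positions(m)
        return TokenSequence(tokens=seq, s=s, image_count=m)

    # -- decoding ------------------------------------------------------------
    def decode_sequence(self, seq: TokenSequence) -> Tensor:
        """Run the decoder stack under the image-level mask; (1, S, dec_dim) out."""
        return self._decode(seq.tokens, image_count=seq.image_count, s=seq.s)

    def _decode(self, tokens: Tensor, image_count: int, s: int) -> Tensor:
        mask = build_image_level_mask(image_count, s)
        bias = mask_to_bias(mask.M)[None, None]  # (1, 1, S, S), broadcast over batch
        x = tokens
        for i, block in enumerate(self.dec_blocks):
            x = block(x, attn_bias=bias)
            if not np.isfinite(x.data).all():
                raise FloatingPointError(f"non-finite activations at decoder layer {i + 1}")
        return self.dec_norm(x)

    def segmentation_head(self, features: Tensor) -> Tensor:
        """Features at one image's s token positions -> (H, W, 2) softmax map."""
        cfg = self.config
        g, p = cfg.grid_size, cfg.patch_size
        logits = self.head(features)  # (s, p^2 * 2)
        logits = ad.reshape(logits, (g, g, p, p, 2))
        logits = ad.transpose(logits, (0, 2, 1, 3, 4))  # (h, p, w, p, 2)
        logits = ad.reshape(logits, (g * p, g * p, 2))
        return ad.softmax(logits, axis=-1)

    # -- end-to-end ----------------------------------------------------------
    def forward_train(self, episode: EpisodeSequence) -> list[Tensor]:
        """Multi-position probabilities at images x_2..x_{n+1} of a training episode."""
        return self.forward_train_batch([episode])[0]

    def forward_train_batch(self, episodes: list[EpisodeSequence]) -> list[list[Tensor]]:
        """Batched multi-position forward: one decoder pass over B episodes.

        All episodes must share the same pair count; returns, per episode, the
        probability maps at supervised positions x_2..x_{n+1}.
        """
        if not episodes:
            raise ValueError("empty batch")
        n_plus_1 = episodes[0].n_pairs
        for ep in episodes:
            if ep.mode != "train":
                raise ValueError("forward_train expects train-mode episodes")
            if ep.n_pairs != n_plus_1:
                raise ValueError("batched episodes must share one pair count")
        cfg = self.config
        if n_plus_1 > cfg.n_max + 1:
            raise ValueError(
                f"{n_plus_1} pairs exceed the positional budget (n_max={cfg.n_max})"
            )
        B = len(episodes)
        m = 2 * n_plus_1  # images per episode
        s = cfg.tokens_per_image
        images = np.concatenate([self._episode_images(ep) for ep in episodes])
        per_image = self.encode_images(images)  # (B*m, s, dec_dim)
        seq = ad.reshape(per_image, (B, m * s, cfg.dec_dim))
        seq = seq + self._positions(m)
        features = self._decode(seq, image_count=m, s=s)
        outputs: list[list[Tensor]] = []
        for b in range(B):
            per_pos = []
            for i in range(2, n_plus_1 + 1):  # supervised positions (1-based)
                img_idx = 2 * (i - 1)  # 0-based image slot of x_i
                feats_i = ad.reshape(
                    features[b, img_idx * s : (img_idx + 1) * s, :],
                    (s, cfg.dec_dim),
                )
                per_pos.append(self.segmentation_head(feats_i))
            outputs.append(per_pos)
        return outputs

    def predict_query(self, episode: EpisodeSequence) -> ProbabilityMap:
        """Foreground probability for the query of an inference episode."""
        if episode.mode != "infer":
            raise ValueError("predict_query expects an infer-mode episode")
        if not (1 <= episode.n_pairs <= self.config.n_max):
            raise ValueError(
                f"prompt pairs must be in 1..{self.config.n_max}, got {episode.n_pairs}"
            )
        seq = self.assemble_token_sequence(episode)
        features = self.decode_sequence(seq)
        s = seq.s
        q_idx = 2 * episode.n_pairs  # 0-based image slot of the query
        feats_q = ad.reshape(
            features[:, q_idx * s : (q_idx + 1) * s, :], (s, self.config.dec_dim)
        )
        probs = self.segmentation_head(feats_q)
        return ProbabilityMap(probs.data[..., 1])
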