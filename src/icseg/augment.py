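"""Episode-consistent data augmentation.

One augmentation kind is drawn uniformly from the 11-entry set per episode
per epoch and applied — with the *same* sampled parameters — to every member
of the episode (all prompt pairs and the query), with overall application
probability p = 0.5.  Geometric kinds transform images and masks identically;
intensity kinds touch images only; the two label kinds (label complement,
Sobel edge map) deliberately redefine the supervision target for the whole
episode, creating a new, internally consistent task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, shift as nd_shift

from .datamodel import BinaryMask, EpisodeSequence, ImageSlice

__all__ = ["AUGMENTATION_KINDS", "AugmentationEvent", "sample_augmentation", "apply_augmentation"]

AUGMENTATION_KINDS = (
    "flip_intensities",
    "flip_labels",
    "horizontal_flip",
    "vertical_flip",
    "sobel_edge_label",
    "affine_shift",
    "brightness_contrast",
    "elastic_warp",
    "gaussian_blur",
    "gaussian_noise",
    "sharpness",
)

GEOMETRIC_KINDS = {"horizontal_flip", "vertical_flip", "affine_shift", "elastic_warp"}
INTENSITY_KINDS = {"flip_intensities", "brightness_contrast", "gaussian_blur",
                   "gaussian_noise", "sharpness"}
LABEL_KINDS = {"flip_labels", "sobel_edge_label"}


@dataclass(frozen=True)
class AugmentationEvent:
    """One sampled augmentation: kind, whether it fires, and its parameters."""

    kind: str
    applied: bool
    params: dict = field(default_factory=dict)
    seed: int = 0


def sample_augmentation(seed: int, probability: float = 0.5) -> AugmentationEvent:
    """Draw the episode's augmentation: kind uniform over the 11-entry set,
    applied with the given probability, parameters fixed for the episode."""
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    kind = AUGMENTATION_KINDS[int(rng.integers(len(AUGMENTATION_KINDS)))]
    applied = bool(rng.random() < probability)
    params: dict = {}
    if kind == "affine_shift":
        params = {"dr": float(rng.uniform(-0.1, 0.1)), "dc": float(rng.uniform(-0.1, 0.1))}
    elif kind == "brightness_contrast":
        params = {"brightness": float(rng.uniform(-0.2, 0.2)),
                  "contrast": float(rng.uniform(0.7, 1.3))}
    elif kind == "elastic_warp":
        params = {"magnitude": float(rng.uniform(1.0, 4.0)),
                  "field_seed": int(rng.integers(2**31))}
    elif kind == "gaussian_blur":
        params = {"sigma": float(rng.uniform(0.5, 1.5))}
    elif kind == "gaussian_noise":
        params = {"sd": float(rng.uniform(0.01, 0.05)),
                  "noise_seed": int(rng.integers(2**31))}
    elif kind == "sharpness":
        params = {"amount": float(rng.uniform(0.5, 2.0))}
    return AugmentationEvent(kind=kind, applied=applied, params=params, seed=int(seed))


def _elastic_field(size: int, magnitude: float, field_seed: int) -> np.ndarray:
    rng = np.random.default_rng(field_seed)
    f = rng.normal(size=(2, size, size))
    f = gaussian_filter(f, sigma=(0, size / 8.0, size / 8.0))
    peak = np.abs(f).max()
    if peak > 0:
        f *= magnitude / peak
    return f


def _warp_with(arr: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    size = arr.shape[0]
    r, c = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    coords = np.stack([r + disp[0], c + disp[1]])
    return map_coordinates(arr.astype(np.float64), coords, order=order, mode="nearest")


def _geometric(kind: str, arr: np.ndarray, params: dict, is_mask: bool) -> np.ndarray:
    if kind == "horizontal_flip":
        return arr[:, ::-1].copy()
    if kind == "vertical_flip":
        return arr[::-1, :].copy()
    if kind == "affine_shift":
        size = arr.shape[0]
        order = 0 if is_mask else 1
        return nd_shift(arr.astype(np.float64), (params["dr"] * size, params["dc"] * size),
                        order=order, mode="constant", cval=0.0)
    if kind == "elastic_warp":
        disp = _elastic_field(arr.shape[0], params["magnitude"], params["field_seed"])
        return _warp_with(arr, disp, order=0 if is_mask else 1)
    raise ValueError(f"unknown geometric kind {kind!r}")


def _intensity(kind: str, img: np.ndarray, params: dict, member_index: int) -> np.ndarray:
    if kind == "flip_intensities":
        return 1.0 - img
    if kind == "brightness_contrast":
        return params["contrast"] * (img - 0.5) + 0.5 + params["brightness"]
    if kind == "gaussian_blur":
        return gaussian_filter(img, sigma=params["sigma"])
    if kind == "gaussian_noise":
        rng = np.random.default_rng((params["noise_seed"] + member_index) & 0x7FFFFFFF)
        return img + rng.normal(0.0, params["sd"], size=img.shape)
    if kind == "sharpness":
        blurred = gaussian_filter(img, sigma=1.0)
        return img + params["amount"] * (img - blurred)
    raise ValueError(f"unknown intensity kind {kind!r}")


def _label(kind: str, mask: np.ndarray) -> np.ndarray:
    if kind == "flip_labels":
        return 1 - mask
    if kind == "sobel_edge_label":
        from skimage.filters import sobel

        return (sobel(mask.astype(np.float64)) > 0).astype(np.uint8)
    raise ValueError(f"unknown label kind {kind!r}")


def apply_augmentation(event: AugmentationEvent, episode: EpisodeSequence) -> EpisodeSequence:
    """Apply one augmentation event consistently to a whole episode.

    Pure function of (event, episode); identity when event.applied is False.
    Images are re-clipped to [0,1] and masks re-binarized after geometric
    interpolation.
    """
    if event.kind not in AUGMENTATION_KINDS:
        raise ValueError(f"unknown augmentation kind {event.kind!r}")
    if not event.applied:
        return episode

    def aug_image(img: ImageSlice, index: int) -> ImageSlice:
        arr = img.pixels.astype(np.float64)
        if event.kind in GEOMETRIC_KINDS:
            arr = _geometric(event.kind, arr, event.params, is_mask=False)
        elif event.kind in INTENSITY_KINDS:
            arr = _intensity(event.kind, arr, event.params, index)
        return ImageSlice(np.clip(arr, 0.0, 1.0))

    def aug_mask(msk: BinaryMask) -> BinaryMask:
        arr = msk.labels
        if event.kind in GEOMETRIC_KINDS:
            arr = (_geometric(event.kind, arr.astype(np.float64), event.params,
                              is_mask=True) > 0.5).astype(np.uint8)
        elif event.kind in LABEL_KINDS:
            arr = _label(event.kind, arr)
        return BinaryMask(arr)

    pairs = [(aug_image(img, i), aug_mask(msk)) for i, (img, msk) in enumerate(episode.pairs)]
    query = aug_image(episode.query, len(episode.pairs)) if episode.query is not None else None
    return EpisodeSequence(pairs=pairs, class_id=episode.class_id,
                           mode=episode.mode, query=query)
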