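"""Synthetic multi-class "organ" segmentation tasks from parameterized shapes.

Generates scenes in which every configured shape family (ellipse, rectangle,
annulus, crescent, blob) appears once at a random non-overlapping location,
with a class-specific intensity distribution over a smooth background field,
optional elastic deformation and additive Gaussian noise.  Scenes decompose
into per-class binary sub-tasks, so the same query image supports several
valid tasks and the segmentation target is defined only by the prompt — the
property the in-context model is supposed to exploit.

Everything is a pure function of (config, seed): identical inputs give
bit-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .datamodel import BinaryMask, EpisodeSequence, ImageSlice
from .seeding import derive_seed, substream

__all__ = [
    "SHAPE_FAMILIES",
    "SyntheticTaskConfig",
    "generate_shape_sample",
    "generate_scene",
    "generate_scene_dataset",
    "generate_task_dataset",
    "generate_scene_task_dataset",
    "sample_episode",
]

SHAPE_FAMILIES = ("ellipse", "rectangle", "annulus", "crescent", "blob")


@dataclass
class SyntheticTaskConfig:
    """Study conditions for the synthetic task corpus.

    Class intensity means are spread across [0.35, 0.9] on a dim background
    (mean 0.12) so foreground is clearly resolvable; geometry additionally
    distinguishes the families, so the prompt mask — not intensity alone —
    defines which structure is the target.
    """

    classes: tuple = ("ellipse", "rectangle", "annulus")
    held_out: tuple = ()
    class_intensity_means: tuple | None = None  # default: evenly spaced
    class_intensity_spread: float = 0.04
    background_mean: float = 0.12
    background_spread: float = 0.03
    deformation: float = 1.5  # max |displacement| in pixels
    noise_sd: float = 0.02
    samples_per_class: int = 40
    eval_samples: int = 16
    image_size: int = 64
    seed: int = 0

    def __post_init__(self):
        for c in self.classes:
            if c not in SHAPE_FAMILIES:
                raise ValueError(f"unknown shape family {c!r}; choose from {SHAPE_FAMILIES}")
        for c in self.held_out:
            if c not in self.classes:
                raise ValueError(f"held-out class {c!r} not among classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate shape families")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if self.class_intensity_means is None:
            k = len(self.classes)
            self.class_intensity_means = tuple(
                float(v) for v in np.linspace(0.35, 0.9, k)
            ) if k > 1 else (0.7,)
        if len(self.class_intensity_means) != len(self.classes):
            raise ValueError("class_intensity_means must match classes")

    @property
    def class_ids(self) -> tuple:
        """Integer class ids 1..K in config order."""
        return tuple(range(1, len(self.classes) + 1))

    def family_of(self, class_id: int) -> str:
        return self.classes[class_id - 1]

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# ---------------------------------------------------------------------------
# shape rasterization (pixel-center membership on the coordinate grid)
# ---------------------------------------------------------------------------

def _grid(size: int):
    r, c = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return r.astype(np.float64), c.astype(np.float64)


def _rotate(dr, dc, theta):
    ct, st = math.cos(theta), math.sin(theta)
    return ct * dr + st * dc, -st * dr + ct * dc


def render_shape(
    family: str,
    size: int,
    center: tuple[float, float],
    scale: float,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize one shape as a {0,1} mask by analytic pixel-center membership."""
    r, c = _grid(size)
    dr, dc = r - center[0], c - center[1]
    u, v = _rotate(dr, dc, theta)
    if family == "ellipse":
        a, b = scale, 0.62 * scale
        return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)
    if family == "rectangle":
        a, b = 0.9 * scale, 0.6 * scale
        return ((np.abs(u) <= a) & (np.abs(v) <= b)).astype(np.uint8)
    if family == "annulus":
        rad = np.hypot(u, v)
        return ((rad <= scale) & (rad >= 0.5 * scale)).astype(np.uint8)
    if family == "crescent":
        rad = np.hypot(u, v)
        rad2 = np.hypot(u - 0.55 * scale, v)
        return ((rad <= scale) & (rad2 > 0.75 * scale)).astype(np.uint8)
    if family == "blob":
        # star-convex region: radius modulated by a few random harmonics
        ang = np.arctan2(v, u)
        coeffs = rng.uniform(-0.25, 0.25, size=3)
        phases = rng.uniform(0, 2 * math.pi, size=3)
        radius = scale * (1.0 + sum(
            coeffs[k] * np.cos((k + 2) * ang + phases[k]) for k in range(3)
        ))
        return (np.hypot(u, v) <= radius).astype(np.uint8)
    raise ValueError(f"unknown shape family {family!r}")


def _displacement_field(size: int, magnitude: float, rng: np.random.Generator):
    if magnitude <= 0:
        return None
    field_ = rng.normal(size=(2, size, size))
    field_ = gaussian_filter(field_, sigma=(0, size / 8.0, size / 8.0))
    peak = np.abs(field_).max()
    if peak > 0:
        field_ *= magnitude / peak
    return field_


def _warp(arr: np.ndarray, disp, order: int) -> np.ndarray:
    if disp is None:
        return arr
    size = arr.shape[0]
    r, c = _grid(size)
    coords = np.stack([r + disp[0], c + disp[1]])
    return map_coordinates(arr.astype(np.float64), coords, order=order, mode="nearest")


def _background(size: int, cfg: SyntheticTaskConfig, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(size=(size, size))
    smooth = gaussian_filter(noise, sigma=size / 4.0)
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth /= peak
    return cfg.background_mean + cfg.background_spread * smooth


def _fill_intensity(size, mean, spread, rng) -> np.ndarray:
    noise = rng.normal(size=(size, size))
    smooth = gaussian_filter(noise, sigma=size / 8.0)
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth /= peak
    return mean + spread * smooth


def _sample_geometry(cfg: SyntheticTaskConfig, rng: np.random.Generator, center_box=None):
    size = cfg.image_size
    scale = rng.uniform(0.11, 0.17) * size
    theta = rng.uniform(0, 2 * math.pi)
    if center_box is None:
        m = 0.25 * size
        center = (rng.uniform(m, size - m), rng.uniform(m, size - m))
    else:
        (r0, r1), (c0, c1) = center_box
        center = (rng.uniform(r0, r1), rng.uniform(c0, c1))
    return center, scale, theta


def generate_shape_sample(
    class_id: int, config: SyntheticTaskConfig, sample_seed: int
) -> tuple[ImageSlice, BinaryMask]:
    """One single-shape sample of `class_id`: deformed shape on a noisy background."""
    family = config.family_of(class_id)
    rng = np.random.default_rng(int(sample_seed) & 0x7FFFFFFF)
    size = config.image_size
    center, scale, theta = _sample_geometry(config, rng)
    mask = render_shape(family, size, center, scale, theta, rng)
    image = _background(size, config, rng)
    fill = _fill_intensity(size, config.class_intensity_means[class_id - 1],
                           config.class_intensity_spread, rng)
    image = np.where(mask > 0, fill, image)
    disp = _displacement_field(size, config.deformation, rng)
    if disp is not None:
        image = _warp(image, disp, order=1)
        mask = (_warp(mask, disp, order=0) > 0.5).astype(np.uint8)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return ImageSlice(image), BinaryMask(mask)


def generate_scene(
    config: SyntheticTaskConfig, scene_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One multi-class scene: every class's shape placed in a distinct cell.

    Returns (image in [0,1], integer label map).  Cell placement keeps the
    shapes disjoint, so the label map is unambiguous.
    """
    rng = np.random.default_rng(int(scene_seed) & 0x7FFFFFFF)
    size = config.image_size
    k = len(config.classes)
    grid_n = math.ceil(math.sqrt(k))
    cell = size / grid_n
    cells = [(i, j) for i in range(grid_n) for j in range(grid_n)]
    order = rng.permutation(len(cells))[:k]

    labels = np.zeros((size, size), dtype=np.int32)
    image = _background(size, config, rng)
    for class_id in config.class_ids:
        ci, cj = cells[order[class_id - 1]]
        pad = 0.38 * cell
        box = ((ci * cell + pad, (ci + 1) * cell - pad),
               (cj * cell + pad, (cj + 1) * cell - pad))
        center, scale, theta = _sample_geometry(config, rng, center_box=box)
        scale = min(scale, 0.42 * cell)
        mask = render_shape(config.family_of(class_id), size, center, scale, theta, rng)
        mask = mask & (labels == 0).astype(np.uint8)
        labels[mask > 0] = class_id
        fill = _fill_intensity(size, config.class_intensity_means[class_id - 1],
                               config.class_intensity_spread, rng)
        image = np.where(mask > 0, fill, image)

    disp = _displacement_field(size, config.deformation, rng)
    if disp is not None:
        image = _warp(image, disp, order=1)
        labels = np.rint(_warp(labels, disp, order=0)).astype(np.int32)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0).astype(np.float32), labels


def generate_scene_dataset(
    config: SyntheticTaskConfig, split: str = "train"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack of scenes for one split; eval scenes use disjoint derived seeds."""
    if split not in ("train", "eval"):
        raise ValueError("split must be 'train' or 'eval'")
    n = config.samples_per_class if split == "train" else config.eval_samples
    images, labels = [], []
    for i in range(n):
        seed = derive_seed(config.seed, "scene", split, i)
        img, lab = generate_scene(config, seed)
        images.append(img)
        labels.append(lab)
    return np.stack(images), np.stack(labels)


def generate_task_dataset(
    config: SyntheticTaskConfig, split: str = "train"
) -> dict[int, list[tuple[ImageSlice, BinaryMask]]]:
    """Per-class single-shape samples: {class_id: [(image, mask)]}.

    Each sample is one deformed shape of the class on a background field, so
    a class's list is a pool of same-category image-mask pairs for prompts
    and queries. Held-out classes are excluded from the train split and
    present in the eval split (the unseen-target protocol). Per-sample seeds
    derive from (config.seed, split, class, index), so datasets are
    reproducible independently of generation order.
    """
    n = config.samples_per_class if split == "train" else config.eval_samples
    if split not in ("train", "eval"):
        raise ValueError("split must be 'train' or 'eval'")
    held = {config.class_ids[config.classes.index(h)] for h in config.held_out}
    grouped: dict[int, list] = {}
    for c in config.class_ids:
        if split == "train" and c in held:
            continue
        grouped[c] = [
            generate_shape_sample(c, config, derive_seed(config.seed, "sample", split, c, i))
            for i in range(n)
        ]
    return grouped


def generate_scene_task_dataset(
    config: SyntheticTaskConfig, split: str = "train"
) -> dict[int, list[tuple[ImageSlice, BinaryMask]]]:
    """Scene-layout alternative: every class indexes the *same* multi-shape
    scenes, decomposed per class, so one query image admits several valid
    tasks (useful for strict prompt-switching studies)."""
    from .datamodel import MultiClassMask, decompose_multiclass

    images, labels = generate_scene_dataset(config, split)
    held = {config.class_ids[config.classes.index(h)] for h in config.held_out}
    grouped: dict[int, list] = {}
    for img, lab in zip(images, labels):
        mcm = MultiClassMask(lab, config.class_ids)
        slc = ImageSlice(img)
        for c, bm in decompose_multiclass(mcm):
            if split == "train" and c in held:
                continue
            grouped.setdefault(c, []).append((slc, bm))
    return grouped


def sample_episode(
    dataset: dict[int, list],
    class_id: int,
    n_pairs: int,
    seed: int,
    query=None,
    mode: str = "infer",
) -> tuple[EpisodeSequence, BinaryMask | None]:
    """Draw an episode of one class, without replacement, seed-deterministic.

    ``query`` may be an ``ImageSlice`` (used as-is; returned target is None),
    an integer index into the class's sample list (that sample becomes the
    query and is excluded from the prompts; its mask is returned), or None
    (a query is drawn from the dataset).  ``mode='train'`` returns an
    (n_pairs+1)-pair training sequence instead, whose last image is the final
    supervised position.
    """
    if class_id not in dataset:
        raise KeyError(f"class {class_id} not in dataset")
    samples = dataset[class_id]
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    if mode == "train":
        need = n_pairs + 1
        if len(samples) < need:
            raise ValueError(f"class {class_id} has {len(samples)} samples, need {need}")
        idx = rng.choice(len(samples), size=need, replace=False)
        pairs = [samples[i] for i in idx]
        return EpisodeSequence(pairs=pairs, class_id=class_id, mode="train"), pairs[-1][1]

    if isinstance(query, ImageSlice):
        pool = list(range(len(samples)))
        target = None
    elif query is None:
        if len(samples) < n_pairs + 1:
            raise ValueError(
                f"class {class_id} has {len(samples)} samples, need {n_pairs + 1}"
            )
        qi = int(rng.integers(len(samples)))
        query, target = samples[qi][0], samples[qi][1]
        pool = [i for i in range(len(samples)) if i != qi]
    else:
        qi = int(query)
        query, target = samples[qi][0], samples[qi][1]
        pool = [i for i in range(len(samples)) if i != qi]

    if len(pool) < n_pairs:
        raise ValueError(f"class {class_id}: {len(pool)} support samples, need {n_pairs}")
    idx = rng.choice(len(pool), size=n_pairs, replace=False)
    pairs = [samples[pool[i]] for i in idx]
    episode = EpisodeSequence(pairs=pairs, class_id=class_id, mode="infer", query=query)
    return episode, target
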