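"""Core data types and dataset plumbing for in-context 2D segmentation.

Holds the image/mask containers, modality-specific intensity normalization
(CT Hounsfield windowing, MRI percentile clipping), multi-class to binary
task decomposition, the Dice similarity coefficient, axial slice extraction
from 3D volumes, and loading of task datasets (NIfTI pairs, PNG pairs, or the
seeded synthetic fixture archive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("icseg")

__all__ = [
    "ImageSlice",
    "BinaryMask",
    "MultiClassMask",
    "TaskSpec",
    "NormalizationSpec",
    "EvalReport",
    "EpisodeSequence",
    "normalize_ct",
    "normalize_mri",
    "decompose_multiclass",
    "dice_coefficient",
    "extract_axial_slices",
    "resize_image",
    "resize_mask",
    "load_task_dataset",
    "save_fixture_archive",
    "load_fixture_archive",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSlice:
    """A normalized 2D grayscale slice with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"ImageSlice must be 2D, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("ImageSlice contains non-finite values")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"ImageSlice values outside [0,1]: min={lo}, max={hi}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A {0,1} target mask paired with an image of the same shape."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"BinaryMask must be 2D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"BinaryMask values must be 0/1, found {uniq[:10]}")
        self.labels = arr.astype(np.uint8)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class MultiClassMask:
    """Integer labels over {0} ∪ class_set, 0 meaning background."""

    labels: np.ndarray
    class_set: tuple

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"MultiClassMask must be 2D, got shape {arr.shape}")
        self.labels = arr.astype(np.int32)
        self.class_set = tuple(sorted(int(c) for c in self.class_set))
        if any(c <= 0 for c in self.class_set):
            raise ValueError("class ids must be positive integers (0 is background)")
        allowed = {0, *self.class_set}
        present = set(np.unique(self.labels).tolist())
        bad = present - allowed
        if bad:
            raise ValueError(f"labels contain values outside class_set: {sorted(bad)}")


@dataclass(frozen=True)
class TaskSpec:
    """One binary sub-task: a class of one source dataset in one modality."""

    source_id: str
    class_id: int
    modality: str  # "CT" | "MRI" | "synthetic"


@dataclass(frozen=True)
class NormalizationSpec:
    """Modality-specific intensity normalization parameters.

    CT uses Hounsfield-unit windowing (level ± width/2); MRI uses per-sample
    percentile clipping (defaults 0.5 / 99.5) because MRI intensities carry no
    standardized physical scale.
    """

    modality: str
    window_level: float | None = None
    window_width: float | None = None
    lower_pct: float = 0.5
    upper_pct: float = 99.5

    def __post_init__(self):
        if self.modality not in ("CT", "MRI"):
            raise ValueError(f"modality must be CT or MRI, got {self.modality!r}")
        if self.modality == "CT":
            if self.window_width is None or self.window_level is None:
                raise ValueError("CT normalization requires window_level and window_width")
            if self.window_width <= 0:
                raise ValueError("window_width must be positive")
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValueError("percentiles must satisfy 0 <= lower < upper <= 100")


@dataclass
class EvalReport:
    """Per-class and mean Dice over queries and prompt-sequence repeats."""

    per_class_dsc: dict
    mean_dsc: float
    n_repeats: int
    seeds: list = field(default_factory=list)

    def __post_init__(self):
        for c, v in self.per_class_dsc.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"DSC for class {c} outside [0,1]: {v}")


@dataclass
class EpisodeSequence:
    """The unit of training/inference: ordered image–mask pairs of one class.

    In ``train`` mode the sequence is n+1 pairs and the later images double as
    intermediate queries; in ``infer`` mode it is 1..n prompt pairs followed by
    a separate query image.
    """

    pairs: list  # list[(ImageSlice, BinaryMask)]
    class_id: int
    mode: str = "infer"  # "train" | "infer"
    query: ImageSlice | None = None

    def __post_init__(self):
        if self.mode not in ("train", "infer"):
            raise ValueError(f"mode must be train or infer, got {self.mode!r}")
        if self.mode == "infer" and self.query is None:
            raise ValueError("infer-mode episode requires a query image")
        if self.mode == "train" and self.query is not None:
            raise ValueError("train-mode episode carries no separate query")
        if not self.pairs:
            raise ValueError("episode needs at least one image-mask pair")
        h, w = self.pairs[0][0].pixels.shape
        for img, msk in self.pairs:
            if img.pixels.shape != (h, w) or msk.labels.shape != (h, w):
                raise ValueError("all episode members must share one resolution")
        if self.query is not None and self.query.pixels.shape != (h, w):
            raise ValueError("query resolution differs from prompt pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def image_count(self) -> int:
        return 2 * len(self.pairs) + (1 if self.query is not None else 0)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_ct(raw: np.ndarray, spec: NormalizationSpec) -> ImageSlice:
    """Window a Hounsfield-unit slice and min-max map the window to [0, 1].

    The clip bounds (level ± width/2) — not the observed post-clip extrema —
    are the min-max reference, so the mapping is a pure function of the spec.
    """
    if spec.modality != "CT":
        raise ValueError("normalize_ct requires a CT NormalizationSpec")
    raw = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(raw).all():
        raise ValueError("CT slice contains non-finite values")
    lo = spec.window_level - spec.window_width / 2.0
    hi = spec.window_level + spec.window_width / 2.0
    clipped = np.clip(raw, lo, hi)
    return ImageSlice((clipped - lo) / (hi - lo))


def normalize_mri(raw: np.ndarray, spec: NormalizationSpec) -> ImageSlice:
    """Clip at per-sample intensity percentiles, then min-max map to [0, 1].

    A constant slice (clip bounds coincide) is degenerate and maps to all
    zeros; this is logged rather than raised so batch pipelines survive blank
    slices at volume ends.
    """
    if spec.modality != "MRI":
        raise ValueError("normalize_mri requires an MRI NormalizationSpec")
    raw = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(raw).all():
        raise ValueError("MRI slice contains non-finite values")
    lo, hi = np.percentile(raw, [spec.lower_pct, spec.upper_pct])
    if hi <= lo:
        logger.warning("degenerate MRI slice (constant after clipping); returning zeros")
        return ImageSlice(np.zeros_like(raw))
    clipped = np.clip(raw, lo, hi)
    return ImageSlice((clipped - lo) / (hi - lo))


def normalize_slice(raw: np.ndarray, spec: NormalizationSpec) -> ImageSlice:
    return normalize_ct(raw, spec) if spec.modality == "CT" else normalize_mri(raw, spec)


# ---------------------------------------------------------------------------
# task decomposition and metric
# ---------------------------------------------------------------------------

def decompose_multiclass(mask: MultiClassMask) -> list[tuple[int, BinaryMask]]:
    """Split a multi-class mask into one binary foreground mask per class.

    Classes absent from the slice yield all-zero masks, so every class of the
    source defines a valid (possibly empty-target) binary sub-task.
    """
    return [
        (c, BinaryMask((mask.labels == c).astype(np.uint8)))
        for c in mask.class_set
    ]


def dice_coefficient(pred: BinaryMask, target: BinaryMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.labels.astype(np.int64)
    t = target.labels.astype(np.int64)
    denom = int(p.sum() + t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


# ---------------------------------------------------------------------------
# volumes and resizing
# ---------------------------------------------------------------------------

def extract_axial_slices(
    volume: np.ndarray,
    labels: np.ndarray,
    class_set: tuple | None = None,
    keep_class: int | None = None,
) -> list[tuple[np.ndarray, MultiClassMask]]:
    """Reformat a 3D volume + label volume into ordered 2D axial pairs.

    Axial is the first array axis. With ``keep_class`` set, only slices in
    which that class appears are returned.
    """
    volume = np.asarray(volume)
    labels = np.asarray(labels)
    if volume.shape != labels.shape:
        raise ValueError(f"volume {volume.shape} and labels {labels.shape} differ")
    if class_set is None:
        present = np.unique(labels)
        class_set = tuple(int(c) for c in present if c > 0)
    out = []
    for z in range(volume.shape[0]):
        lab = labels[z]
        if keep_class is not None and not (lab == keep_class).any():
            continue
        out.append((volume[z], MultiClassMask(lab, class_set)))
    return out


def resize_image(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a [0,1] image to size x size."""
    from skimage.transform import resize

    if pixels.shape == (size, size):
        return np.asarray(pixels, dtype=np.float32)
    out = resize(pixels.astype(np.float64), (size, size), order=1, mode="edge",
                 anti_aliasing=pixels.shape[0] > size, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_mask(labels: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor resize of an integer label map (preserves label values)."""
    from skimage.transform import resize

    if labels.shape == (size, size):
        return np.asarray(labels)
    out = resize(labels.astype(np.float64), (size, size), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.rint(out).astype(labels.dtype)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def save_fixture_archive(
    path: str | Path,
    images: np.ndarray,
    labels: np.ndarray,
    class_set: tuple,
    config_json: str = "{}",
    seed: int = 0,
    layout: str = "scene",
) -> None:
    """Persist a generated dataset: images (N,H,W) in [0,1], integer labels.

    ``layout='scene'`` means every image may contain several classes and each
    class sees every image (possibly with an empty target); ``'single'`` means
    each image belongs to the one class present in its label map.
    """
    if layout not in ("scene", "single"):
        raise ValueError("layout must be 'scene' or 'single'")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        images=np.asarray(images, dtype=np.float32),
        labels=np.asarray(labels, dtype=np.int32),
        class_set=np.asarray(class_set, dtype=np.int32),
        config_json=np.asarray(config_json),
        seed=np.asarray(seed),
        layout=np.asarray(layout),
    )


def load_fixture_archive(path: str | Path):
    with np.load(Path(path), allow_pickle=False) as z:
        layout = str(z["layout"]) if "layout" in z.files else "scene"
        return (
            z["images"],
            z["labels"],
            tuple(int(c) for c in z["class_set"]),
            str(z["config_json"]),
            int(z["seed"]),
            layout,
        )


def _group_scenes(
    images: np.ndarray, labels: np.ndarray, class_set: tuple, image_size: int,
    layout: str = "scene",
) -> dict[int, list[tuple[ImageSlice, BinaryMask]]]:
    grouped: dict[int, list] = {c: [] for c in class_set}
    for img, lab in zip(images, labels):
        img_r = resize_image(img, image_size)
        lab_r = resize_mask(lab, image_size)
        mcm = MultiClassMask(lab_r, class_set)
        slc = ImageSlice(img_r)
        for c, bm in decompose_multiclass(mcm):
            if layout == "single" and not bm.labels.any():
                continue
            grouped[c].append((slc, bm))
    return {c: v for c, v in grouped.items() if v}


def load_task_dataset(
    path: str | Path,
    spec: NormalizationSpec | None = None,
    image_size: int = 256,
) -> dict[int, list[tuple[ImageSlice, BinaryMask]]]:
    """Load a task dataset grouped per class: {class_id: [(image, binary mask)]}.

    Accepts (a) a fixture archive (.npz) written by the synthetic generator —
    images already normalized; (b) a directory of NIfTI volume/label pairs
    named ``<stem>_image.nii[.gz]`` / ``<stem>_label.nii[.gz]`` — normalized
    per ``spec``; (c) a directory of PNG pairs ``<stem>_image.png`` /
    ``<stem>_label.png`` with 8-bit images and integer label maps.  Ordering
    is deterministic (sorted stems, ascending slice index).
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".npz":
        images, labels, class_set, _, _, layout = load_fixture_archive(path)
        return _group_scenes(images, labels, class_set, image_size, layout)
    if not path.is_dir():
        raise FileNotFoundError(f"no such dataset: {path}")

    nii_images = sorted(
        p for p in path.iterdir()
        if p.name.endswith(("_image.nii", "_image.nii.gz"))
    )
    png_images = sorted(path.glob("*_image.png"))
    if not nii_images and not png_images:
        raise ValueError(f"empty dataset: no *_image.nii[.gz] or *_image.png under {path}")

    scenes_img: list[np.ndarray] = []
    scenes_lab: list[np.ndarray] = []
    class_union: set[int] = set()

    if nii_images:
        import nibabel as nib

        if spec is None:
            raise ValueError("NIfTI loading requires a NormalizationSpec")
        for img_path in nii_images:
            stem = img_path.name.replace("_image.nii.gz", "").replace("_image.nii", "")
            lab_path = None
            for ext in ("_label.nii.gz", "_label.nii"):
                cand = img_path.with_name(stem + ext)
                if cand.exists():
                    lab_path = cand
                    break
            if lab_path is None:
                raise FileNotFoundError(f"missing label partner for {img_path.name}")
            vol = np.asanyarray(nib.load(str(img_path)).dataobj)
            lab = np.asanyarray(nib.load(str(lab_path)).dataobj).astype(np.int32)
            for raw, mcm in extract_axial_slices(vol, lab):
                scenes_img.append(normalize_slice(raw, spec).pixels)
                scenes_lab.append(mcm.labels)
                class_union.update(mcm.class_set)
    else:
        import imageio.v3 as iio

        for img_path in png_images:
            stem = img_path.name[: -len("_image.png")]
            lab_path = img_path.with_name(stem + "_label.png")
            if not lab_path.exists():
                raise FileNotFoundError(f"missing label partner for {img_path.name}")
            img = np.asarray(iio.imread(img_path))
            if img.ndim == 3:
                img = img[..., 0]
            scenes_img.append((img.astype(np.float64) / 255.0).astype(np.float32))
            scenes_lab.append(np.asarray(iio.imread(lab_path)).astype(np.int32))
            class_union.update(int(c) for c in np.unique(scenes_lab[-1]) if c > 0)

    class_set = tuple(sorted(class_union))
    if not class_set:
        raise ValueError(f"dataset under {path} contains no foreground classes")
    return _group_scenes(np.asarray(scenes_img, dtype=object) if len({i.shape for i in scenes_img}) > 1 else np.stack(scenes_img),
                         np.asarray(scenes_lab, dtype=object) if len({m.shape for m in scenes_lab}) > 1 else np.stack(scenes_lab),
                         class_set, image_size)
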