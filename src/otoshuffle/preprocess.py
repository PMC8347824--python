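"""Endoscope-image preprocessing and training-time augmentation.

Raw otoscope captures are a bright circular field on a black margin.  The
pipeline is: (1) locate the tightest box around non-black content and crop
it away, (2) resize the crop to a square working resolution (270 by
default) with values scaled to [0, 1], and (3) during training draw a
random dihedral transform (horizontal/vertical mirror, rotation by
multiples of 90 degrees) followed by a random crop to the patch size (256
by default); evaluation uses the deterministic centre crop instead.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

DEFAULT_MARGIN_THRESHOLD = 10
DEFAULT_RESIZE_SIZE = 270
DEFAULT_PATCH_SIZE = 256


@dataclasses.dataclass(frozen=True)
class CropBox:
    """Axis-aligned pixel box, (top, left) inclusive origin."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("CropBox must have positive extent")
        if self.top < 0 or self.left < 0:
            raise ValueError("CropBox origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.top + self.height), slice(self.left, self.left + self.width)


@dataclasses.dataclass(frozen=True)
class AugmentParams:
    """One draw of the stochastic training transform."""

    flip_h: bool
    flip_v: bool
    rot_k: int  # counter-clockwise 90-degree steps
    top: int
    left: int


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB array, got shape {image.shape}")
    if image.shape[0] < 64 or image.shape[1] < 64:
        raise ValueError("image smaller than 64x64")
    return image


def find_content_box(image: np.ndarray, intensity_threshold: float = DEFAULT_MARGIN_THRESHOLD) -> CropBox:
    """Tightest box containing every pixel brighter than the threshold.

    Brightness is the max over channels.  A degenerate (all-dark) image
    yields the full-image box with a warning rather than an exception.
    """
    image = _validate_image(image)
    bright = image.max(axis=2) > intensity_threshold
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    if rows.size == 0:
        warnings.warn("no pixel exceeds the margin threshold; keeping the full frame", stacklevel=2)
        return CropBox(0, 0, image.shape[0], image.shape[1])
    return CropBox(int(rows[0]), int(cols[0]), int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))


def standardize(image: np.ndarray, box: CropBox | None = None, size: int = DEFAULT_RESIZE_SIZE) -> np.ndarray:
    """Crop to ``box`` (default: detected content box) and resize to
    ``size`` x ``size`` float32 RGB in [0, 1], bilinear."""
    image = _validate_image(image)
    if box is None:
        box = find_content_box(image)
    rs, cs = box.slices()
    if rs.stop > image.shape[0] or cs.stop > image.shape[1]:
        raise ValueError("CropBox extends outside the image")
    crop = image[rs, cs]
    if np.issubdtype(crop.dtype, np.integer):
        crop = crop.astype(np.float32) / 255.0
    out = _sk_resize(crop, (size, size), order=1, mode="reflect", anti_aliasing=min(crop.shape[:2]) > size,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def normalize(image: np.ndarray, mode: str = "unit", mean=None, std=None) -> np.ndarray:
    """Optional per-channel standardisation on top of [0,1] scaling."""
    if mode == "unit":
        return image.astype(np.float32)
    if mode == "channel":
        m = np.asarray(mean if mean is not None else image.mean(axis=(0, 1)), dtype=np.float32)
        s = np.asarray(std if std is not None else image.std(axis=(0, 1)) + 1e-8, dtype=np.float32)
        return ((image - m) / s).astype(np.float32)
    raise ValueError(f"unknown normalization mode {mode!r}")


def draw_augment_params(rng: np.random.Generator, size: int, patch_size: int) -> AugmentParams:
    """Sample mirror flags, rotation and crop offset.

    The (flip_h, flip_v, rot_k) triple double-covers the dihedral group of
    the square, so each of its 8 elements occurs with probability 1/8; the
    crop offset is uniform over the (size - patch + 1)^2 valid positions.
    """
    span = size - patch_size + 1
    if span < 1:
        raise ValueError("patch size exceeds image size")
    return AugmentParams(
        flip_h=bool(rng.integers(2)),
        flip_v=bool(rng.integers(2)),
        rot_k=int(rng.integers(4)),
        top=int(rng.integers(span)),
        left=int(rng.integers(span)),
    )


def apply_augment(image: np.ndarray, params: AugmentParams, patch_size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Deterministically apply one augmentation draw.

    Composition order: horizontal mirror, vertical mirror, rotation by
    ``rot_k`` quarter-turns, then crop; every step before the crop is a
    pixel permutation, so content is preserved up to the crop.
    """
    out = image
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    if params.rot_k:
        out = np.rot90(out, k=params.rot_k)
    patch = out[params.top : params.top + patch_size, params.left : params.left + patch_size]
    if patch.shape[:2] != (patch_size, patch_size):
        raise ValueError("crop fell outside the image")
    return np.ascontiguousarray(patch, dtype=np.float32)


def augment(image: np.ndarray, rng_seed: int | np.random.Generator,
            patch_size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Random training patch: seeded dihedral transform + random crop."""
    if image.shape[0] != image.shape[1]:
        raise ValueError("augment expects a square standardized image")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    params = draw_augment_params(rng, image.shape[0], patch_size)
    return apply_augment(image, params, patch_size)


def eval_patch(image: np.ndarray, patch_size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """Deterministic centre crop used at evaluation time."""
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError("image smaller than the patch size")
    top, left = (h - patch_size) // 2, (w - patch_size) // 2
    return np.ascontiguousarray(image[top : top + patch_size, left : left + patch_size], dtype=np.float32)


def standardize_batch(images, size: int = DEFAULT_RESIZE_SIZE,
                      margin_threshold: float = DEFAULT_MARGIN_THRESHOLD) -> np.ndarray:
    """Margin-crop and resize a sequence of raw images into one array."""
    return np.stack([
        standardize(img, find_content_box(img, margin_threshold), size=size) for img in images
    ])


def load_image(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG file as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB array (uint8, or float in [0,1]) as PNG."""
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.floating):
        arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr).save(path)
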