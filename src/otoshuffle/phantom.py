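"""Synthetic otoscopy phantoms for the four middle-ear diagnoses.

Each phantom emulates an endoscope capture: a 640x480 black frame with a
bright circular field (the ear-canal view), a tympanic-membrane disk inside
it, and a class-specific cue matching the clinical criterion for each
diagnosis:

* ``normal`` — pearly-gray membrane with a light reflex and malleus streak;
* ``OME`` — intact membrane with an amber effusion tint gradient;
* ``COM`` — dark irregular perforation hole with a pale rim;
* ``cholesteatoma`` — superior-quadrant (attic) erosion blob with white
  keratin-debris speckle.

The cues are geometric/colorimetric, not photorealistic: they make the four
classes learnable by a CNN so the preprocessing, training, Grad-CAM and
cross-validation machinery can be exercised end-to-end without clinical
images.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import save_image

LABELS = ("normal", "OME", "COM", "cholesteatoma")

#: class mix matching the reported clinical prevalence 1180/400/627/165
PREVALENCE_MIX = (1180 / 2372, 400 / 2372, 627 / 2372, 165 / 2372)
#: near-equal mix mirroring the 19/17/17/18 curated test set
BALANCED_MIX = (19 / 71, 17 / 71, 17 / 71, 18 / 71)


@dataclasses.dataclass(frozen=True)
class PhantomParams:
    """Rendering conditions for the synthetic endoscope frames."""

    width: int = 640
    height: int = 480
    field_radius_range: tuple[float, float] = (170.0, 205.0)
    center_jitter: float = 18.0
    class_mix: tuple[float, float, float, float] = PREVALENCE_MIX
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-6:
            raise ValueError("class_mix must sum to 1")
        rmax = self.field_radius_range[1] + self.center_jitter
        if rmax >= min(self.width, self.height) / 2:
            raise ValueError("field radius + jitter must fit inside the canvas")


@dataclasses.dataclass
class LabeledImage:
    """An RGB frame with its diagnosis, provenance, and render metadata."""

    pixels: np.ndarray  # HxWx3 uint8
    label: str
    source_id: str
    provenance: str = "synthetic"
    meta: dict = dataclasses.field(default_factory=dict)


def _irregular_mask(yy, xx, cy, cx, r0, rng, wobble=(0.18, 0.12)) -> np.ndarray:
    """Blob with angularly perturbed radius (jagged, organic boundary)."""
    theta = np.arctan2(yy - cy, xx - cx)
    p3, p5 = rng.uniform(0, 2 * np.pi, 2)
    r = r0 * (1.0 + wobble[0] * np.sin(3 * theta + p3) + wobble[1] * np.sin(5 * theta + p5))
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)


def render_phantom(label: str, params: PhantomParams = PhantomParams(),
                   rng: np.random.Generator | int | None = None,
                   source_id: str = "phantom") -> LabeledImage:
    """Render one labeled phantom frame.

    Deterministic for a fixed ``rng`` seed; with ``noise_sd = 0`` the frame
    is exactly reproducible bit for bit.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; choose from {LABELS}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    img = np.zeros((h, w, 3), dtype=np.float32)
    meta: dict = {}

    # endoscope field: bright reddish canal wall with radial shading
    jx, jy = rng.uniform(-params.center_jitter, params.center_jitter, 2)
    cx, cy = w / 2 + jx, h / 2 + jy
    R = rng.uniform(*params.field_radius_range)
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    field_alpha = np.clip((R - r) / 2.5, 0.0, 1.0)  # soft 2-3 px edge
    shade = 1.0 - 0.35 * np.clip(r / R, 0, 1) ** 2
    canal = np.array([200, 152, 132], np.float32) + rng.uniform(-12, 12, 3).astype(np.float32)
    img += (field_alpha * shade)[:, :, None] * canal
    meta["field"] = {"cx": float(cx), "cy": float(cy), "radius": float(R)}

    # tympanic membrane disk, slightly off-centre
    mx = cx + rng.uniform(-0.08, 0.08) * R
    my = cy + rng.uniform(-0.08, 0.08) * R
    mr = rng.uniform(0.55, 0.68) * R
    rm = np.sqrt((yy - my) ** 2 + (xx - mx) ** 2)
    mem_alpha = 0.78 * np.clip((mr - rm) / 3.0, 0.0, 1.0)
    pearly = np.array([208, 202, 196], np.float32) + rng.uniform(-6, 6, 3).astype(np.float32)
    img = img * (1 - mem_alpha[:, :, None]) + mem_alpha[:, :, None] * shade[:, :, None] * pearly

    # malleus handle: darkened streak from the centre toward 1 o'clock
    ang = rng.uniform(np.pi / 3, np.pi / 2.2)
    ux, uy = np.cos(ang), -np.sin(ang)
    t = (xx - mx) * ux + (yy - my) * uy
    d = np.abs(-(xx - mx) * uy + (yy - my) * ux)
    streak = (t > 0) & (t < 0.8 * mr) & (d < 0.045 * mr) & (rm < mr)
    img[streak] *= 0.82

    # light reflex: small bright spot on the inferior membrane
    lx = mx + rng.uniform(-0.35, -0.15) * mr
    ly = my + rng.uniform(0.25, 0.45) * mr
    reflex = np.exp(-(((yy - ly) ** 2 + (xx - lx) ** 2) / (0.06 * mr) ** 2)).astype(np.float32)
    img += 55.0 * (reflex * (rm < mr))[:, :, None]

    if label == "OME":
        # amber effusion tint behind the intact membrane, denser inferiorly
        grad = np.clip((yy - (my - mr)) / (2 * mr), 0, 1)
        tint_alpha = (0.35 + 0.4 * grad) * (rm < mr)
        amber = np.array([224, 158, 58], np.float32)
        img = img * (1 - tint_alpha[:, :, None]) + tint_alpha[:, :, None] * shade[:, :, None] * amber
        meta["lesion_bbox"] = _bbox_of(rm < mr)
    elif label == "COM":
        # irregular dark perforation with a pale thickened rim
        hx = mx + rng.uniform(-0.2, 0.2) * mr
        hy = my + rng.uniform(-0.2, 0.2) * mr
        hr = rng.uniform(0.28, 0.45) * mr
        hole = _irregular_mask(yy, xx, hy, hx, hr, rng)
        rim = _irregular_mask(yy, xx, hy, hx, hr + 0.12 * mr, rng, wobble=(0.15, 0.1)) & ~hole
        img[rim & (rm < mr)] = img[rim & (rm < mr)] * 0.35 + 0.65 * np.array([228, 219, 206], np.float32)
        dark = np.array([46, 26, 24], np.float32) + rng.uniform(-6, 6, 3).astype(np.float32)
        img[hole] = dark * shade[hole, None]
        meta["lesion_bbox"] = _bbox_of(hole)
    elif label == "cholesteatoma":
        # attic (superior-quadrant) erosion blob with white debris speckle
        bang = rng.uniform(np.pi / 2 - 0.45, np.pi / 2 + 0.45)  # near straight up
        bd = rng.uniform(0.55, 0.75) * R
        bx = cx + bd * np.cos(bang)
        by = cy - bd * np.sin(bang)
        br = rng.uniform(0.20, 0.30) * R
        blob = _irregular_mask(yy, xx, by, bx, br, rng) & (r < R - 2)
        img[blob] = img[blob] * 0.4 + 0.6 * np.array([128, 94, 80], np.float32)
        speck = rng.random((h, w)) < 0.45
        debris = blob & speck
        img[debris] = img[debris] * 0.2 + 0.8 * np.array([242, 236, 224], np.float32)
        meta["lesion_bbox"] = _bbox_of(blob)

    if params.noise_sd > 0:
        # sensor noise is visible only in the illuminated field; the black
        # margin stays exactly black so margin removal is well defined
        noise = rng.normal(0.0, params.noise_sd, img.shape).astype(np.float32)
        img += noise * (field_alpha > 0)[:, :, None]
    pixels = np.clip(img, 0, 255).round().astype(np.uint8)
    return LabeledImage(pixels=pixels, label=label, source_id=source_id, meta=meta)


def generate_dataset(n: int, params: PhantomParams = PhantomParams(),
                     one_per_class: bool = False,
                     out_dir: str | Path | None = None) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate ``n`` phantoms with labels drawn from ``params.class_mix``.

    Fully deterministic given ``params.seed``: each image gets its own
    recorded sub-seed, so any row of the manifest regenerates its frame.
    With ``one_per_class`` the first ``n`` labels cycle through the four
    classes instead of being sampled (``n`` must then be a multiple of 4).
    """
    if n < 4:
        raise ValueError("need n >= 4 to cover the four classes")
    master = np.random.default_rng(params.seed)
    if one_per_class:
        if n % 4:
            raise ValueError("one_per_class requires n divisible by 4")
        labels = [LABELS[i % 4] for i in range(n)]
    else:
        labels = list(master.choice(LABELS, size=n, p=np.asarray(params.class_mix)))
    sub_seeds = master.integers(0, 2**31, size=n)
    images: list[LabeledImage] = []
    rows = []
    for i, (label, sub) in enumerate(zip(labels, sub_seeds)):
        source_id = f"phantom_{i:05d}"
        img = render_phantom(label, params, rng=int(sub), source_id=source_id)
        images.append(img)
        rows.append({"file": f"{source_id}.png", "label": label, "seed": int(sub)})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, rows):
            save_image(img.pixels, out_dir / row["file"])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return images, manifest


def manifest_hash(manifest: pd.DataFrame) -> str:
    """Stable digest of a manifest, for reproducibility checks."""
    return hashlib.sha256(manifest.to_csv(index=False).encode()).hexdigest()
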