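"""Grad-CAM saliency from the last convolutional layer.

For a target class c, the class logit is backpropagated to the activations
A_k of the final convolutional feature map; the channel weights are the
spatially averaged gradients w_k = mean_ij dY_c/dA_k(i,j), and the map is
ReLU(sum_k w_k A_k), normalised to [0, 1] by its maximum.  A model with
constant logits has zero gradients and yields an all-zero map, which is
returned as-is with a warning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from . import nn


@dataclasses.dataclass
class SaliencyMap:
    """Normalised class-activation map at the hooked layer's resolution."""

    values: np.ndarray  # H' x W' float in [0, 1]
    target_class: int
    layer_name: str
    is_zero: bool = False


def grad_cam(model, image: np.ndarray, target_class: int) -> SaliencyMap:
    """Compute Grad-CAM for one evaluation patch.

    ``model`` is any module whose forward records the final feature map as
    ``last_feature_map`` (the residual classifiers do); ``image`` is an
    HxWx3 float patch in [0, 1].
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 image patch")
    model.eval()
    x = nn.Tensor(image.transpose(2, 0, 1)[None])
    logits = model(x)
    k = logits.shape[1]
    if not (0 <= target_class < k):
        raise ValueError(f"target class {target_class} outside [0, {k})")
    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0
    logits.backward(seed)
    fmap = model.last_feature_map
    acts = fmap.data[0]
    grads = fmap.grad[0] if fmap.grad is not None else np.zeros_like(acts)
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    peak = cam.max()
    layer_name = getattr(model, "feature_layer_name", "last_conv")
    if peak <= 0:
        warnings.warn("Grad-CAM map is identically zero for this class", stacklevel=2)
        return SaliencyMap(np.zeros_like(cam, dtype=np.float32), target_class, layer_name, is_zero=True)
    return SaliencyMap((cam / peak).astype(np.float32), target_class, layer_name)


def overlay(smap: SaliencyMap, image: np.ndarray, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Blend the saliency map over the image as an RGB heat map.

    The map is bilinearly upsampled to the image size m(i,j) and blended as
    ``(1 - alpha) * image + alpha * m * colormap(m)``: a zero map gives
    exactly the dimmed image, ``alpha = 0`` the original, and the strongest
    heat lands on the upsampled map's argmax neighbourhood.  Deterministic.
    """
    image = np.asarray(image, dtype=np.float32)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        image = image / 255.0
    m = _sk_resize(smap.values, image.shape[:2], order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True).astype(np.float32)
    heat = colormaps[cmap](m)[:, :, :3].astype(np.float32)
    out = (1.0 - alpha) * image + alpha * m[:, :, None] * heat
    return np.clip(out, 0.0, 1.0)


def saliency_mass_split(smap: SaliencyMap, image_shape: tuple[int, int],
                        bbox: tuple[int, int, int, int]) -> tuple[float, float]:
    """Saliency mass inside vs outside a (top, left, height, width) box,
    measured on the map upsampled to ``image_shape``."""
    m = _sk_resize(smap.values, image_shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    top, left, h, w = bbox
    inside = float(m[top : top + h, left : left + w].sum())
    return inside, float(m.sum() - inside)
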