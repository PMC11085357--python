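"""Grad-CAM heatmaps over the shared trunk.

For a chosen output (a class logit, or the regression head), the gradient
of that output with respect to the trunk activation map (the ReLU after
the residual addition — the deepest spatial layer) is spatially averaged
into per-channel weights; the weighted, ReLU-rectified channel sum is
upsampled to the input size and min-max normalised.  Bright regions are
the ones whose activations most influence the chosen prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from skimage.transform import resize

from .model import MultiOutputNet

TARGET_REGRESSION = "regression"


@dataclass
class Heatmap:
    values: np.ndarray  # (S, S) in [0, 1]
    target: Union[int, str]
    source_layer: str = "post_add_relu"


def _as_input(net: MultiOutputNet, image: np.ndarray) -> np.ndarray:
    x = np.asarray(image)
    if x.ndim != 3 or x.shape[-1] != 3:
        raise ValueError(f"expected (S, S, 3) image, got {x.shape}")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / np.float32(255.0)
    return x[None].astype(np.float32)


def grad_cam(net: MultiOutputNet, image: np.ndarray,
             target: Union[int, str] = "auto") -> Heatmap:
    """Grad-CAM heatmap for one image.

    ``target`` is a class index, ``"auto"`` (the predicted class), or
    ``"regression"`` for the day head.
    """
    x = _as_input(net, image)
    logits, _ = net.forward(x, train=False)
    k = net.spec.n_classes
    dlogits = np.zeros_like(logits)
    dday = None
    if target == TARGET_REGRESSION:
        if net.reg_head is None:
            raise ValueError("network has no regression head")
        dday = np.ones(1, dtype=np.float32)
    else:
        t = int(np.argmax(logits[0])) if target == "auto" else int(target)
        if not 0 <= t < k:
            raise ValueError(f"class index {t} out of range [0, {k})")
        dlogits[0, t] = 1.0
        target = t
    da = net.backward(dlogits, dday, to_trunk=True)  # (1, h, w, C)
    activ = net.trunk_activation
    weights = da.mean(axis=(1, 2))                   # (1, C)
    cam = np.maximum((weights[:, None, None, :] * activ).sum(axis=-1), 0.0)[0]
    s = net.spec.input_size
    cam = resize(cam, (s, s), order=1, preserve_range=True)
    top = cam.max()
    if top > 0:
        cam = cam / top
    return Heatmap(values=cam.astype(np.float64), target=target)


def focus_score(heatmap: np.ndarray, mask: np.ndarray) -> float:
    """Mean heatmap value inside the plant mask minus outside.

    Positive scores mean the model's attention sits on the plant.
    """
    h = np.asarray(heatmap, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if h.shape != m.shape:
        raise ValueError(f"heatmap {h.shape} and mask {m.shape} shapes differ")
    if not m.any() or m.all():
        raise ValueError("mask must have both plant and background pixels")
    return float(h[m].mean() - h[~m].mean())


def save_heatmap_png(heatmap: np.ndarray, path) -> None:
    """Write a heatmap (values in [0, 1]) as an 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(heatmap, dtype=float), 0, 1)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def heatmap_overlay(image: np.ndarray, heatmap: np.ndarray,
                    alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a colormapped heatmap onto an RGB image (uint8 out)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    img = np.asarray(image)
    h = np.asarray(heatmap, dtype=float)
    if img.shape[:2] != h.shape:
        raise ValueError("image and heatmap shapes differ")
    import matplotlib

    cmap = matplotlib.colormaps["jet"]
    colored = cmap(np.clip(h, 0, 1))[..., :3] * 255.0
    out = (1.0 - alpha) * img.astype(float) + alpha * colored
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
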