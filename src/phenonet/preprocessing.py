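"""Plant/background segmentation in CIE L*a*b* and network input preparation.

The rosette is separated from the soil by thresholding the a* (green-red)
opponent channel: vegetation is strongly green (a* well below zero) while
soil is reddish-brown (a* above zero).  The threshold is found by Otsu's
method on a* by default, which makes the mask invariant to uniform
brightness changes (those live entirely in L*); a fixed threshold is
available as a fallback.  Small components are removed and a gentle
morphological opening cleans speckle without eating leaf edges.

Masked or raw images are finally resized (bilinear, anti-aliased) to the
square network input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening, remove_small_objects
from skimage.transform import resize


@dataclass
class SegmentationConfig:
    a_threshold_mode: str = "otsu"      # "otsu" | "fixed"
    a_threshold_value: float = -10.0    # a* units, used when mode == "fixed"
    min_region_px: int = 25
    morph_open_radius: int = 1
    input_size: int = 150

    def __post_init__(self):
        if self.a_threshold_mode not in ("otsu", "fixed"):
            raise ValueError("a_threshold_mode must be 'otsu' or 'fixed'")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if self.min_region_px < 0:
            raise ValueError("min_region_px must be >= 0")


@dataclass
class SegmentationResult:
    mask: np.ndarray        # bool (H, W)
    segmented: np.ndarray   # uint8 (H, W, 3), background zeroed
    coverage: float         # fraction of pixels inside the mask


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB (uint8 or float in [0,1]) -> CIE L*a*b* under D65/2 degrees."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    return rgb2lab(image)


# a masked region whose mean a* is above this is not vegetation at all
_GREEN_SANITY_A = -5.0


def plant_mask(lab_image: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Binary plant mask from an L*a*b* image (True = plant)."""
    a = lab_image[..., 1]
    if config.a_threshold_mode == "otsu":
        if np.ptp(a) < 1.0:  # essentially achromatic along a*: nothing green
            return np.zeros(a.shape, dtype=bool)
        thresh = threshold_otsu(a)
    else:
        thresh = config.a_threshold_value
    # <= matches the skimage Otsu convention for dark-side objects
    # (foreground = image > t), so a cluster sitting exactly at the
    # returned threshold stays in the mask
    mask = a <= thresh
    if config.a_threshold_mode == "otsu" and mask.any():
        # Otsu always splits; reject the split when the "green" side isn't green
        if a[mask].mean() > _GREEN_SANITY_A:
            return np.zeros(a.shape, dtype=bool)
    if config.min_region_px > 0:
        # drop components of fewer than min_region_px pixels
        mask = remove_small_objects(mask, max_size=config.min_region_px - 1)
    if config.morph_open_radius > 0:
        mask = opening(mask, disk(config.morph_open_radius))
    return mask


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the mask (elementwise product per channel)."""
    image = np.asarray(image)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} shapes differ"
        )
    return (image * mask[..., None].astype(image.dtype)).astype(image.dtype)


def segment_image(image: np.ndarray, config: SegmentationConfig) -> SegmentationResult:
    """Full segmentation: LAB threshold -> cleaned mask -> masked image."""
    mask = plant_mask(rgb_to_lab(image), config)
    return SegmentationResult(
        mask=mask,
        segmented=apply_mask(image, mask),
        coverage=float(mask.mean()),
    )


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Anti-aliased bilinear resize to ``size x size``, preserving uint8 range."""
    if image.shape[0] == size and image.shape[1] == size:
        return image.astype(np.uint8, copy=False)
    out = resize(image, (size, size), order=1, anti_aliasing=True,
                 preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def preprocess_image(image: np.ndarray, config: SegmentationConfig,
                     remove_background: bool = False) -> np.ndarray:
    """Optionally segment, then resize to the network input size (uint8)."""
    if remove_background:
        image = segment_image(image, config).segmented
    return resize_image(image, config.input_size)


def load_manifest_arrays(manifest, root, config: SegmentationConfig,
                         remove_background: bool = False):
    """Load every manifest image, preprocess, scale into [0, 1] float32.

    Returns ``(X, labels, days)`` where ``X`` is ``(n, S, S, 3)`` float32,
    ``labels`` is an object array of class names, and ``days`` is a float
    array (NaN where the manifest has no day).
    """
    root = Path(root)
    n = len(manifest)
    s = config.input_size
    x = np.empty((n, s, s, 3), dtype=np.float32)
    labels = np.empty(n, dtype=object)
    days = np.full(n, np.nan)
    for i, row in enumerate(manifest.itertuples(index=False)):
        img = np.asarray(Image.open(root / row.path).convert("RGB"))
        x[i] = preprocess_image(img, config, remove_background) / np.float32(255.0)
        labels[i] = row.label
        if row.day is not None and not (isinstance(row.day, float) and np.isnan(row.day)):
            try:
                days[i] = float(row.day)
            except (TypeError, ValueError):
                pass
    return x, labels, days
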