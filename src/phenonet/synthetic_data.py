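"""Synthetic Arabidopsis imagery with ground truth.

Two generators emulate the structure of the real study material without
requiring any download:

* **Rosette time series** — per-plant 22-day sequences of a growing rosette
  photographed against soil.  Each accession (Sf-2, Cvi, Ler-1, Col-0) has
  its own leaf-emergence rate, leaf-elongation rate, leaf aspect ratio and
  hue, so both the genotype and the growth day are recoverable from the
  image.  Leaves unfold at a visible start length (as in real time-lapse
  material, where the day-1 frame already shows an established seedling),
  so every frame of a series carries genotype signal.  The soil background darkens linearly with the day, so background
  pixels also carry (weaker) day information — this is deliberate and makes
  the background-vs-no-background experiment meaningful on synthetic data.
* **Organelle images** — fluorescence-style dark-field frames where the
  class (chloroplast / mitochondria / peroxisome) is encoded purely in blob
  shape statistics: few large round blobs, many small elongated ones, or
  intermediate round dots.

All randomness flows from per-plant (or per-image) child streams of one
root seed, so adding plants to a spec never reshuffles existing ones, and
rendering the same plant twice is bit-identical.

The rosette model guarantees *monotone growth*: every leaf is an ellipse
anchored at the rosette centre whose linear dimensions scale with time, so
the rasterised plant mask at day ``d`` is a subset of the mask at ``d+1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse as draw_ellipse

from .manifest import write_manifest

GOLDEN_ANGLE_DEG = 137.508

# ---------------------------------------------------------------------------
# specs


@dataclass
class AccessionParams:
    """Visual growth parameters of one accession.

    Rates are expressed at the 320 px reference resolution and scaled
    proportionally when rendering at other image sizes.
    """

    name: str
    leaf_count_rate: float   # new leaves per day
    leaf_length_rate: float  # px (at 320 px scale) of leaf elongation per day
    leaf_aspect: float       # minor/major axis ratio of the leaf ellipse
    hue_mean: float          # degrees, green range
    hue_sd: float = 3.0      # degrees
    rosette_jitter: float = 6.0  # px positional jitter of the rosette centre
    leaf_start_length: float = 24.0  # px (320 px scale) a leaf has when it unfolds

    def __post_init__(self):
        if self.leaf_count_rate <= 0 or self.leaf_length_rate <= 0:
            raise ValueError("growth rates must be strictly positive")
        if not 60.0 <= self.hue_mean <= 160.0:
            raise ValueError("hue_mean must lie in the green range [60, 160]")


def make_default_accessions() -> list:
    """The four default accessions, pairwise distinct in several fields."""
    return [
        AccessionParams("Sf-2", leaf_count_rate=0.45, leaf_length_rate=5.2,
                        leaf_aspect=0.34, hue_mean=96.0),
        AccessionParams("Cvi", leaf_count_rate=0.62, leaf_length_rate=4.2,
                        leaf_aspect=0.50, hue_mean=120.0),
        AccessionParams("Ler-1", leaf_count_rate=0.36, leaf_length_rate=6.0,
                        leaf_aspect=0.27, hue_mean=136.0),
        AccessionParams("Col-0", leaf_count_rate=0.52, leaf_length_rate=4.8,
                        leaf_aspect=0.42, hue_mean=110.0),
    ]


@dataclass
class GrowthSeriesSpec:
    """Layout of a rosette time-series dataset."""

    plants_per_accession: Dict[str, int] = field(
        default_factory=lambda: {"Sf-2": 5, "Cvi": 5, "Ler-1": 5, "Col-0": 5}
    )
    n_days: int = 22
    image_size: int = 320
    soil_base_color: Tuple[int, int, int] = (120, 84, 58)
    soil_darkening_rate: float = 1.8  # intensity units per day
    seed: int = 0
    accessions: Optional[list] = None  # defaults to make_default_accessions()

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if any(c < 1 for c in self.plants_per_accession.values()):
            raise ValueError("plant counts must be >= 1")

    def accession_map(self) -> Dict[str, AccessionParams]:
        acc = self.accessions or make_default_accessions()
        table = {a.name: a for a in acc}
        missing = set(self.plants_per_accession) - set(table)
        if missing:
            raise ValueError(f"no AccessionParams for label(s) {sorted(missing)}")
        return table


@dataclass
class BlobClassParams:
    """Shape statistics of one organelle class."""

    count_range: Tuple[int, int]
    radius_range: Tuple[float, float]      # equivalent radius, px
    elongation_range: Tuple[float, float]  # major/minor axis ratio

    def mean_radius(self) -> float:
        return 0.5 * (self.radius_range[0] + self.radius_range[1])


ORGANELLE_CLASSES = ("chloroplast", "mitochondria", "peroxisome")


def default_organelle_classes(image_size: int = 1024) -> Dict[str, BlobClassParams]:
    """Per-class blob statistics, radius scaled from the 1024 px reference."""
    s = image_size / 1024.0
    return {
        "chloroplast": BlobClassParams((8, 16), (28 * s, 40 * s), (1.0, 1.3)),
        "mitochondria": BlobClassParams((40, 70), (6 * s, 10 * s), (2.5, 4.0)),
        "peroxisome": BlobClassParams((30, 60), (7 * s, 11 * s), (1.0, 1.25)),
    }


@dataclass
class OrganelleSpec:
    """Layout of an organelle image dataset."""

    images_per_class: int = 300
    image_size: int = 1024
    class_params: Optional[Dict[str, BlobClassParams]] = None
    seed: int = 0

    def __post_init__(self):
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.class_params is None:
            self.class_params = default_organelle_classes(self.image_size)


# ---------------------------------------------------------------------------
# presets


def desk_growth_spec(seed: int = 0, plants: int = 5) -> GrowthSeriesSpec:
    """Small fast preset: ``plants`` plants per accession at 96 px."""
    return GrowthSeriesSpec(
        plants_per_accession={a.name: plants for a in make_default_accessions()},
        image_size=96,
        seed=seed,
    )


def full_growth_spec(seed: int = 0) -> GrowthSeriesSpec:
    """Full-scale preset matching the real study layout (97 plants, 320 px)."""
    return GrowthSeriesSpec(
        plants_per_accession={"Cvi": 25, "Col-0": 24, "Ler-1": 26, "Sf-2": 22},
        image_size=320,
        seed=seed,
    )


def desk_organelle_spec(seed: int = 0, images_per_class: int = 40) -> OrganelleSpec:
    """Small fast organelle preset at 48 px.

    Blob parameters are set at this scale by hand (not proportionally
    scaled) so that the class-discriminating shape statistics remain
    resolvable: naive 1024 -> 48 scaling would make mitochondrial blobs
    sub-pixel.
    """
    return OrganelleSpec(
        images_per_class=images_per_class,
        image_size=48,
        class_params={
            "chloroplast": BlobClassParams((5, 9), (5.0, 7.0), (1.0, 1.3)),
            "mitochondria": BlobClassParams((18, 30), (1.3, 1.9), (2.5, 4.0)),
            "peroxisome": BlobClassParams((12, 20), (2.3, 3.1), (1.0, 1.25)),
        },
        seed=seed,
    )


def full_organelle_spec(seed: int = 0) -> OrganelleSpec:
    return OrganelleSpec(images_per_class=300, image_size=1024, seed=seed)


# ---------------------------------------------------------------------------
# rosette rendering


@dataclass
class LabeledImage:
    """An RGB image with its class label and (optional) growth day."""

    image: np.ndarray  # uint8 (H, W, 3)
    label: str
    day: Optional[int] = None


def _hsv_to_rgb(h_deg: float, s: float, v: float) -> np.ndarray:
    import colorsys

    r, g, b = colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v)
    return np.array([r, g, b]) * 255.0


def render_rosette(params: AccessionParams, day: int, spec: GrowthSeriesSpec,
                   rng_state, *, max_leaves: Optional[int] = None):
    """Render one plant at one day.

    ``rng_state`` (an int seed, SeedSequence or Generator) identifies the
    plant: calling with the same state and different days renders the same
    individual at different growth stages, with a nested (non-decreasing)
    plant mask.  ``max_leaves=0`` renders soil only (empty mask).

    Returns ``(LabeledImage, mask)`` where ``mask`` is the boolean ground
    truth plant region.
    """
    if not 1 <= day <= spec.n_days:
        raise ValueError(f"day {day} outside [1, {spec.n_days}]")
    rng = np.random.default_rng(rng_state)
    s = spec.image_size
    scale = s / 320.0

    # plant-level draws, in fixed order, independent of `day`
    count_rate = params.leaf_count_rate * max(0.05, 1 + 0.10 * rng.standard_normal())
    len_rate = params.leaf_length_rate * scale * max(
        0.05, 1 + 0.10 * rng.standard_normal()
    )
    centre = s / 2.0 + rng.uniform(-1, 1, 2) * params.rosette_jitter * scale
    n_max = 2 + math.ceil(count_rate * spec.n_days)
    angles = np.arange(n_max) * GOLDEN_ANGLE_DEG + rng.normal(0, 10.0, n_max)
    hues = rng.normal(params.hue_mean, params.hue_sd, n_max)
    vals = rng.uniform(0.35, 0.55, n_max)
    # multiplicative per-pixel leaf texture: real leaves are not flat in
    # colour, and a flat (two-valued) histogram would be degenerate input
    # for histogram-based thresholding downstream
    leaf_texture = np.clip(1.0 + 0.08 * rng.standard_normal((s, s)), 0.7, 1.3)
    soil_noise = rng.normal(0.0, 5.0, (s, s, 1))

    # soil background, darkening with the day; texture is static per plant
    soil = np.asarray(spec.soil_base_color, dtype=float)
    img = np.clip(soil - spec.soil_darkening_rate * day + soil_noise, 0, 255)
    mask = np.zeros((s, s), dtype=bool)

    # leaf i starts growing at day t_i; the first two (cotyledons) at day 1
    starts = np.array(
        [1.0 if i < 2 else 1.0 + (i - 1) / count_rate for i in range(n_max)]
    )
    n_active = n_max if max_leaves is None else min(max_leaves, n_max)
    len_cap = 0.42 * s
    start_len = params.leaf_start_length * scale
    for i in range(n_active):
        if starts[i] > day:
            continue
        length = min(len_cap, start_len + len_rate * (day - starts[i]))
        a = length / 2.0
        b = params.leaf_aspect * a
        if length < 2.0:
            continue  # sub-pixel leaf, not yet drawable
        # displace along the ellipse's own major-axis direction, which for
        # skimage's rotation convention is (cos t, sin t) in (row, col):
        # the leaf then has a vertex exactly at the rosette centre, so the
        # whole leaf is a pure dilation of its day-1 shape and masks nest
        # across days
        theta = math.radians(angles[i])
        er = centre[0] + a * math.cos(theta)
        ec = centre[1] + a * math.sin(theta)
        rr, cc = draw_ellipse(er, ec, a, b, shape=(s, s), rotation=theta)
        if rr.size == 0:
            continue
        mask[rr, cc] = True
        img[rr, cc] = np.clip(
            _hsv_to_rgb(hues[i], 0.75, vals[i]) * leaf_texture[rr, cc, None], 0, 255
        )

    return LabeledImage(img.astype(np.uint8), params.name, day), mask


def _plant_seed(spec_seed: int, group_index: int, item_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(spec_seed, spawn_key=(group_index, item_index))


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in label)


def generate_phenotype_dataset(spec: GrowthSeriesSpec, out_dir) -> pd.DataFrame:
    """Write one PNG per (plant, day) and a ``manifest.csv``; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = spec.accession_map()
    rows = []
    for ai, (label, count) in enumerate(sorted(spec.plants_per_accession.items())):
        params = table[label]
        for pi in range(count):
            seed = _plant_seed(spec.seed, ai, pi)
            for day in range(1, spec.n_days + 1):
                sample, _ = render_rosette(params, day, spec, seed)
                name = f"{_safe(label)}_p{pi:03d}_d{day:02d}.png"
                Image.fromarray(sample.image).save(out_dir / name)
                rows.append({"path": name, "label": label, "day": day,
                             "split": "unassigned"})
    df = pd.DataFrame(rows)
    df["day"] = df["day"].astype("Int64")
    write_manifest(df, out_dir / "manifest.csv")
    return df


# ---------------------------------------------------------------------------
# organelle rendering

ORGANELLE_TINT = np.array([255.0, 214.0, 48.0])  # pseudo-stain yellow


def render_organelle_image(params: BlobClassParams, size: int, rng_state) -> np.ndarray:
    """One dark-field frame of bright elliptical blobs; returns uint8 RGB.

    Blobs have semi-axes ``(r * sqrt(e), r / sqrt(e))`` so their area is
    ``pi * r**2`` regardless of elongation ``e`` — the equivalent radius
    measured from the image estimates ``r`` directly.
    """
    rng = np.random.default_rng(rng_state)
    canvas = np.zeros((size, size), dtype=float)
    n = int(rng.integers(params.count_range[0], params.count_range[1] + 1))
    margin = params.radius_range[1] * math.sqrt(params.elongation_range[1])
    for _ in range(n):
        r = rng.uniform(*params.radius_range)
        e = rng.uniform(*params.elongation_range)
        ang = rng.uniform(0, math.pi)
        er = rng.uniform(margin, size - margin)
        ec = rng.uniform(margin, size - margin)
        bright = rng.uniform(0.6, 1.0)
        rr, cc = draw_ellipse(er, ec, r * math.sqrt(e), r / math.sqrt(e),
                              shape=(size, size), rotation=ang)
        canvas[rr, cc] = np.maximum(canvas[rr, cc], bright)
    noise = rng.normal(0, 0.01, (size, size))
    field = np.clip(canvas + 0.03 + noise, 0, 1)
    return np.clip(field[..., None] * ORGANELLE_TINT, 0, 255).astype(np.uint8)


def generate_organelle_dataset(spec: OrganelleSpec, out_dir) -> pd.DataFrame:
    """Write ``images_per_class`` PNGs per organelle class plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, label in enumerate(ORGANELLE_CLASSES):
        params = spec.class_params[label]
        for i in range(spec.images_per_class):
            img = render_organelle_image(params, spec.image_size,
                                         _plant_seed(spec.seed, ci, i))
            name = f"{_safe(label)}_{i:04d}.png"
            Image.fromarray(img).save(out_dir / name)
            rows.append({"path": name, "label": label, "day": pd.NA,
                         "split": "unassigned"})
    df = pd.DataFrame(rows)
    df["day"] = df["day"].astype("Int64")
    write_manifest(df, out_dir / "manifest.csv")
    return df
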