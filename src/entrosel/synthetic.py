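"""Synthetic MRI-like images, boxes and 1-D signals with planted class structure.

The generator emulates the structure of a brain-MRI ROI dataset so every
downstream stage is testable without real scans or a trained detector:

* background (non-tumor) tissue is a smooth, strongly autocorrelated texture
  — an AR(1) process (coefficient 0.95 by default) lightly blurred — on a
  brain-like elliptical disk over a dark field;
* tumor tissue is an elliptical blob of high-variance speckle texture (white
  noise mixed with sparse large-amplitude bursts), i.e. higher textural
  irregularity and hence higher entropy than background.

"Paper-emulation" mode fixes the dataset shape to 583/123/128 train/val/test
images, each test image contributing one tumor and one non-tumor ROI, so the
classification stage sees a 256-row table.  Splitting happens before ROI
extraction and no source image crosses splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .preprocess import BoundingBox, Image, RegionClass

PAPER_SPLIT_COUNTS = (583, 123, 128)  # train / val / test images


@dataclass
class SynthConfig:
    image_size: tuple[int, int] = (160, 160)
    blob_radius_range: tuple[int, int] = (12, 30)
    tumor_noise_sd: float = 40.0
    speckle_weight: float = 0.5
    speckle_rate: float = 0.15
    speckle_scale: float = 90.0
    ar_coefficient: float = 0.95
    ar_innovation_sd: float = 8.0
    background_level: float = 110.0
    tumor_level: float = 150.0
    n_per_class: int = 50
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise InvalidArgumentError("split fractions must sum to 1")
        if not -1 < self.ar_coefficient < 1:
            raise InvalidArgumentError("AR coefficient must lie in (-1, 1)")
        if self.n_per_class < 1:
            raise InvalidArgumentError("counts must be >= 1")
        if 2 * self.blob_radius_range[1] >= min(self.image_size):
            raise InvalidArgumentError("blob larger than image")


def _ar1_field(shape: tuple[int, int], coef: float, innovation_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Raster-order AR(1) noise lightly blurred into a smooth 2-D texture."""
    from scipy import ndimage

    n = shape[0] * shape[1]
    eps = rng.normal(0.0, innovation_sd, size=n)
    x = np.empty(n)
    x[0] = eps[0]
    for i in range(1, n):  # first-order recursion along the raster scan
        x[i] = coef * x[i - 1] + eps[i]
    field = x.reshape(shape)
    return ndimage.gaussian_filter(field, sigma=1.5, mode="reflect")


def _ar1_series(length: int, coef: float, innovation_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, innovation_sd, size=length)
    x = np.empty(length)
    x[0] = eps[0]
    for i in range(1, length):
        x[i] = coef * x[i - 1] + eps[i]
    return x


def _speckle_series(length: int, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """White noise mixed with sparse large-amplitude bursts (tumor texture)."""
    noise = rng.normal(0.0, config.tumor_noise_sd, size=length)
    bursts = rng.random(length) < config.speckle_rate
    spikes = np.where(bursts, rng.choice([-1.0, 1.0], size=length)
                      * rng.exponential(config.speckle_scale, size=length), 0.0)
    return (1 - config.speckle_weight) * noise + config.speckle_weight * spikes


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _box_from_rect(r0: int, r1: int, c0: int, c1: int, shape: tuple[int, int],
                   cls: RegionClass) -> BoundingBox:
    h, w = shape
    return BoundingBox(cls, cx=(c0 + c1) / (2 * w), cy=(r0 + r1) / (2 * h),
                       w=(c1 - c0) / w, h=(r1 - r0) / h)


def generate_image(cls: RegionClass, config: SynthConfig,
                   rng: np.random.Generator, image_id: str = "") -> tuple[Image, list[BoundingBox]]:
    """One synthetic image with its boxes.

    Every image yields a non-tumor box over background tissue; tumor-class
    images additionally contain a speckle blob with its enclosing tumor box.
    """
    h, w = config.image_size
    px = np.full((h, w), 10.0)  # dark field
    brain_c = (h / 2.0, w / 2.0)
    brain_r = (0.42 * h, 0.46 * w)
    brain = _ellipse_mask((h, w), brain_c, brain_r)
    texture = _ar1_field((h, w), config.ar_coefficient, config.ar_innovation_sd, rng)
    px[brain] = config.background_level + texture[brain]

    boxes: list[BoundingBox] = []
    tumor_rect = None
    if cls is RegionClass.TUMOR:
        r_min, r_max = config.blob_radius_range
        ra = rng.integers(r_min, r_max + 1)
        rb = rng.integers(r_min, r_max + 1)
        # keep the blob inside the brain disk
        cy = rng.uniform(brain_c[0] - brain_r[0] * 0.5, brain_c[0] + brain_r[0] * 0.5)
        cx = rng.uniform(brain_c[1] - brain_r[1] * 0.5, brain_c[1] + brain_r[1] * 0.5)
        blob = _ellipse_mask((h, w), (cy, cx), (ra, rb))
        n_blob = int(blob.sum())
        px[blob] = config.tumor_level + _speckle_series(n_blob, config, rng)
        r0, r1 = max(int(cy - ra), 0), min(int(cy + ra) + 1, h)
        c0, c1 = max(int(cx - rb), 0), min(int(cx + rb) + 1, w)
        tumor_rect = (r0, r1, c0, c1)
        boxes.append(_box_from_rect(r0, r1, c0, c1, (h, w), RegionClass.TUMOR))

    # non-tumor box: background tissue patch, disjoint from the tumor rect
    side = int(rng.integers(config.blob_radius_range[0] * 2, config.blob_radius_range[1] * 2))
    for _ in range(200):
        r0 = int(rng.integers(int(brain_c[0] - brain_r[0] * 0.6),
                              int(brain_c[0] + brain_r[0] * 0.6 - side)))
        c0 = int(rng.integers(int(brain_c[1] - brain_r[1] * 0.6),
                              int(brain_c[1] + brain_r[1] * 0.6 - side)))
        r1, c1 = r0 + side, c0 + side
        if tumor_rect is None:
            break
        tr0, tr1, tc0, tc1 = tumor_rect
        if r1 <= tr0 or r0 >= tr1 or c1 <= tc0 or c0 >= tc1:
            break
    boxes.append(_box_from_rect(r0, r1, c0, c1, (h, w), RegionClass.NON_TUMOR))

    px = np.clip(px, 0.0, 255.0)
    return Image(px, image_id=image_id), boxes


@dataclass
class DatasetManifest:
    splits: dict[str, list[str]] = field(default_factory=dict)

    def subset_of(self, image_id: str) -> str:
        for name, ids in self.splits.items():
            if image_id in ids:
                return name
        raise KeyError(image_id)


def generate_dataset(config: SynthConfig, paper_mode: bool = False,
                     subset: str | None = None):
    """Images, per-image boxes and a train/val/test manifest.

    ``paper_mode=True`` fixes counts to 583/123/128 tumor-bearing images (two
    ROIs each), yielding a 256-row classification table for the test split.
    The seeded split shuffle happens before any ROI extraction and image ids
    never cross subsets.  Each image draws from its own child RNG keyed by
    (seed, index), so ``subset`` can restrict materialization to one split
    without changing any image's content.
    """
    rng = np.random.default_rng(config.seed)
    if paper_mode:
        ids_cls = [(f"img_{i:04d}", RegionClass.TUMOR) for i in range(sum(PAPER_SPLIT_COUNTS))]
        counts = PAPER_SPLIT_COUNTS
    else:
        ids_cls = [(f"img_t{i:04d}", RegionClass.TUMOR) for i in range(config.n_per_class)]
        ids_cls += [(f"img_n{i:04d}", RegionClass.NON_TUMOR) for i in range(config.n_per_class)]
        total = len(ids_cls)
        n_train = int(round(config.split_fractions[0] * total))
        n_val = int(round(config.split_fractions[1] * total))
        counts = (n_train, n_val, total - n_train - n_val)
        if min(counts) < 1:
            raise InvalidArgumentError("counts too small for the requested split")

    # stratified seeded shuffle prior to generation/extraction
    order = rng.permutation(len(ids_cls))
    shuffled = [ids_cls[i] for i in order]
    splits = {
        "train": [sid for sid, _ in shuffled[: counts[0]]],
        "val": [sid for sid, _ in shuffled[counts[0] : counts[0] + counts[1]]],
        "test": [sid for sid, _ in shuffled[counts[0] + counts[1] :]],
    }
    manifest = DatasetManifest(splits=splits)

    if subset is None:
        wanted = None
    elif subset == "none":  # manifest only, no image materialization
        wanted = set()
    else:
        wanted = set(manifest.splits[subset])
    images: dict[str, Image] = {}
    boxes: dict[str, list[BoundingBox]] = {}
    for i, (sid, cls) in enumerate(ids_cls):
        if wanted is not None and sid not in wanted:
            continue
        child = np.random.default_rng([config.seed, i])
        img, bxs = generate_image(cls, config, child, image_id=sid)
        images[sid] = img
        boxes[sid] = bxs
    return images, boxes, manifest


def generate_signal_pair(cls: RegionClass, length: int, config: SynthConfig,
                         rng: np.random.Generator):
    """A :class:`SamplePair`-ready (primary, reference) signal couple.

    Tumor signals are speckle mixtures; non-tumor signals are AR(1).  The
    reference is the opposite-class texture drawn from the same seed stream,
    mimicking the within-image tumor/background pairing.
    """
    from .entropy.registry import SamplePair

    if length < 64:
        raise InvalidArgumentError("length must be >= 64")
    tumor = config.tumor_level + _speckle_series(length, config, rng)
    background = config.background_level + _ar1_series(
        length, config.ar_coefficient, config.ar_innovation_sd, rng
    )
    if cls is RegionClass.TUMOR:
        primary, reference = tumor, background
    else:
        primary, reference = background, tumor
    return SamplePair(primary, reference, cls)


def generate_pair_table(n_per_class: int, length: int, config: SynthConfig, seed: int):
    """Convenience: n tumor + n non-tumor sample pairs from one seeded stream."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_per_class):
        pairs.append(generate_signal_pair(RegionClass.TUMOR, length, config, rng))
        pairs.append(generate_signal_pair(RegionClass.NON_TUMOR, length, config, rng))
    return pairs
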