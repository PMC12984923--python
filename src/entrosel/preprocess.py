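"""ROI standardization: denoising, resizing, cropping and 1-D transformation.

Image patches are held as float arrays in arbitrary intensity units.  Bounding
boxes follow the YOLO text convention (normalized center format).  Cropped
regions of interest (ROIs) are resized to a configurable standard size and
raster-scanned (row-major, top-left origin) into 1-D signals for the entropy
feature bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DegenerateRoiError, InvalidArgumentError, InvalidInputError

#: kernel truncation radius for Gaussian denoising, in units of sigma
GAUSS_TRUNCATE = 4.0

#: default standard ROI size (pixels per side) after resizing
DEFAULT_ROI_SIZE = 64

#: default denoising bandwidth in pixels
DEFAULT_SIGMA = 1.0


class RegionClass(str, Enum):
    TUMOR = "tumor"
    NON_TUMOR = "non_tumor"


#: YOLO class index mapping: class 0 = tumor, class 1 = non_tumor
YOLO_CLASS_MAP = {0: RegionClass.TUMOR, 1: RegionClass.NON_TUMOR}
YOLO_CLASS_INDEX = {RegionClass.TUMOR: 0, RegionClass.NON_TUMOR: 1}


@dataclass
class Image:
    """A 2-D grayscale intensity grid with an opaque identifier."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InvalidInputError("image must be a 2-D grid with positive dimensions")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("image contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BoundingBox:
    """Normalized center-format box: (cx, cy) center, (w, h) extent, all in [0,1]."""

    region_class: RegionClass
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise InvalidInputError("box center must lie in the unit square")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise InvalidInputError("box extent must lie in (0, 1]")


@dataclass
class RoiPatch:
    """A cropped 2-D region with its class label and source-image identity."""

    pixels: np.ndarray
    region_class: RegionClass
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("ROI contains non-finite intensities")


def gaussian_denoise(image: Image, sigma: float = DEFAULT_SIGMA) -> Image:
    """Convolve with a normalized 2-D Gaussian kernel (reflective borders).

    ``sigma`` is the kernel bandwidth in pixels; the kernel is truncated at
    4*sigma.  ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise InvalidArgumentError("sigma must be >= 0")
    if sigma == 0:
        return Image(image.pixels.copy(), image.image_id)
    out = ndimage.gaussian_filter(image.pixels, sigma=sigma, mode="reflect", truncate=GAUSS_TRUNCATE)
    return Image(out, image.image_id)


def bilinear_resize(image: Image, target_h: int, target_w: int) -> Image:
    """Bilinear resampling with align-corners coordinate mapping.

    Output corner samples coincide with input corner samples; resizing to the
    current dimensions returns the pixels unchanged.
    """
    if target_h < 1 or target_w < 1:
        raise InvalidArgumentError("target dimensions must be >= 1")
    h, w = image.pixels.shape
    if (target_h, target_w) == (h, w):
        return Image(image.pixels.copy(), image.image_id)
    rows = np.linspace(0.0, h - 1.0, target_h) if target_h > 1 else np.array([(h - 1) / 2.0])
    cols = np.linspace(0.0, w - 1.0, target_w) if target_w > 1 else np.array([(w - 1) / 2.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(image.pixels, [rr, cc], order=1, mode="nearest")
    return Image(out, image.image_id)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def crop_roi(image: Image, box: BoundingBox) -> RoiPatch:
    """Crop the pixel rectangle denoted by a normalized center-format box.

    Coordinates are denormalized by rounding half up into 0-based, half-open
    pixel intervals.  Crops smaller than 2x2 raise :class:`DegenerateRoiError`.
    """
    h, w = image.pixels.shape
    c0 = _round_half_up((box.cx - box.w / 2.0) * w)
    c1 = _round_half_up((box.cx + box.w / 2.0) * w)
    r0 = _round_half_up((box.cy - box.h / 2.0) * h)
    r1 = _round_half_up((box.cy + box.h / 2.0) * h)
    c0, c1 = max(c0, 0), min(c1, w)
    r0, r1 = max(r0, 0), min(r1, h)
    if (r1 - r0) < 2 or (c1 - c0) < 2:
        raise DegenerateRoiError(f"crop [{r0}:{r1}, {c0}:{c1}] is smaller than 2x2")
    return RoiPatch(image.pixels[r0:r1, c0:c1].copy(), box.region_class, image.image_id)


def scale_intensity(pixels: np.ndarray, lo: float = 0.0, hi: float = 255.0) -> np.ndarray:
    """Map intensities linearly onto [lo, hi]; a constant input maps to all-lo.

    Fixing the range lets histogram-based measures use a fixed support.
    """
    pixels = np.asarray(pixels, dtype=float)
    pmin, pmax = pixels.min(), pixels.max()
    if pmax == pmin:
        return np.full_like(pixels, lo)
    return lo + (pixels - pmin) * (hi - lo) / (pmax - pmin)


def standardize_roi(
    patch: RoiPatch,
    roi_size: int = DEFAULT_ROI_SIZE,
    sigma: float = DEFAULT_SIGMA,
    rescale: bool = True,
) -> RoiPatch:
    """Denoise, resize to ``roi_size`` x ``roi_size`` and rescale to [0, 255]."""
    img = Image(patch.pixels, patch.source_image_id)
    img = gaussian_denoise(img, sigma)
    img = bilinear_resize(img, roi_size, roi_size)
    px = scale_intensity(img.pixels) if rescale else img.pixels
    return RoiPatch(px, patch.region_class, patch.source_image_id)


def flatten_to_signal(patch: RoiPatch) -> np.ndarray:
    """Row-major raster scan of the patch (top-left origin)."""
    return patch.pixels.ravel(order="C").copy()


def unflatten_signal(signal: np.ndarray, height: int, width: int) -> np.ndarray:
    """Inverse of :func:`flatten_to_signal`; recovers the 2-D grid exactly."""
    signal = np.asarray(signal, dtype=float)
    if signal.size != height * width:
        raise InvalidArgumentError("signal length does not match the requested grid")
    return signal.reshape(height, width)


# ---------------------------------------------------------------------------
# File I/O: PNG/TIFF grayscale images and YOLO label text files
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> Image:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)), dtype=float)
    if arr.ndim == 3:  # collapse any color axis to luminance by simple mean
        arr = arr.mean(axis=-1)
    return Image(arr, image_id=Path(path).stem)


def save_image(image: Image, path: str | Path) -> None:
    import imageio.v3 as iio

    px = np.clip(image.pixels, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), px)


def parse_yolo_labels(text: str) -> list[BoundingBox]:
    """Parse YOLO label lines: ``class cx cy w h`` (whitespace separated)."""
    boxes = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise InvalidInputError(f"malformed YOLO label line: {line!r}")
        cls_idx = int(parts[0])
        if cls_idx not in YOLO_CLASS_MAP:
            raise InvalidInputError(f"unknown class index {cls_idx}")
        cx, cy, w, h = (float(v) for v in parts[1:])
        boxes.append(BoundingBox(YOLO_CLASS_MAP[cls_idx], cx, cy, w, h))
    return boxes


def format_yolo_labels(boxes: list[BoundingBox]) -> str:
    lines = [
        f"{YOLO_CLASS_INDEX[b.region_class]} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        for b in boxes
    ]
    return "\n".join(lines) + ("\n" if lines else "")
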