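"""Segmentation of myelin-positive signal ("step 1" of the complexity analysis).

The stages mirror the blinded-analysis workflow used on MBP immunostains:
rolling-ball style background subtraction, conversion to 8-bit, global
thresholding (Otsu by default, manual override available), optional hole
filling, and removal of small noise particles.  Background subtraction is
realized as grayscale opening with a disk structuring element, the
documented contract of the rolling-ball operation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .io import Micrograph

__all__ = [
    "SegmentationParams",
    "BinaryMask",
    "subtract_background",
    "disk_opening",
    "otsu_threshold",
    "apply_threshold",
    "to_8bit",
    "remove_small_particles",
    "segment",
]


@dataclass
class SegmentationParams:
    """Parameters of the segmentation pipeline.

    Attributes
    ----------
    rolling_ball_radius : int
        Disk radius (px) of the background estimate; >= 1.  Features wider
        than roughly twice the radius start to be treated as background.
    threshold_mode : str
        ``"otsu"`` (default, reproducible) or ``"manual"``.
    manual_threshold : int
        8-bit intensity cut used iff ``threshold_mode == "manual"``.
    min_particle_area : int
        Components (8-connected) smaller than this many pixels are removed.
    fill_holes : bool
        Fill enclosed background holes before particle removal.
    """

    rolling_ball_radius: int = 50
    threshold_mode: str = "otsu"
    manual_threshold: int = 128
    min_particle_area: int = 20
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.threshold_mode not in ("otsu", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0 <= self.manual_threshold <= 65535:
            raise ValueError("manual_threshold outside intensity range")
        if self.min_particle_area < 0:
            raise ValueError("min_particle_area must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class BinaryMask:
    """Boolean raster of myelin-positive pixels, with provenance."""

    mask: np.ndarray
    pixel_size: float
    params: SegmentationParams | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def field_area_mm2(self) -> float:
        return self.mask.size * (self.pixel_size * 1e-3) ** 2


def _disk_rank_filter(img: np.ndarray, radius: int, maximum: bool) -> np.ndarray:
    """Exact grayscale erosion/dilation by a Euclidean disk.

    The disk of radius r is decomposed into its horizontal chords: row
    offset dr contributes a 1D window of half-width floor(sqrt(r²-dr²)).
    Out-of-image pixels are ignored (min/max over the in-bounds part of
    the disk), so constants are exact fixed points.  O(radius · n) via
    running 1D filters.
    """
    rows = img.shape[0]
    fill = -np.inf if maximum else np.inf
    filt = ndimage.maximum_filter1d if maximum else ndimage.minimum_filter1d
    reduce_ = np.maximum if maximum else np.minimum
    work = img.astype(np.float64)
    out = np.full_like(work, fill)
    for dr in range(-radius, radius + 1):
        if abs(dr) >= rows:
            continue
        half = int(math.floor(math.sqrt(radius * radius - dr * dr)))
        line = filt(work, 2 * half + 1, axis=1, mode="constant", cval=fill)
        if dr >= 0:
            out[: rows - dr] = reduce_(out[: rows - dr], line[dr:])
        else:
            out[-dr:] = reduce_(out[-dr:], line[: rows + dr])
    return out


def disk_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening (erosion then dilation) by a Euclidean disk."""
    return _disk_rank_filter(_disk_rank_filter(img, radius, False), radius, True)


def subtract_background(image: Micrograph, radius: int = 50) -> Micrograph:
    """Subtract a morphological background estimate (grayscale opening).

    The background is the grayscale opening of the image by a disk of the
    given radius — the rolling-ball contract: structures narrower than
    the disk survive the subtraction, broad background does not.  The
    result is nonnegative and never exceeds the input.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    background = disk_opening(image.pixels, radius)
    out = (image.pixels - background).astype(image.pixels.dtype)
    return Micrograph(out, image.bit_depth, image.pixel_size, image.source_id)


def otsu_threshold(image: Micrograph | np.ndarray) -> int:
    """Otsu's threshold: the cut maximizing between-class intensity variance.

    Candidates t split the histogram into {intensity <= t} and
    {intensity > t}; the smallest argmax is returned, so the result is
    deterministic.  Raises on a constant image.
    """
    pixels = image.pixels if isinstance(image, Micrograph) else np.asarray(image)
    n_bins = 256 if pixels.max() <= 255 else 65536
    hist = np.bincount(pixels.ravel().astype(np.int64), minlength=n_bins).astype(
        np.float64
    )
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: no threshold separates two classes")
    total = hist.sum()
    levels = np.arange(n_bins, dtype=np.float64)
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu0 = np.divide(sum0, w0, out=np.zeros_like(sum0), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros_like(sum0), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[w1 == 0] = -1.0  # t with empty upper class is not a valid cut
    return int(np.argmax(between))


def apply_threshold(image: Micrograph, t: int) -> BinaryMask:
    """Binary mask, true where intensity > t."""
    return BinaryMask(image.pixels > t, image.pixel_size)


def to_8bit(image: Micrograph) -> Micrograph:
    """Linearly rescale [min, max] to [0, 255] (round half away from zero).

    8-bit input is returned unchanged; a constant image maps to all zeros.
    """
    if image.bit_depth == 8:
        return image
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros(image.shape, dtype=np.uint8)
    else:
        scaled = 255.0 * (px - lo) / (hi - lo)
        out = np.floor(scaled + 0.5).astype(np.uint8)  # half away from zero (>=0)
    return Micrograph(out, 8, image.pixel_size, image.source_id)


def remove_small_particles(mask: BinaryMask, min_area: int) -> BinaryMask:
    """Delete 8-connected foreground components with fewer than min_area px."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area <= 1:
        return BinaryMask(mask.mask.copy(), mask.pixel_size, mask.params)
    labels, n = ndimage.label(mask.mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return BinaryMask(mask.mask.copy(), mask.pixel_size, mask.params)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return BinaryMask(keep[labels], mask.pixel_size, mask.params)


def segment(image: Micrograph, params: SegmentationParams | None = None) -> BinaryMask:
    """Full segmentation pipeline producing the myelin-positive mask.

    Composition: subtract_background -> to_8bit -> threshold (Otsu or
    manual) -> optional hole filling -> remove_small_particles.  A blank
    field (constant after background subtraction) raises, reported as
    "no signal detected".
    """
    params = params or SegmentationParams()
    corrected = subtract_background(image, params.rolling_ball_radius)
    img8 = to_8bit(corrected)
    if params.threshold_mode == "otsu":
        try:
            t = otsu_threshold(img8)
        except ValueError as exc:
            raise ValueError(f"no signal detected in {image.source_id!r}") from exc
    else:
        t = int(params.manual_threshold)
    mask = apply_threshold(img8, t)
    if params.fill_holes:
        mask = BinaryMask(
            ndimage.binary_fill_holes(mask.mask), mask.pixel_size, params
        )
    out = remove_small_particles(mask, params.min_particle_area)
    return BinaryMask(out.mask, image.pixel_size, params)
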