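"""Image and result I/O.

Coordinate convention used throughout the package: the origin is the
top-left pixel, indexing is 0-based ``(row, col)``, and the row index
increases downward.  The pixel scale (µm per pixel, isotropic) is a
required user input; no proprietary microscope metadata is parsed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "Micrograph",
    "RegionOfInterest",
    "ResultRow",
    "read_micrograph",
    "read_mask",
    "write_micrograph",
    "write_mask",
    "write_results",
    "write_overlay",
]

#: RGB color used for mask/skeleton pixels in overlay renderings.
OVERLAY_COLOR = (255, 0, 0)

ROI_LABELS = frozenset(
    {"signal", "background", "total_cortex", "myelinated_cortex", "analysis"}
)


@dataclass
class Micrograph:
    """A 2D single-channel intensity image with physical pixel scale.

    Parameters
    ----------
    pixels : ndarray
        2D non-negative intensity raster (rows x cols).
    bit_depth : int
        8 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size : float
        Micrometres per pixel (isotropic, > 0).
    source_id : str
        Free-text provenance label.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(f"image too small: {self.pixels.shape} (minimum 16x16)")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_intensity(self) -> int:
        """Largest representable intensity at this bit depth."""
        return 2**self.bit_depth - 1

    def field_area_mm2(self) -> float:
        """Physical area of the whole field in mm²."""
        n_px = self.pixels.size
        return n_px * (self.pixel_size * 1e-3) ** 2


@dataclass
class RegionOfInterest:
    """A boolean mask congruent with a parent micrograph.

    ``label`` names the role of the region: ``signal``, ``background``,
    ``total_cortex``, ``myelinated_cortex`` or ``analysis``.
    """

    mask: np.ndarray
    label: str = "analysis"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}")
        if self.label in ("signal", "analysis") and not self.mask.any():
            raise ValueError(f"ROI with label {self.label!r} must be nonempty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_rectangle(
        cls, shape: tuple[int, int], top: int, left: int, bottom: int, right: int,
        label: str = "analysis",
    ) -> "RegionOfInterest":
        """Rectangular ROI; bounds half-open, (row, col) indexing."""
        m = np.zeros(shape, dtype=bool)
        m[top:bottom, left:right] = True
        return cls(m, label)


@dataclass
class ResultRow:
    """One measured metric for one source image."""

    source_id: str
    metric: str
    value: float
    units: str = ""
    params: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.metric!r} has non-finite value {self.value}")


def _as_micrograph(arr: np.ndarray, pixel_size: float, source_id: str) -> Micrograph:
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif np.issubdtype(arr.dtype, np.integer):
        depth = 8 if arr.max() <= 255 else 16
        arr = arr.astype(np.uint16 if depth == 16 else np.uint8)
    else:
        raise ValueError(f"unsupported image dtype {arr.dtype}; expected 8- or 16-bit")
    return Micrograph(arr, depth, pixel_size, source_id)


def read_micrograph(
    path: str | os.PathLike,
    pixel_size: float,
    channel: int | None = None,
) -> Micrograph:
    """Read a TIFF or PNG micrograph, preserving intensities bit-exactly.

    Multi-channel (RGB) input is accepted only when a ``channel`` index is
    given, or when all channels are identical (then channel 0 is used).
    3D stacks are rejected.
    """
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] > 4:
            raise ValueError(f"3D stacks are not supported (shape {arr.shape})")
        if channel is None:
            if all(
                np.array_equal(arr[..., 0], arr[..., c]) for c in range(arr.shape[2])
            ):
                arr = arr[..., 0]
            else:
                raise ValueError(
                    "multi-channel image with unequal channels; pass a channel index"
                )
        else:
            arr = arr[..., channel]
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    return _as_micrograph(arr, pixel_size, source_id=os.path.basename(path))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a boolean mask from an image file (nonzero -> True)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_micrograph(image: Micrograph, path: str | os.PathLike) -> None:
    """Write the raw intensity raster to TIFF or PNG (bit-exact)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    arr = image.pixels.astype(np.uint8 if image.bit_depth == 8 else np.uint16)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit image with values {0, 255}."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr).save(os.fspath(path))


def write_results(rows: list[ResultRow], path: str | os.PathLike) -> None:
    """Write ResultRows as CSV with header; values survive round-trip exactly.

    Columns: ``source_id,metric,value,units,params``.
    """
    if not rows:
        raise ValueError("no result rows to write")
    df = pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "metric": r.metric,
                "value": repr(float(r.value)),
                "units": r.units,
                "params": r.params,
            }
            for r in rows
        ]
    )
    df.to_csv(os.fspath(path), index=False)


def read_results(path: str | os.PathLike) -> list[ResultRow]:
    """Read back a CSV written by :func:`write_results`."""
    df = pd.read_csv(os.fspath(path), keep_default_na=False)
    return [
        ResultRow(
            source_id=str(r.source_id),
            metric=str(r.metric),
            value=float(r.value),
            units=str(r.units),
            params=str(r.params),
        )
        for r in df.itertuples()
    ]


def to_8bit_display(image: Micrograph) -> np.ndarray:
    """8-bit rendering for overlays: identity for 8-bit, >>8 for 16-bit."""
    if image.bit_depth == 8:
        return image.pixels.astype(np.uint8)
    return (image.pixels >> 8).astype(np.uint8)


def write_overlay(
    image: Micrograph,
    mask_or_skeleton: np.ndarray,
    path: str | os.PathLike,
    color: tuple[int, int, int] = OVERLAY_COLOR,
) -> np.ndarray:
    """Write an RGB rendering with overlay pixels painted in ``color``.

    Pixels outside the overlay keep their grayscale value in all three
    channels.  Returns the rendered RGB array.
    """
    overlay = np.asarray(mask_or_skeleton, dtype=bool)
    if overlay.shape != image.shape:
        raise ValueError(
            f"overlay shape {overlay.shape} does not match image {image.shape}"
        )
    gray = to_8bit_display(image)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[overlay] = np.asarray(color, dtype=np.uint8)
    Image.fromarray(rgb).save(os.fspath(path))
    return rgb
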