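"""Extent-of-myelination metrics.

Three standard measures of how much myelin a cortical field contains:

* **myelinated-cortex fraction** — area of the myelinated band divided by
  the total cortical area, as a percentage (drawn as ROIs on low-power
  images);
* **immunodensity** — mean grey value over the signal region minus the
  mean of a background-staining region, optionally normalized to the mean
  of control animals (controls = 100 %);
* **positive-area fraction** — percentage of the analysis field covered
  by the thresholded myelin-positive mask.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import Micrograph, RegionOfInterest
from .segmentation import BinaryMask

__all__ = [
    "myelinated_cortex_fraction",
    "immunodensity",
    "normalize_to_control",
    "positive_area_fraction",
    "darkest_fraction_roi",
]


def myelinated_cortex_fraction(
    total_cortex: RegionOfInterest, myelinated: RegionOfInterest
) -> float:
    """100 * area(myelinated) / area(total_cortex); areas in px (scale cancels).

    The myelinated region must lie inside the total-cortex region.
    """
    if total_cortex.area_px == 0:
        raise ValueError("total_cortex ROI is empty")
    if np.any(myelinated.mask & ~total_cortex.mask):
        raise ValueError("myelinated ROI extends outside total_cortex ROI")
    return 100.0 * myelinated.area_px / total_cortex.area_px


def immunodensity(
    image: Micrograph,
    signal: RegionOfInterest,
    background: RegionOfInterest,
) -> float:
    """Background-corrected mean grey value over the signal region.

    Returns mean(signal) - mean(background) in native intensity units.
    A negative result (background brighter than signal) is reported as
    computed, with a warning — clipping would bias group means.
    """
    if not signal.mask.any() or not background.mask.any():
        raise ValueError("signal and background ROIs must be nonempty")
    value = float(
        image.pixels[signal.mask].mean() - image.pixels[background.mask].mean()
    )
    if value < 0:
        warnings.warn(
            f"negative background-corrected immunodensity ({value:.3g}) for "
            f"{image.source_id!r}; reported unclipped",
            stacklevel=2,
        )
    return value


def normalize_to_control(
    values: "np.ndarray | list[float]",
    control_values: "np.ndarray | list[float]",
) -> np.ndarray:
    """Express per-animal values as a percentage of the control-group mean.

    The control group's transformed mean is exactly 100.
    """
    control_mean = float(np.mean(control_values))
    if not control_mean > 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return 100.0 * np.asarray(values, dtype=float) / control_mean


def positive_area_fraction(
    mask: BinaryMask, analysis_roi: RegionOfInterest | None = None
) -> float:
    """Percentage of the field (or ROI) that is myelin-positive."""
    if analysis_roi is None:
        roi = np.ones(mask.shape, dtype=bool)
    else:
        if analysis_roi.mask.shape != mask.shape:
            raise ValueError("ROI shape does not match mask")
        roi = analysis_roi.mask
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("analysis ROI is empty")
    return 100.0 * int((mask.mask & roi).sum()) / n_roi


def darkest_fraction_roi(image: Micrograph, fraction: float = 0.05) -> RegionOfInterest:
    """Fallback background region: the darkest ``fraction`` of pixels.

    Used when no background-staining ROI is supplied; a deviation from
    drawing the region by hand, and documented as such in outputs.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = max(1, int(round(fraction * image.pixels.size)))
    cut = np.partition(image.pixels.ravel(), n - 1)[n - 1]
    mask = image.pixels <= cut
    return RegionOfInterest(mask, "background")
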