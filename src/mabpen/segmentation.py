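"""Tumor and functional-vessel segmentation.

The tumor foreground is derived from the nuclei (DAPI) channel: Gaussian
smoothing, thresholding (Otsu by default), hole filling, small-object
removal, then the largest connected component.  The sub-pixel boundary
contour is extracted at the 0.5-level of the binary mask, so it runs halfway
between foreground and background pixel centers — the same boundary
definition used for all distance measurements.

Vessels are thresholded on the lectin channel (unsmoothed by default: vessel
lumina are only a few pixels across and smoothing erodes them; small-object
filtering handles speckle), filtered by minimum area, and optionally
restricted to the tumor mask.  The study protocol traced these regions by
hand; automatic thresholding substitutes a reproducible surrogate, and
externally drawn masks can be injected via :func:`mabpen.io.read_mask`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .exceptions import EmptyVesselMaskWarning, SegmentationError
from .io import BoundaryContour, Mask, SectionImage


@dataclass
class SegmentationParams:
    threshold_method: str = "otsu"     # {"otsu", "fixed"}
    fixed_threshold: float = 0.5       # a.u., used when threshold_method == "fixed"
    smoothing_sigma: float = 2.6       # µm, nuclei channel
    min_object_area: float = 2000.0    # µm², tumor candidates below this are dropped
    fill_holes: bool = True
    vessel_smoothing_sigma: float = 0.0  # µm
    vessel_min_area: float = 20.0      # µm²
    restrict_vessels_to_tumor: bool = True

    def validate(self) -> None:
        if self.smoothing_sigma < 0 or self.vessel_smoothing_sigma < 0:
            raise SegmentationError("smoothing sigmas must be >= 0")
        if self.min_object_area < 0 or self.vessel_min_area < 0:
            raise SegmentationError("minimum areas must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise SegmentationError("threshold_method must be 'otsu' or 'fixed'")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _threshold(img: np.ndarray, params: SegmentationParams,
               within: np.ndarray | None = None) -> float:
    values = img if within is None else img[within]
    if params.threshold_method == "fixed":
        return params.fixed_threshold
    return float(filters.threshold_otsu(values))


def _largest_component(labels: np.ndarray, n: int) -> np.ndarray:
    """Largest label by area; ties broken by lowest (row, col) of first pixel."""
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = np.max(areas)
    candidates = [i + 1 for i, a in enumerate(areas) if a == best]
    if len(candidates) > 1:
        firsts = {lab: tuple(np.argwhere(labels == lab)[0]) for lab in candidates}
        candidates.sort(key=lambda lab: firsts[lab])
    return labels == candidates[0]


def extract_contour(mask: np.ndarray) -> BoundaryContour:
    """Sub-pixel 0.5-level boundary of a binary mask (longest closed contour)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no boundary contour")
    longest = max(contours, key=len)
    if not np.allclose(longest[0], longest[-1]):
        longest = np.vstack([longest, longest[:1]])
    return BoundaryContour(coords=longest)


def segment_tumor(section: SectionImage,
                  params: SegmentationParams | None = None
                  ) -> tuple[Mask, BoundaryContour]:
    """Tumor mask + boundary contour from the nuclei channel.

    Raises :class:`SegmentationError` if the channel is constant or no
    component survives filtering.
    """
    params = params or SegmentationParams()
    params.validate()
    img = section.nuclei
    if np.ptp(img) == 0:
        raise SegmentationError("nuclei channel is constant; cannot segment tumor")
    sigma_px = params.smoothing_sigma / section.pixel_size
    smooth = ndi.gaussian_filter(img, sigma_px) if sigma_px > 0 else img
    mask = smooth > _threshold(smooth, params)
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    min_px = params.min_object_area / section.pixel_size ** 2
    labels, n = ndi.label(mask)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        keep = np.flatnonzero(areas >= min_px) + 1
        mask = np.isin(labels, keep)
        labels, n = ndi.label(mask)
    if n == 0:
        raise SegmentationError("no tumor foreground after filtering")
    mask = _largest_component(labels, n)
    return Mask(pixels=mask, kind="tumor"), extract_contour(mask)


def segment_vessels(section: SectionImage, tumor: Mask,
                    params: SegmentationParams | None = None) -> Mask:
    """Functional-vessel mask from the lectin channel.

    An all-background result is not fatal: an :class:`EmptyVesselMaskWarning`
    is emitted and an empty mask returned (vessel profiling is then
    unavailable).
    """
    params = params or SegmentationParams()
    params.validate()
    img = section.vessel
    sigma_px = params.vessel_smoothing_sigma / section.pixel_size
    smooth = ndi.gaussian_filter(img, sigma_px) if sigma_px > 0 else img
    region = tumor.pixels if params.restrict_vessels_to_tumor else None
    values = smooth if region is None else smooth[region]
    if values.size == 0 or np.ptp(values) == 0:
        warnings.warn("vessel channel constant; empty vessel mask",
                      EmptyVesselMaskWarning, stacklevel=2)
        return Mask(pixels=np.zeros(section.shape, dtype=bool), kind="vessel")
    mask = smooth > _threshold(smooth, params, within=region)
    min_px = params.vessel_min_area / section.pixel_size ** 2
    labels, n = ndi.label(mask)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        keep = np.flatnonzero(areas >= min_px) + 1
        mask = np.isin(labels, keep)
    if params.restrict_vessels_to_tumor:
        mask &= tumor.pixels
    if not mask.any():
        warnings.warn("no vessel component survived filtering",
                      EmptyVesselMaskWarning, stacklevel=2)
    return Mask(pixels=mask, kind="vessel")
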