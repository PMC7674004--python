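"""Macrovasculature and optic-nerve-head hollow-area segmentation.

Two structures are masked out of every region of interest before computing
microvascular features:

* **Macrovasculature** — large vessels, segmented on the superficial layer
  (highest contrast) by thresholding at the upper 88th intensity percentile,
  denoising with a morphological opening then closing, and discarding
  8-connected components smaller than 250 px (at the reference 245x245 grid;
  the area cutoff scales with image area at other resolutions).
* **ONH optically hollow area** — the dark disc centre, segmented on the
  choroid (best hollow/vascular contrast) by keeping the lower 40th
  percentile of the histogram-equalized image and fitting a circle of equal
  area to the largest 8-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, morphology
from skimage.measure import label, regionprops

from .core import DetectionError

REFERENCE_GRID_AREA_PX = 245 * 245


@dataclass(frozen=True)
class OnhCircle:
    """Circle fitted to the optically hollow disc region.

    ``radius = sqrt(area / pi)`` of the source component, so the circle has
    the component's area regardless of its exact shape.
    """

    center: tuple[float, float]  # (row, col)
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def contains(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers lie inside the circle."""
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


def macrovessel_mask(
    superficial: np.ndarray,
    percentile: float = 88.0,
    min_area_px: int = 250,
    footprint: np.ndarray | None = None,
) -> np.ndarray:
    """Segment large vessels on the superficial en-face image.

    Pixels at or above the ``percentile``-th intensity percentile are
    candidates.  Tie rule: when the percentile value saturates at the image
    minimum or maximum the comparison becomes strict (``>``), so a constant
    image gives an empty mask, a dark-majority image still captures its
    bright blobs, and a bright-majority image does not turn all-true.
    An opening followed by a closing (3x3 square, one iteration each)
    removes speckle, then 8-connected components with area below the
    resolution-scaled ``min_area_px`` are dropped.
    """
    img = np.asarray(superficial, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    thr = np.percentile(img, percentile)
    if thr <= img.min() or thr >= img.max():
        mask = img > thr
    else:
        mask = img >= thr
    if not mask.any():
        return mask
    if footprint is None:
        footprint = np.ones((3, 3), dtype=bool)
    mask = morphology.opening(mask, footprint)
    mask = morphology.closing(mask, footprint)
    # 250 px is calibrated to a 245x245 grid; scale with image area.
    effective_min = int(np.ceil(min_area_px * img.size / REFERENCE_GRID_AREA_PX))
    if effective_min > 1:
        lab = label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        keep = counts >= effective_min
        keep[0] = False
        mask = keep[lab]
    return mask


def onh_hollow_circle(choroid: np.ndarray, percentile: float = 40.0) -> OnhCircle:
    """Fit the optically hollow disc circle on the choroid en-face image.

    The image is globally histogram-equalized; pixels at or below the
    ``percentile``-th percentile of the equalized image are kept (strictly
    below when the percentile value saturates at the maximum, so a
    two-level image with a dark minority still isolates the dark region).
    The largest 8-connected component gives the circle: centroid center,
    radius ``sqrt(area / pi)``.
    """
    img = np.asarray(choroid, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    eq = exposure.equalize_hist(img)
    thr = np.percentile(eq, percentile)
    mask = eq <= thr
    if mask.all():
        mask = eq < thr
    lab = label(mask, connectivity=2)
    props = regionprops(lab)
    if not props:
        raise DetectionError("no dark component found for the ONH hollow area")
    largest = max(props, key=lambda p: p.area)
    return OnhCircle(center=largest.centroid, radius=float(np.sqrt(largest.area / np.pi)))
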