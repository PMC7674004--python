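"""Fovea-disc axis estimation and mask rotation.

Eyes are imaged with variable head tilt, so sector analysis first rotates
everything to a common anatomical reference in which the fovea-disc axis is
horizontal ("zero degrees").  The device's annotated fundus overview
("Panomap") carries two coloured delineation circles, one around the optic
disc and one around the fovea; the axis angle alpha is the angle subtended
by their centroids.

Conventions (documented, since the device specification is not public):

* Image coordinates are (row, col) with row increasing downward.
* ``alpha`` is positive when the fovea lies *below* the disc row.
* Reference frame: fovea temporal to the disc at alpha = 0.  For a right
  eye (OD) temporal is the +col direction; a left eye (OS) is mirrored
  horizontally before rotation so that homologous sectors align.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops
from skimage.transform import rotate as _sk_rotate

from .core import DetectionError

#: Default annotation palette (RGB).  The disc circle is drawn in red and
#: the fovea circle in blue; both are configurable because device palettes
#: differ.
DEFAULT_DISC_COLOR: tuple[int, int, int] = (255, 0, 0)
DEFAULT_FOVEA_COLOR: tuple[int, int, int] = (0, 0, 255)


@dataclass(frozen=True)
class PanomapAnnotation:
    """Disc and fovea circle centroids extracted from a Panomap image."""

    disc_centroid: tuple[float, float]
    fovea_centroid: tuple[float, float]
    laterality: str
    source_image: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        if np.allclose(self.disc_centroid, self.fovea_centroid):
            raise ValueError("disc and fovea centroids must be distinct")


@dataclass(frozen=True)
class FoveaDiscAngle:
    """The fovea-disc axis angle alpha, in degrees, in (-180, 180]."""

    alpha_deg: float
    laterality: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha_deg):
            raise ValueError("alpha must be finite")
        if not (-180.0 < self.alpha_deg <= 180.0):
            raise ValueError("alpha must lie in (-180, 180]")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")


def _color_component_centroid(image: np.ndarray, color: tuple[int, int, int]) -> list[tuple[float, float]]:
    """Centroids of connected components matching ``color``, largest first."""
    mask = np.all(image[..., :3] == np.asarray(color, dtype=image.dtype), axis=-1)
    lab = label(mask, connectivity=2)
    props = sorted(regionprops(lab), key=lambda p: p.area, reverse=True)
    return [p.centroid for p in props]


def detect_circle_centroids(
    panomap_image: np.ndarray,
    laterality: str,
    disc_color: tuple[int, int, int] = DEFAULT_DISC_COLOR,
    fovea_color: tuple[int, int, int] = DEFAULT_FOVEA_COLOR,
) -> PanomapAnnotation:
    """Locate the disc and fovea delineation circles in an annotated image.

    Roles are assigned by annotation colour, never by position.  If a colour
    matches more than one component the largest is used (with a warning);
    a colour with no component raises :class:`DetectionError`.
    """
    if panomap_image.ndim != 3 or panomap_image.shape[-1] < 3:
        raise DetectionError("expected an RGB annotation image")
    centroids: dict[str, tuple[float, float]] = {}
    for name, color in (("disc", disc_color), ("fovea", fovea_color)):
        found = _color_component_centroid(panomap_image, color)
        if not found:
            raise DetectionError(f"no {name} annotation circle found (color {color})")
        if len(found) > 1:
            warnings.warn(
                f"{len(found)} candidate {name} components; keeping the largest",
                stacklevel=2,
            )
        centroids[name] = found[0]
    return PanomapAnnotation(
        disc_centroid=centroids["disc"],
        fovea_centroid=centroids["fovea"],
        laterality=laterality,
        source_image=panomap_image,
    )


def estimate_fovea_disc_angle(ann: PanomapAnnotation) -> FoveaDiscAngle:
    """Angle subtended by the fovea and disc centroids.

    For OD, ``alpha = atan2(row_f - row_d, col_f - col_d)``; for OS the
    column difference is negated (temporal points toward -col), so a
    mirrored pair of eyes yields the same alpha.
    """
    dr = ann.fovea_centroid[0] - ann.disc_centroid[0]
    dc = ann.fovea_centroid[1] - ann.disc_centroid[1]
    if dr == 0 and dc == 0:
        raise ValueError("coincident centroids: fovea-disc angle undefined")
    if ann.laterality == "OS":
        dc = -dc
    alpha = math.degrees(math.atan2(dr, dc))
    if alpha <= -180.0:
        alpha += 360.0
    return FoveaDiscAngle(alpha_deg=alpha, laterality=ann.laterality)


def rotate_mask(
    mask: np.ndarray,
    angle: FoveaDiscAngle,
    center: tuple[float, float],
) -> np.ndarray:
    """Rotate a binary mask by ``-alpha`` about ``center`` (OS mirrored first).

    Nearest-neighbour resampling keeps the mask binary; pixels rotated out
    of the frame are dropped.  The output has the same shape as the input.
    """
    grid = np.asarray(mask, dtype=bool)
    if not (0 <= center[0] < grid.shape[0] and 0 <= center[1] < grid.shape[1]):
        raise ValueError("rotation center must lie inside the mask grid")
    if angle.laterality == "OS":
        grid = np.fliplr(grid)
        center = (center[0], grid.shape[1] - 1 - center[1])
    if angle.alpha_deg == 0.0:
        return grid.copy()
    # skimage's center is (col, row); positive angle is counter-clockwise
    # with the row axis pointing down, i.e. clockwise anatomically.
    out = _sk_rotate(
        grid.astype(float),
        angle=-angle.alpha_deg,
        center=(center[1], center[0]),
        order=0,
        preserve_range=True,
    )
    return out > 0.5
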