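"""Garway-Heath peripapillary sectors and the VIM feature.

The peripapillary annulus — from the rim of the optic-nerve-head hollow
circle out to the nearest image border, the largest radius usable for all
sectors — is partitioned into the six Garway-Heath wedges plus their union,
the circumpapillary (CP) sector.  Within each (layer, sector) ROI the
feature is the **microvascular intensity median (VIM)**: the median pixel
intensity after excluding macrovessels and the hollow disc circle.  The
median, unlike the mean, is robust to residual bright-vessel outliers and
needs no normality assumption.

Sector geometry is computed analytically in polar coordinates (pixel-center
inclusion, arcs half-open at their start), so the six wedges partition the
annulus exactly and rotation by the fovea-disc angle costs no resampling.
The anatomical angle ``theta`` is measured from the disc-to-fovea (temporal)
direction, increasing toward superior; left eyes (OS) are mirrored so that
homologous sectors coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import FoveaDiscAngle, PanomapAnnotation, estimate_fovea_disc_angle
from .core import (
    LAYERS,
    SECTORS,
    WEDGE_SECTORS,
    EnFaceLayerStack,
    FeatureUndefinedError,
)
from .segmentation import OnhCircle, macrovessel_mask, onh_hollow_circle

#: Standard Garway-Heath arc layout (degrees of anatomical angle theta,
#: half-open [start, end) with wrap-around): temporal 90 deg centered on the
#: fovea direction, the four oblique sectors 40 deg each, nasal 110 deg.
DEFAULT_ARCS: dict[str, tuple[float, float]] = {
    "T": (315.0, 45.0),
    "ST": (45.0, 85.0),
    "SN": (85.0, 125.0),
    "N": (125.0, 235.0),
    "IN": (235.0, 275.0),
    "IT": (275.0, 315.0),
}


@dataclass(frozen=True)
class SectorSpec:
    """Angular extents of the six wedges and the annulus radii.

    ``outer_radius=None`` means "largest possible": the minimum distance
    from the disc center to any image border.
    """

    arcs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ARCS)
    )
    inner_radius: float | None = None  # defaults to the ONH circle radius
    outer_radius: float | None = None

    def __post_init__(self) -> None:
        if set(self.arcs) != set(WEDGE_SECTORS):
            raise ValueError(f"arcs must be keyed by {WEDGE_SECTORS}")
        total = sum((end - start) % 360.0 or 360.0 for start, end in self.arcs.values())
        if not np.isclose(total, 360.0):
            raise ValueError(f"arcs must cover 360 degrees exactly, got {total}")


@dataclass
class RoiMaskSet:
    """The seven sector masks plus the geometry they were built from."""

    masks: dict[str, np.ndarray]
    circle: OnhCircle
    angle: FoveaDiscAngle
    inner_radius: float
    outer_radius: float

    def __getitem__(self, sector: str) -> np.ndarray:
        return self.masks[sector]


@dataclass
class FeatureRecord:
    """One subject's 42 VIM features plus clinical scalars and labels."""

    subject_id: str
    laterality: str
    vim: dict[tuple[str, str], float]
    rnfl_um: float | None = None
    vf_md_db: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        expected = {(layer, sector) for layer in LAYERS for sector in SECTORS}
        if set(self.vim) != expected:
            raise ValueError(
                f"expected exactly {len(expected)} (layer, sector) VIM entries, "
                f"got {len(self.vim)}"
            )

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "subject_id": self.subject_id,
            "label": self.label,
            "laterality": self.laterality,
            "rnfl_um": self.rnfl_um,
            "vf_md_db": self.vf_md_db,
        }
        for layer in LAYERS:
            for sector in SECTORS:
                row[f"{layer}_{sector}"] = self.vim[(layer, sector)]
        return row


def anatomical_angle(
    shape: tuple[int, int], center: tuple[float, float], angle: FoveaDiscAngle
) -> np.ndarray:
    """Per-pixel anatomical angle theta in [0, 360).

    theta = 0 along the disc-to-fovea (temporal) direction, increasing
    toward superior, for either laterality.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    # Up-positive frame: phi = atan2(-(row - r0), col - c0).
    phi = np.degrees(np.arctan2(-(rr - center[0]), cc - center[1]))
    # Direction of the fovea in that frame.
    if angle.laterality == "OD":
        theta = phi - (-angle.alpha_deg)
    else:  # OS: temporal points toward -col; superior is clockwise from it.
        theta = (180.0 + angle.alpha_deg) - phi
    return np.mod(theta, 360.0)


def _arc_membership(theta: np.ndarray, arc: tuple[float, float]) -> np.ndarray:
    start, end = (arc[0] % 360.0, arc[1] % 360.0)
    if start < end:
        return (theta >= start) & (theta < end)
    return (theta >= start) | (theta < end)


def build_roi_masks(
    circle: OnhCircle,
    angle: FoveaDiscAngle,
    image_shape: tuple[int, int],
    spec: SectorSpec | None = None,
) -> RoiMaskSet:
    """Build the seven Garway-Heath ROI masks on the peripapillary annulus.

    The annulus runs from the hollow-circle radius out to the nearest image
    border (constant radius for all sectors, the largest possible).  Raises
    if the disc touches the border (outer <= inner).
    """
    spec = spec or SectorSpec()
    r0, c0 = circle.center
    inner = spec.inner_radius if spec.inner_radius is not None else circle.radius
    if spec.outer_radius is not None:
        outer = spec.outer_radius
    else:
        outer = min(r0, c0, image_shape[0] - 1 - r0, image_shape[1] - 1 - c0)
    if outer <= inner:
        raise ValueError(
            f"annulus degenerate: outer radius {outer:.1f} <= inner {inner:.1f} "
            "(disc touching the image border?)"
        )
    rr, cc = np.ogrid[: image_shape[0], : image_shape[1]]
    dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
    annulus = (dist2 > inner**2) & (dist2 <= outer**2)
    theta = anatomical_angle(image_shape, circle.center, angle)
    masks = {
        sector: annulus & _arc_membership(theta, spec.arcs[sector])
        for sector in WEDGE_SECTORS
    }
    masks["CP"] = annulus
    return RoiMaskSet(
        masks=masks, circle=circle, angle=angle, inner_radius=inner, outer_radius=outer
    )


def compute_vim(
    layer: np.ndarray,
    roi: np.ndarray,
    macro: np.ndarray,
    onh: OnhCircle,
) -> float:
    """Median intensity over ``roi`` minus macrovessels and the ONH circle.

    Raises :class:`FeatureUndefinedError` on an empty effective ROI — a
    silent zero would mimic vascular loss.
    """
    img = np.asarray(layer, dtype=float)
    effective = np.asarray(roi, bool) & ~np.asarray(macro, bool) & ~onh.contains(img.shape)
    if not effective.any():
        raise FeatureUndefinedError("ROI empty after macrovessel/ONH exclusion")
    return float(np.median(img[effective]))


def extract_feature_vector(
    stack: EnFaceLayerStack,
    panomap: PanomapAnnotation,
    spec: SectorSpec | None = None,
    macro_percentile: float = 88.0,
    macro_min_area_px: int = 250,
    onh_percentile: float = 40.0,
) -> FeatureRecord:
    """Full image-processing chain for one subject: 42 VIM features.

    Axis correction (from the Panomap annotation), macrovessel and hollow-
    circle segmentation, ROI construction, then the VIM for every
    (layer, sector) pair.
    """
    angle = estimate_fovea_disc_angle(panomap)
    macro = macrovessel_mask(
        stack["superficial"], percentile=macro_percentile, min_area_px=macro_min_area_px
    )
    onh = onh_hollow_circle(stack["choroid"], percentile=onh_percentile)
    rois = build_roi_masks(onh, angle, stack.shape, spec)
    vim = {
        (layer, sector): compute_vim(stack[layer], rois[sector], macro, onh)
        for layer in LAYERS
        for sector in SECTORS
    }
    return FeatureRecord(
        subject_id=stack.subject_id,
        laterality=stack.laterality,
        vim=vim,
        rnfl_um=stack.meta.get("rnfl_um"),
        vf_md_db=stack.meta.get("vf_md_db"),
        label=stack.meta.get("label"),
    )
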