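"""Synthetic peripapillary OCTA phantoms.

No public OCTA glaucoma cohort exists at the granularity this pipeline
needs, so every downstream stage is exercised on phantoms that reproduce
the *structure* of a 3x3 mm disc-centered angiography scan:

* six co-registered en-face layers on a 245x245 grid, 8-bit intensity range;
* a dark, optically hollow optic-disc region in every layer (strongest
  contrast on the choroid, which anchors the hollow-circle segmentation);
* a bright macrovessel tree on the superficial layer (and, fainter
  projections aside, the retina/deep layers), with branch areas above the
  250-px component-survival threshold;
* sector- and layer-specific microvascular background whose median falls
  with disease severity, the signal the VIM feature measures;
* a rotatable fovea-disc axis and OD/OS laterality.

What the phantom does **not** emulate: OCTA speckle statistics,
decorrelation/projection artifacts, or anatomically realistic vessel
morphology — green tests establish pipeline correctness, not clinical
performance.

A feature-level shortcut, :func:`generate_cohort_feature_table`, draws the
42-column VIM table directly (Gaussian around group means) for
classification and statistics tests where image synthesis would only add
runtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .axis import FoveaDiscAngle, PanomapAnnotation
from .core import (
    LAYERS,
    SECTORS,
    WEDGE_SECTORS,
    ConfigurationError,
    EnFaceLayerStack,
    severity_from_vf_md,
)
from .sectors import SectorSpec, build_roi_masks
from .segmentation import OnhCircle

#: Layer-typical background levels (arbitrary 8-bit units; the source data
#: report no intensity statistics, so these are free parameters chosen to
#: give each layer a plausible relative brightness: vascular plexuses and
#: choroid bright, avascular nearly flat and dark).
DEFAULT_BACKGROUND: dict[str, float] = {
    "superficial": 120.0,
    "deep": 110.0,
    "avascular": 30.0,
    "retina": 115.0,
    "choriocapillaris": 130.0,
    "choroid": 140.0,
}

#: Severity steps used by the cohort generator (healthy = 0 ... severe = 3).
SEVERITY_STEP: dict[str, int] = {
    "control": 0,
    "healthy": 0,
    "mild": 1,
    "moderate": 2,
    "severe": 3,
}

#: Glaucoma severity mix of the reference cohort (mild/moderate/severe).
GLAUCOMA_SEVERITY_MIX: tuple[int, int, int] = (37, 26, 19)


@dataclass(frozen=True)
class MacroTreeConfig:
    """Branching macrovessel tree drawn on the superficial layer."""

    n_branches: int = 7
    width_px: tuple[int, int] = (4, 8)  # min/max stamp diameter
    intensity: float = 230.0
    length_px: tuple[int, int] = (90, 140)

    def __post_init__(self) -> None:
        if self.n_branches < 0:
            raise ConfigurationError("n_branches must be >= 0")
        if not 0 <= self.intensity <= 255:
            raise ConfigurationError("tree intensity must lie in [0, 255]")
        if self.width_px[0] < 1 or self.width_px[1] < self.width_px[0]:
            raise ConfigurationError("invalid width range")


@dataclass(frozen=True)
class PhantomConfig:
    """Stated world of one synthetic eye."""

    image_size_px: tuple[int, int] = (245, 245)
    onh_center_px: tuple[float, float] | None = None  # defaults to image center
    onh_radius_px: float = 30.0
    onh_intensity: float = 25.0
    macro_tree: MacroTreeConfig | None = field(default_factory=MacroTreeConfig)
    background_intensity: float | Mapping = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    noise_sd: float = 6.0
    fovea_disc_angle_deg: float = 0.0
    laterality: str = "OD"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 32 or w < 32:
            raise ConfigurationError("image must be at least 32x32 px")
        if not 0 < self.onh_radius_px < min(h, w) / 2:
            raise ConfigurationError("onh_radius_px must be in (0, min(image_size)/2)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0 <= self.onh_intensity <= 255:
            raise ConfigurationError("onh_intensity must lie in [0, 255]")
        if not -180.0 < self.fovea_disc_angle_deg <= 180.0:
            raise ConfigurationError("fovea_disc_angle_deg must lie in (-180, 180]")
        if self.laterality not in ("OD", "OS"):
            raise ConfigurationError("laterality must be OD or OS")
        for layer in LAYERS:
            for sector in WEDGE_SECTORS:
                v = self.background_value(layer, sector)
                if not 0 <= v <= 255:
                    raise ConfigurationError(
                        f"background intensity {v} for ({layer}, {sector}) "
                        "outside [0, 255]"
                    )

    @property
    def center(self) -> tuple[float, float]:
        if self.onh_center_px is not None:
            return self.onh_center_px
        return ((self.image_size_px[0] - 1) / 2, (self.image_size_px[1] - 1) / 2)

    def background_value(self, layer: str, sector: str) -> float:
        """Resolve the background mean for a (layer, sector) pair.

        ``background_intensity`` may be a scalar, a per-layer mapping, a
        per-(layer, sector) nested mapping, or a flat mapping keyed by
        ``(layer, sector)`` tuples.
        """
        bg = self.background_intensity
        if not isinstance(bg, Mapping):
            return float(bg)
        if (layer, sector) in bg:
            return float(bg[(layer, sector)])
        entry = bg.get(layer, DEFAULT_BACKGROUND[layer])
        if isinstance(entry, Mapping):
            return float(entry.get(sector, DEFAULT_BACKGROUND[layer]))
        return float(entry)


def _stamp_disk(mask: np.ndarray, row: float, col: float, radius: float) -> None:
    r0 = max(int(row - radius) - 1, 0)
    r1 = min(int(row + radius) + 2, mask.shape[0])
    c0 = max(int(col - radius) - 1, 0)
    c1 = min(int(col + radius) + 2, mask.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def _draw_tree(
    shape: tuple[int, int],
    center: tuple[float, float],
    start_radius: float,
    cfg: MacroTreeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Branches radiating from the disc rim as jittered thick polylines."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(cfg.n_branches):
        theta = rng.uniform(0, 2 * math.pi)
        width = rng.integers(cfg.width_px[0], cfg.width_px[1] + 1)
        length = rng.integers(cfg.length_px[0], cfg.length_px[1] + 1)
        row = center[0] - start_radius * math.sin(theta)
        col = center[1] + start_radius * math.cos(theta)
        heading = theta
        for _step in range(int(length)):
            row -= math.sin(heading)
            col += math.cos(heading)
            if not (0 <= row < shape[0] and 0 <= col < shape[1]):
                break
            _stamp_disk(mask, row, col, width / 2)
            heading += rng.normal(0, 0.06)  # gentle meander
    return mask


def generate_layer_stack(cfg: PhantomConfig, subject_id: str = "phantom") -> EnFaceLayerStack:
    """Render the six en-face layers of one phantom eye.

    Deterministic for a fixed config (the seed is part of the config).
    The ground-truth macrovessel mask is stored in ``stack.meta`` for
    oracle-style tests.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.image_size_px
    center = cfg.center
    circle = OnhCircle(center=center, radius=cfg.onh_radius_px)
    angle = FoveaDiscAngle(cfg.fovea_disc_angle_deg, cfg.laterality)
    rois = build_roi_masks(circle, angle, shape)
    disc = circle.contains(shape)

    tree = (
        _draw_tree(shape, center, cfg.onh_radius_px, cfg.macro_tree, rng)
        if cfg.macro_tree is not None and cfg.macro_tree.n_branches > 0
        else np.zeros(shape, dtype=bool)
    )
    tree &= ~disc

    layers: dict[str, np.ndarray] = {}
    for layer in LAYERS:
        base = cfg.background_value(layer, "T")
        img = np.full(shape, base, dtype=float)
        for sector in WEDGE_SECTORS:
            img[rois[sector]] = cfg.background_value(layer, sector)
        img[disc] = cfg.onh_intensity
        if layer in ("superficial", "deep", "retina") and cfg.macro_tree is not None:
            img[tree] = cfg.macro_tree.intensity
        if cfg.noise_sd > 0:
            img += rng.normal(0, cfg.noise_sd, shape)
        layers[layer] = np.clip(img, 0, 255)

    return EnFaceLayerStack(
        layers=layers,
        laterality=cfg.laterality,
        subject_id=subject_id,
        meta={"macro_mask": tree, "config": cfg},
    )


def generate_panomap(
    cfg: PhantomConfig,
    fovea_distance_px: float | None = None,
    render: bool = False,
    circle_radius_px: float = 8.0,
    disc_color: tuple[int, int, int] = (255, 0, 0),
    fovea_color: tuple[int, int, int] = (0, 0, 255),
) -> PanomapAnnotation:
    """Panomap annotation whose centroids subtend exactly the configured angle.

    The fovea sits temporal to the disc (toward +col for OD, -col for OS)
    at ``fovea_distance_px`` (default 0.35 x the smaller image dimension),
    displaced vertically so the axis angle equals
    ``cfg.fovea_disc_angle_deg``.  With ``render=True`` an RGB image with
    filled annotation circles is attached.
    """
    h, w = cfg.image_size_px
    d = fovea_distance_px if fovea_distance_px is not None else 0.35 * min(h, w)
    alpha = math.radians(cfg.fovea_disc_angle_deg)
    r0, c0 = cfg.center
    drow = d * math.sin(alpha)
    dcol = d * math.cos(alpha)
    if cfg.laterality == "OS":
        dcol = -dcol
    fovea = (r0 + drow, c0 + dcol)
    image = None
    if render:
        image = np.zeros((h, w, 3), dtype=np.uint8)
        for (pr, pc), color in (((r0, c0), disc_color), (fovea, fovea_color)):
            rr, cc = np.ogrid[:h, :w]
            sel = (rr - pr) ** 2 + (cc - pc) ** 2 <= circle_radius_px**2
            image[sel] = color
    return PanomapAnnotation(
        disc_centroid=(r0, c0),
        fovea_centroid=fovea,
        laterality=cfg.laterality,
        source_image=image,
    )


def default_effect_map(scale: float = 1.0) -> dict[tuple[str, str], float]:
    """Severity effect per step (a.u.) shaped like glaucomatous loss.

    Largest deficit at the superficial inferotemporal sector, substantial
    loss across superficial/deep/retina, minimal change in the avascular
    and choroidal layers.
    """
    per_layer = {
        "superficial": -6.0,
        "deep": -5.0,
        "avascular": 0.0,
        "retina": -5.5,
        "choriocapillaris": -1.5,
        "choroid": -1.0,
    }
    emphasis = {"IT": 1.6, "ST": 1.3, "IN": 1.2, "CP": 1.1}
    return {
        (layer, sector): scale * per_layer[layer] * emphasis.get(sector, 1.0)
        for layer in LAYERS
        for sector in SECTORS
    }


@dataclass(frozen=True)
class CohortEffectSpec:
    """Stated world of a synthetic cohort feature table.

    ``effect_map`` is the additive shift of each (layer, sector) mean VIM
    per severity step (negative = loss); ``rnfl_effect`` likewise for RNFL
    thickness, clamped below at ``floor_level`` (the RNFL floor effect).
    """

    n_per_group: dict[str, int]
    effect_map: Mapping[tuple[str, str], float] = field(default_factory=default_effect_map)
    rnfl_effect: float = -12.0
    floor_level: float = 50.0
    seed: int = 0
    baseline_vim: float = 100.0
    vim_sd: float = 8.0
    rnfl_baseline: float = 95.0
    rnfl_sd: float = 8.0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ConfigurationError("n_per_group must name at least one group")
        for group, n in self.n_per_group.items():
            if n < 2:
                raise ConfigurationError(f"group {group!r} must have >= 2 subjects")
        if self.vim_sd < 0 or self.rnfl_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        if not 0 <= self.baseline_vim <= 255:
            raise ConfigurationError("baseline_vim must lie in [0, 255]")


def _draw_vf_md(severity: str, rng: np.random.Generator) -> float:
    """Visual-field mean deviation consistent with the severity stratum."""
    if severity == "healthy":
        return float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0))
    if severity == "mild":
        return float(rng.uniform(-5.5, -0.5))
    if severity == "moderate":
        return float(rng.uniform(-11.5, -6.0))
    return float(rng.uniform(-20.0, -12.5))


def generate_cohort_feature_table(spec: CohortEffectSpec) -> pd.DataFrame:
    """Draw a cohort's 42-column VIM feature table directly.

    Groups may be diagnosis labels (``control``/``glaucoma``), glaucoma
    types (``POAG``/``NTG``) or severity strata.  Diagnosis/type groups get
    a severity stratum drawn with the reference cohort's 37/26/19
    mild/moderate/severe mix; each feature is Gaussian around
    ``baseline + step * effect`` and clipped to the 8-bit range.
    """
    rng = np.random.default_rng(spec.seed)
    mix = np.asarray(GLAUCOMA_SEVERITY_MIX, dtype=float)
    mix /= mix.sum()
    rows = []
    idx = 0
    for group, n in spec.n_per_group.items():
        for _ in range(n):
            if group in SEVERITY_STEP:
                severity = group if group != "control" else "healthy"
            else:  # glaucoma / POAG / NTG: heterogeneous severity
                severity = ("mild", "moderate", "severe")[rng.choice(3, p=mix)]
            step = SEVERITY_STEP.get(group, SEVERITY_STEP[severity])
            vf_md = _draw_vf_md(severity, rng)
            rnfl = spec.rnfl_baseline + step * spec.rnfl_effect + rng.normal(0, spec.rnfl_sd)
            rnfl = float(np.clip(max(rnfl, spec.floor_level), 0, None))
            row: dict[str, object] = {
                "subject_id": f"S{idx:04d}",
                "label": group,
                "laterality": "OD" if rng.random() < 0.5 else "OS",
                "rnfl_um": rnfl,
                "vf_md_db": vf_md,
            }
            for layer in LAYERS:
                for sector in SECTORS:
                    mean = spec.baseline_vim + step * float(
                        spec.effect_map.get((layer, sector), 0.0)
                    )
                    value = mean + (rng.normal(0, spec.vim_sd) if spec.vim_sd > 0 else 0.0)
                    row[f"{layer}_{sector}"] = float(np.clip(value, 0, 255))
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)
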