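"""Shared vocabulary for the peripapillary OCTA analysis.

Six device-segmented en-face layers are analysed per eye, each split into
the seven Garway-Heath peripapillary sectors (six wedges plus the
circumpapillary union, CP), giving the canonical 42-dimensional
microvascular-intensity-median (VIM) feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

LAYERS: tuple[str, ...] = (
    "superficial",
    "deep",
    "avascular",
    "retina",
    "choriocapillaris",
    "choroid",
)

#: Six angular sectors plus the circumpapillary union.
SECTORS: tuple[str, ...] = ("ST", "SN", "N", "IN", "IT", "T", "CP")

#: Angular wedges only (CP is their union, not a wedge of its own).
WEDGE_SECTORS: tuple[str, ...] = ("ST", "SN", "N", "IN", "IT", "T")

LATERALITIES: tuple[str, ...] = ("OD", "OS")

#: Severity strata from visual-field mean deviation (dB):
#: mild > -6; -12 <= moderate <= -6; severe < -12.
VF_MD_MILD_CUTOFF_DB: float = -6.0
VF_MD_SEVERE_CUTOFF_DB: float = -12.0

SEVERITY_LEVELS: tuple[str, ...] = ("healthy", "mild", "moderate", "severe")


def feature_columns() -> list[str]:
    """Canonical layer-major, sector-minor ordering of the 42 VIM columns."""
    return [f"{layer}_{sector}" for layer in LAYERS for sector in SECTORS]


def severity_from_vf_md(vf_md_db: float) -> str:
    """Map a visual-field mean deviation (dB) to a glaucoma severity stratum."""
    if vf_md_db > VF_MD_MILD_CUTOFF_DB:
        return "mild"
    if vf_md_db < VF_MD_SEVERE_CUTOFF_DB:
        return "severe"
    return "moderate"


@dataclass
class EnFaceLayerStack:
    """One subject's six co-registered grayscale en-face OCTA projections."""

    layers: Mapping[str, np.ndarray]
    laterality: str
    subject_id: str = "anonymous"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [name for name in LAYERS if name not in self.layers]
        if missing:
            raise ValueError(f"missing layer(s): {', '.join(missing)}")
        shapes = {name: np.asarray(img).shape for name, img in self.layers.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"layer shapes differ: {shapes}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.layers[LAYERS[0]]).shape

    def __getitem__(self, layer: str) -> np.ndarray:
        return np.asarray(self.layers[layer])


class ConfigurationError(ValueError):
    """An invalid phantom or pipeline configuration."""


class DetectionError(RuntimeError):
    """A landmark (annotation circle, dark region, ...) could not be found."""


class FeatureUndefinedError(RuntimeError):
    """An ROI is empty after exclusions; the feature is undefined, never zero."""
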