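"""Format plumbing and end-to-end pipeline orchestration.

Interchange formats are deliberately plain: layer stacks as six 8-bit PNGs
with a JSON sidecar manifest, feature tables as CSV, reports as JSON.
Every output records the configuration hash and master seed so a run can
be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import LAYERS, EnFaceLayerStack
from .harness import (
    HyperparameterGrid,
    run_nested_evaluation,
    score_binary,
    score_multiclass,
)
from .phantom import (
    SEVERITY_STEP,
    CohortEffectSpec,
    MacroTreeConfig,
    PhantomConfig,
    default_effect_map,
    generate_cohort_feature_table,
    generate_layer_stack,
    generate_panomap,
)
from .sectors import extract_feature_vector

log = logging.getLogger("octamls")

FEATURE_TABLE_ID_COLUMNS = ["subject_id", "label", "laterality", "rnfl_um", "vf_md_db"]


class PipelineConfig(BaseModel):
    """Everything a pipeline run depends on; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "out"
    # cohort
    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {"healthy": 10, "mild": 4, "moderate": 3, "severe": 3}
    )
    effect_scale: float = 1.0
    noise_sd: float = 6.0
    image_size_px: tuple[int, int] = (245, 245)
    onh_radius_px: float = 30.0
    max_axis_tilt_deg: float = 12.0
    # segmentation tunables
    macro_percentile: float = 88.0
    macro_min_area_px: int = 250
    onh_percentile: float = 40.0
    # evaluation
    task: str = "diagnosis"
    model: str = "svm"
    feature_set: str = "all"
    tiny_grid: bool = True
    n_boot: int = 1000
    qc_subjects: int = 3

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


def write_layer_stack(stack: EnFaceLayerStack, out_dir: str | Path) -> Path:
    """Write six PNGs plus a ``manifest.json``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for layer in LAYERS:
        fname = f"{stack.subject_id}_{layer}.png"
        img = np.clip(np.asarray(stack[layer]), 0, 255).round().astype(np.uint8)
        iio.imwrite(out / fname, img)
        files[layer] = fname
    manifest = {
        "subject_id": stack.subject_id,
        "laterality": stack.laterality,
        "layers": files,
        "meta": {
            k: v
            for k, v in stack.meta.items()
            if isinstance(v, (str, int, float, bool, type(None)))
        },
    }
    manifest_path = out / f"{stack.subject_id}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_layer_stack(manifest_path: str | Path) -> EnFaceLayerStack:
    """Load a stack from its manifest; errors name the offending layer."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    layers: dict[str, np.ndarray] = {}
    shapes: dict[str, tuple] = {}
    for layer in LAYERS:
        if layer not in manifest.get("layers", {}):
            raise ValueError(f"manifest missing layer {layer!r}")
        path = manifest_path.parent / manifest["layers"][layer]
        if not path.exists():
            raise FileNotFoundError(f"layer {layer!r}: image file {path} not found")
        img = np.asarray(iio.imread(path), dtype=float)
        layers[layer] = img
        shapes[layer] = img.shape
    if len(set(shapes.values())) != 1:
        raise ValueError(f"layer shape mismatch: {shapes}")
    return EnFaceLayerStack(
        layers=layers,
        laterality=manifest["laterality"],
        subject_id=manifest.get("subject_id", manifest_path.stem),
        meta=manifest.get("meta", {}),
    )


def write_feature_table(records, path: str | Path) -> pd.DataFrame:
    table = pd.DataFrame([r.as_row() for r in records])
    table.to_csv(path, index=False)
    return table


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _phantom_for_subject(
    label: str, cfg: PipelineConfig, rng: np.random.Generator
) -> PhantomConfig:
    """Phantom whose sector backgrounds carry the label's severity deficit."""
    step = SEVERITY_STEP.get(label, 1)
    effects = default_effect_map(scale=cfg.effect_scale)
    from .phantom import DEFAULT_BACKGROUND  # layer base levels

    background = {
        layer: {
            sector: float(
                np.clip(DEFAULT_BACKGROUND[layer] + step * effects[(layer, sector)], 0, 255)
            )
            for sector in ("ST", "SN", "N", "IN", "IT", "T", "CP")
        }
        for layer in LAYERS
    }
    return PhantomConfig(
        image_size_px=tuple(cfg.image_size_px),
        onh_radius_px=cfg.onh_radius_px,
        background_intensity=background,
        noise_sd=cfg.noise_sd,
        fovea_disc_angle_deg=float(rng.uniform(-cfg.max_axis_tilt_deg, cfg.max_axis_tilt_deg)),
        laterality="OD" if rng.random() < 0.5 else "OS",
        seed=int(rng.integers(0, 2**31 - 1)),
        macro_tree=MacroTreeConfig(),
    )


def qc_overlay(stack: EnFaceLayerStack, rois, macro, out_path: str | Path) -> None:
    """Save a QC figure: sector masks and macrovessels over the superficial layer."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(stack["superficial"], cmap="gray", vmin=0, vmax=255)
    overlay = np.zeros((*stack.shape, 4))
    overlay[macro] = (0, 1, 0, 0.5)
    for sector in ("ST", "SN", "N", "IN", "IT", "T"):
        edge = rois[sector] & ~_erode(rois[sector])
        overlay[edge] = (1, 0, 0, 0.9)
    ax.imshow(overlay)
    ax.set_title(f"{stack.subject_id} ({stack.laterality})")
    ax.axis("off")
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def _erode(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_erosion(mask)


def run_pipeline(config: PipelineConfig) -> dict:
    """Synthesize an image cohort, extract features, evaluate, and report.

    Deterministic for a fixed config (the master seed is part of it).
    Returns a dict of output paths; raises on any stage failure with the
    stage and subject named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chash = config.config_hash()
    log.info("pipeline start: hash=%s seed=%d", chash, config.seed)

    from .axis import estimate_fovea_disc_angle
    from .sectors import build_roi_masks
    from .segmentation import macrovessel_mask, onh_hollow_circle

    records = []
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    subj_idx = 0
    for label, n in config.n_per_group.items():
        for _ in range(n):
            subject_id = f"S{subj_idx:04d}"
            try:
                pcfg = _phantom_for_subject(label, config, rng)
                stack = generate_layer_stack(pcfg, subject_id=subject_id)
                stack.meta["label"] = label
                panomap = generate_panomap(pcfg)
                record = extract_feature_vector(
                    stack,
                    panomap,
                    macro_percentile=config.macro_percentile,
                    macro_min_area_px=config.macro_min_area_px,
                    onh_percentile=config.onh_percentile,
                )
                record.label = label
            except Exception:
                log.exception("subject %s failed at feature extraction", subject_id)
                raise
            records.append(record)
            if subj_idx < config.qc_subjects:
                angle = estimate_fovea_disc_angle(panomap)
                macro = macrovessel_mask(stack["superficial"], config.macro_percentile,
                                         config.macro_min_area_px)
                onh = onh_hollow_circle(stack["choroid"], config.onh_percentile)
                rois = build_roi_masks(onh, angle, stack.shape)
                qc_overlay(stack, rois, macro, qc_dir / f"{subject_id}_qc.png")
            subj_idx += 1

    features_path = out / "features.csv"
    table = write_feature_table(records, features_path)
    table["config_hash"] = chash  # recorded, then dropped for modeling
    table.to_csv(features_path, index=False)
    table = table.drop(columns=["config_hash"])

    grid = HyperparameterGrid.tiny() if config.tiny_grid else HyperparameterGrid()
    result = run_nested_evaluation(
        table,
        task=config.task,
        model=config.model,
        grid=grid,
        feature_set=config.feature_set,
        seed=config.seed,
    )
    scorer = score_multiclass if config.task == "severity" else score_binary
    report = scorer(result, n_boot=config.n_boot, seed=config.seed)
    metrics = {
        "config_hash": chash,
        "seed": config.seed,
        "task": report.task,
        "model": report.model,
        "metrics": {
            name: {"point": p, "ci_low": lo, "ci_high": hi}
            for name, (p, lo, hi) in report.metrics.items()
        },
        "note": report.note,
    }
    if report.confusion_matrix is not None:
        metrics["confusion_matrix"] = report.confusion_matrix.tolist()
        metrics["classes"] = report.classes
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2))
    log.info("pipeline done: %d subjects, metrics at %s", len(records), metrics_path)
    return {"features": features_path, "metrics": metrics_path, "qc_dir": qc_dir}


def synth_cohort_csv(spec: CohortEffectSpec, path: str | Path) -> pd.DataFrame:
    """Feature-level synthetic cohort straight to CSV."""
    table = generate_cohort_feature_table(spec)
    table.to_csv(path, index=False)
    return table
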