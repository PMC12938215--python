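"""File formats, run configuration, and seed fan-out.

Formats are deliberately plain: 8-bit grayscale PNGs for images, 0/255
PNGs for masks, CSV manifests and annotation tables, JSON for activation
regions and reports. Readers validate schemas strictly and point at the
offending line; writers round-trip exactly through the readers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from usgrad_audit.annotation import AnnotationLabel, AnnotationRecord, ConsensusResult
from usgrad_audit.gradcam import GRID_SIZE, ActivationGrid, ActivationRegion
from usgrad_audit.phantom import MASK_CATEGORIES, PhantomConfig, PhantomFrame, SectorGeometry, SpeckleConfig

logger = logging.getLogger("usgrad_audit")

MANIFEST_COLUMNS = ["image", "mask_lymph_node", "mask_vessel", "mask_artifact",
                    "mask_other", "station", "patient_id", "quality"]
ANNOTATION_COLUMNS = ["image_id", "rater_id", "label"]
CONSENSUS_COLUMNS = ["image_id", "final_label", "agreement_level"]

_MASK_COLUMN = {"lymph_node": "mask_lymph_node", "vessel": "mask_vessel",
                "artifact": "mask_artifact", "other_structure": "mask_other"}


class SchemaError(ValueError):
    """A file failed validation; the message names the line/column."""


# ---------------------------------------------------------------------------
# dataset on disk

def save_dataset(frames: Sequence[PhantomFrame], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write images, masks and manifest.csv under `out_dir`."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for frame, (_, row) in zip(frames, manifest.iterrows()):
        iio.imwrite(out / row["image"],
                    np.round(np.clip(frame.image, 0, 1) * 255).astype(np.uint8))
        for cat in MASK_CATEGORIES:
            iio.imwrite(out / row[_MASK_COLUMN[cat]],
                        (frame.masks[cat].astype(np.uint8) * 255))
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest is missing column(s) {missing}")
    bad = df[(df["quality"] < 0) | (df["quality"] > 1)]
    if len(bad):
        raise SchemaError(f"{path}: quality outside [0,1] at line {bad.index[0] + 2}")
    return df[MANIFEST_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_frames(manifest: pd.DataFrame, root: str | Path) -> list[PhantomFrame]:
    """Reconstruct PhantomFrames from a saved dataset directory."""
    root = Path(root)
    frames = []
    for _, row in manifest.iterrows():
        image = iio.imread(root / row["image"]).astype(np.float64) / 255.0
        masks = {cat: iio.imread(root / row[_MASK_COLUMN[cat]]) > 127
                 for cat in MASK_CATEGORIES}
        frame = PhantomFrame(image=image, masks=masks, station=row["station"],
                             patient_id=row["patient_id"], quality=float(row["quality"]))
        frame.frame_id = Path(row["image"]).stem
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# annotations

def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"image_id": r.image_id, "rater_id": r.rater_id, "label": r.label.value}
         for r in records]
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: annotation table is missing column(s) {missing}")
    valid = {lab.value for lab in AnnotationLabel}
    records = []
    for i, row in df.iterrows():
        if row["label"] not in valid:
            raise SchemaError(
                f"{path}: line {i + 2}: label {row['label']!r} not one of {sorted(valid)}"
            )
        records.append(AnnotationRecord(str(row["image_id"]), str(row["rater_id"]),
                                        AnnotationLabel(row["label"])))
    return records


def annotations_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"image_id": r.image_id, "rater_id": r.rater_id, "label": r.label.value}
         for r in records]
    )


def write_consensus(results: Sequence[ConsensusResult], path: str | Path) -> None:
    pd.DataFrame(
        [{"image_id": r.image_id,
          "final_label": "" if r.final_label is None else r.final_label.value,
          "agreement_level": r.agreement_level}
         for r in results]
    ).to_csv(path, index=False)


def read_consensus(path: str | Path) -> list[ConsensusResult]:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in CONSENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: consensus table is missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        label = None if row["final_label"] == "" else AnnotationLabel(row["final_label"])
        if row["agreement_level"] not in ("complete", "majority", "disagreement"):
            raise SchemaError(f"{path}: line {i + 2}: bad agreement level "
                              f"{row['agreement_level']!r}")
        out.append(ConsensusResult(str(row["image_id"]), label, row["agreement_level"]))
    return out


def read_adjudication(path: str | Path) -> dict[str, AnnotationLabel]:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("image_id", "final_label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: adjudication table is missing column {col!r}")
    return {str(r["image_id"]): AnnotationLabel(r["final_label"]) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# activation regions

def write_regions(entries: Sequence[dict], path: str | Path) -> None:
    """Each entry: {image_id, station, grid: ActivationGrid, region: ActivationRegion}."""
    payload = []
    for e in entries:
        grid: ActivationGrid = e["grid"]
        region: ActivationRegion = e["region"]
        payload.append({
            "image_id": e["image_id"],
            "station": e.get("station"),
            "target_class": grid.target_class,
            "grid": [round(float(v), 6) for v in grid.values.ravel()],
            "region_cells": sorted([list(c) for c in region.cells]),
            "max_cell": list(region.max_cell) if region.max_cell else None,
            "threshold": region.threshold,
            "degenerate": grid.degenerate,
        })
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_regions(path: str | Path) -> list[dict]:
    path = Path(path)
    payload = json.loads(path.read_text())
    out = []
    for i, e in enumerate(payload):
        grid_vals = e.get("grid")
        if grid_vals is None or len(grid_vals) != GRID_SIZE * GRID_SIZE:
            raise SchemaError(f"{path}: entry {i}: grid must hold {GRID_SIZE**2} values")
        grid = ActivationGrid(np.array(grid_vals).reshape(GRID_SIZE, GRID_SIZE),
                              degenerate=bool(e["degenerate"]),
                              target_class=int(e["target_class"]))
        region = ActivationRegion(
            cells=frozenset(tuple(c) for c in e["region_cells"]),
            max_cell=tuple(e["max_cell"]) if e["max_cell"] else None,
            threshold=float(e.get("threshold", 0.9)),
        )
        out.append({"image_id": e["image_id"], "station": e.get("station"),
                    "grid": grid, "region": region})
    return out


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class GradCamSection:
    threshold: float = 0.9
    use_true_class: bool = False


@dataclass(frozen=True)
class AnnotationSection:
    n_raters: int = 3
    flip_probability: float = 0.15
    min_cell_fraction: float = 0.25
    quality_floor: float = 0.30


@dataclass(frozen=True)
class TrainSection:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-2
    weight_decay: float = 1e-4
    patience: int = 20
    dropout_rate: float = 0.5
    backbone: str = "small"
    augment: bool = True


@dataclass(frozen=True)
class EvaluationSection:
    stratified_averaging: str = "macro"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; the global seed fans out to per-stage seeds."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    train: TrainSection = field(default_factory=TrainSection)
    gradcam: GradCamSection = field(default_factory=GradCamSection)
    annotation: AnnotationSection = field(default_factory=AnnotationSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    seed: int = 0
    out_dir: str = "runs/audit"


def _build_dataclass(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise SchemaError(f"config section {context!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} in config section {context!r}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        default = (f.default_factory() if f.default_factory is not dataclasses.MISSING
                   else f.default)
        if dataclasses.is_dataclass(default) and isinstance(value, dict):
            kwargs[name] = _build_dataclass(type(default), value, f"{context}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build_dataclass(RunConfig, data, "root")


def derive_seeds(global_seed: int, names: Sequence[str]) -> dict[str, int]:
    """Deterministically fan a global seed out to named per-stage seeds.

    Every stage gets an independent stream (< 2**31) so any stage can be
    re-run in isolation; the mapping is logged.
    """
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(names))
    seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
             for name, child in zip(names, children)}
    for name, s in seeds.items():
        logger.info("seed[%s] = %d", name, s)
    return seeds
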