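"""End-to-end audit pipeline: generate -> split -> train -> explain ->
annotate -> consensus -> agree -> evaluate.

Every stage draws its randomness from a seed fanned out deterministically
from the run's global seed, so the whole report is reproducible from
(config, seed) and any stage can be re-run in isolation. Stage failures
abort with the stage name; artifacts written before the failure stay on
disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from usgrad_audit import io as uio
from usgrad_audit.activation_analysis import frequency_table, max_cell_frequency
from usgrad_audit.agreement import compute_agreement_report
from usgrad_audit.annotation import (
    AnnotationRecord, OverlapRules, RaterModel, adjudicate, agreement_distribution,
    consensus, oracle_label, simulate_rater,
)
from usgrad_audit.classifier import AugmentConfig, TrainConfig, split_patientwise, train_model
from usgrad_audit.evaluation import aggregate, confusion, per_class, round1, stratify
from usgrad_audit.gradcam import compute_cam, extract_region
from usgrad_audit.io import RunConfig
from usgrad_audit.phantom import STATIONS, generate_dataset

logger = logging.getLogger("usgrad_audit")

REPORT_SECTIONS = ("dataset", "training", "classification", "activation_maps",
                   "annotation", "agreement", "stratified")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full audit on a synthetic dataset; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = uio.derive_seeds(config.seed, ["phantom", "split", "train", "raters"])
    stage = "setup"
    try:
        # -- generate ------------------------------------------------------
        stage = "generate"
        phantom_cfg = replace(config.phantom, seed=seeds["phantom"])
        frames, manifest = generate_dataset(phantom_cfg)
        manifest.to_csv(out / "manifest.csv", index=False)
        by_id = {Path(row["image"]).stem: frame
                 for frame, (_, row) in zip(frames, manifest.iterrows())}
        images = {row["image"]: f.image
                  for f, (_, row) in zip(frames, manifest.iterrows())}
        labels = dict(zip(manifest["image"], manifest["station"]))

        # -- split ---------------------------------------------------------
        stage = "split"
        split = split_patientwise(manifest, fractions=(0.70, 0.20, 0.10),
                                  seed=seeds["split"])
        _dump_json({"patient_assignment": split.patient_assignment,
                    "n_train": len(split.train), "n_val": len(split.val),
                    "n_test": len(split.test)}, out / "split.json")

        # -- train ---------------------------------------------------------
        stage = "train"
        ts = config.train
        train_cfg = TrainConfig(epochs=ts.epochs, batch_size=ts.batch_size,
                                learning_rate=ts.learning_rate,
                                weight_decay=ts.weight_decay,
                                patience=min(ts.patience, ts.epochs),
                                dropout_rate=ts.dropout_rate,
                                input_size=config.phantom.image_size,
                                seed=seeds["train"])
        augment = AugmentConfig() if ts.augment else None
        model, history = train_model(split, train_cfg, ts.backbone,
                                     images=images, labels=labels, augment=augment)
        history.to_csv(out / "history.csv", index=False)

        # -- explain (Grad-CAM on the test set) ----------------------------
        stage = "explain"
        class_index = {c: i for i, c in enumerate(model.class_order)}
        test_ids = list(split.test)
        predictions, region_entries = [], []
        for image_id in test_ids:
            frame = by_id[Path(image_id).stem]
            probs = model.predict_proba(frame.image)
            predicted = model.class_order[int(np.argmax(probs))]
            target = class_index[frame.station] if config.gradcam.use_true_class else None
            grid = compute_cam(model, frame.image, target_class=target)
            region = extract_region(grid, threshold=config.gradcam.threshold)
            predictions.append({"image_id": image_id, "true_station": frame.station,
                                "predicted_station": predicted})
            region_entries.append({"image_id": image_id, "station": frame.station,
                                   "grid": grid, "region": region})
        pred_df = pd.DataFrame(predictions)
        pred_df.to_csv(out / "predictions.csv", index=False)
        uio.write_regions(region_entries, out / "regions.json")

        # -- activation-pattern analysis -----------------------------------
        stage = "activation_analysis"
        maps = max_cell_frequency(
            (e["station"], e["region"]) for e in region_entries
        )
        frequency_table(maps).to_csv(out / "frequency_maps.csv", index=False)

        # -- annotate ------------------------------------------------------
        stage = "annotate"
        rules = OverlapRules(min_cell_fraction=config.annotation.min_cell_fraction,
                             quality_floor=config.annotation.quality_floor)
        truth = {e["image_id"]: oracle_label(e["region"], by_id[Path(e["image_id"]).stem], rules)
                 for e in region_entries}
        raters = [RaterModel(f"r{k + 1}", config.annotation.flip_probability)
                  for k in range(config.annotation.n_raters)]
        rng = np.random.default_rng(seeds["raters"])
        records = [AnnotationRecord(image_id, rater.rater_id,
                                    simulate_rater(truth[image_id], rater, rng))
                   for image_id in test_ids for rater in raters]
        uio.write_annotations(records, out / "annotations.csv")

        # -- consensus -----------------------------------------------------
        stage = "consensus"
        by_image: dict[str, list[AnnotationRecord]] = {}
        for r in records:
            by_image.setdefault(r.image_id, []).append(r)
        results = [consensus(by_image[i]) for i in test_ids]
        results = adjudicate(results, {i: truth[i] for i in test_ids})
        uio.write_consensus(results, out / "consensus.csv")
        distribution = agreement_distribution(results)

        # -- agree ---------------------------------------------------------
        stage = "agree"
        report_agree = compute_agreement_report(uio.annotations_frame(records))
        _dump_json(report_agree.to_dict(), out / "agreement.json")

        # -- evaluate ------------------------------------------------------
        stage = "evaluate"
        true_labels = pred_df["true_station"].tolist()
        pred_labels = pred_df["predicted_station"].tolist()
        cm = confusion(true_labels, pred_labels, model.class_order)
        agg = aggregate(cm, model.class_order)
        final_by_image = {r.image_id: r.final_label for r in results}
        strata = stratify(true_labels, pred_labels,
                          [final_by_image[i] for i in test_ids],
                          model.class_order,
                          averaging=config.evaluation.stratified_averaging)
        pd.DataFrame(cm, index=model.class_order,
                     columns=model.class_order).to_csv(out / "confusion_matrix.csv")

        report = {
            "seed": config.seed,
            "derived_seeds": seeds,
            "dataset": {
                "n_frames": len(frames),
                "n_patients": phantom_cfg.n_patients,
                "image_size": phantom_cfg.image_size,
                "stations": list(STATIONS),
                "station_counts": manifest["station"].value_counts().sort_index().to_dict(),
            },
            "training": {
                "backbone": ts.backbone,
                "selected_epoch": model.selected_epoch,
                "epochs_run": int(history["epoch"].max()),
                "best_val_loss": round(float(
                    history[history["split"] == "val"]["loss"].min()), 6),
            },
            "classification": {
                "n_test": len(test_ids),
                "accuracy": round1(agg.accuracy),
                "macro": {k: round1(v) for k, v in agg.macro.items()},
                "weighted": {k: round1(v) for k, v in agg.weighted.items()},
                "per_class": [
                    {"station": m.station, "precision": round1(m.precision),
                     "sensitivity": round1(m.sensitivity), "f1": round1(m.f1),
                     "support": m.support}
                    for m in per_class(cm, model.class_order)
                ],
                "confusion_matrix": cm.tolist(),
            },
            "activation_maps": {
                "overall_counts": maps.overall.counts.tolist(),
                "n_degenerate": maps.n_degenerate,
                "per_station_n": {s: fm.n_images for s, fm in maps.by_station.items()},
            },
            "annotation": {
                "distribution": distribution,
                "truth_label_counts": pd.Series(
                    [t.value for t in truth.values()]).value_counts().sort_index().to_dict(),
            },
            "agreement": report_agree.to_dict(),
            "stratified": {cat: m.to_dict() for cat, m in strata.items()},
        }
        _dump_json(report, out / "report.json")
        _write_html(report, out / "report.html")
        return report
    except Exception as exc:  # noqa: BLE001 - stage name matters to callers
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def _write_html(report: dict, path: Path) -> None:
    body = json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    path.write_text(
        "<html><head><title>Grad-CAM audit report</title></head>"
        f"<body><h1>Grad-CAM audit report</h1><pre>{body}</pre></body></html>"
    )
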