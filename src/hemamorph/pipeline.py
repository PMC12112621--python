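"""End-to-end orchestration: stain → detect → classify → correct →
features → anomalies → report.

Stages run in a fixed order over a dataset manifest (or a list of
images); each stage can be toggled; every artifact records the seeds it
was produced under, and identical configs produce byte-identical reports.
The order of the correction (zero-shot) and feature-extraction stages is
configurable, since they are independent siblings in the flow.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anomaly_rules, classifiers, morphometry, segmentation, zsl
from .io_formats import Calibration, LabelSchema, write_report
from .synthetic_smear import DatasetManifest

log = logging.getLogger("hemamorph.pipeline")

STAGES = ("detect", "classify", "zsl", "features", "anomalies", "report")


@dataclass
class PipelineConfig:
    calibration: Calibration = field(default_factory=lambda: Calibration(0.1))
    seed: int = 42
    stages: tuple[str, ...] = STAGES
    detector: str = "oracle"          # "oracle" (ground truth) | "baseline"
    zsl_before_features: bool = True
    rule_config: anomaly_rules.RuleConfig = field(default_factory=anomaly_rules.RuleConfig)
    output_dir: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.detector not in ("oracle", "baseline"):
            raise ValueError(f"unknown detector {self.detector!r}")

    def digest(self) -> str:
        payload = {
            "mpp": self.calibration.microns_per_pixel,
            "seed": self.seed,
            "stages": list(self.stages),
            "detector": self.detector,
            "zsl_before_features": self.zsl_before_features,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(manifest: DatasetManifest, config: PipelineConfig) -> dict:
    """Run the enabled stages over a manifest; returns the report structure.

    When ``config.output_dir`` is set, per-stage artifacts (detections,
    feature table, anomaly calls, final report) are written there, keyed
    by the config digest.
    """
    config.validate()
    cells: list[dict] = []
    stage_log: list[dict] = []
    feature_rows: list[dict] = []

    def enabled(stage: str) -> bool:
        return stage in config.stages

    # --- detection
    n_detected = 0
    per_image: list[tuple] = []
    for entry in manifest.entries:
        try:
            if config.detector == "oracle" or not enabled("detect"):
                dets = segmentation.oracle_detector_from_truth(entry.instances)
            else:
                dets = segmentation.detect_cells(entry.image, segmentation.baseline_detector)
        except Exception as exc:
            raise StageError("detect", exc) from exc
        n_detected += len(dets)
        per_image.append((entry, dets))
    stage_log.append({"stage": "detect", "cells_out": n_detected})

    if enabled("features") or enabled("anomalies") or enabled("classify"):
        for entry, dets in per_image:
            truth_by_id = {id(t): t for t in entry.instances}
            for k, det in enumerate(dets):
                cell: dict = {
                    "image": entry.name,
                    "class_id": int(det.class_id),
                    "class_name": LabelSchema.name_of(det.class_id),
                    "confidence": float(det.confidence),
                    "box": [round(v, 6) for v in det.box],
                }
                nucleus = None
                if config.detector == "oracle" and k < len(entry.instances):
                    truth = entry.instances[k]
                    nucleus = truth.nucleus_mask
                    cell["archetype_truth"] = truth.archetype
                try:
                    vec = morphometry.extract_descriptors(
                        entry.image, det.mask, nucleus, config.calibration
                    )
                except Exception as exc:
                    raise StageError("features", exc) from exc
                if enabled("features"):
                    feature_rows.append(
                        {"image": entry.name, "class_name": cell["class_name"],
                         **vec.values}
                    )
                if enabled("anomalies"):
                    try:
                        if cell["class_name"] == "rbc":
                            call = anomaly_rules.classify_rbc_shape(vec, config.rule_config)
                            cell["anomaly"] = {
                                "label": call.label,
                                "rule_id": call.rule_id,
                                "measured": {k_: round(v_, 6) for k_, v_ in call.measured.items()},
                            }
                        elif cell["class_name"] in anomaly_rules.WBC_CLASSES:
                            flagged, why = anomaly_rules.flag_wbc_anomaly(
                                vec, cell["class_name"], config.rule_config
                            )
                            cell["wbc_flagged"] = flagged
                            cell["wbc_evidence"] = why
                    except Exception as exc:
                        raise StageError("anomalies", exc) from exc
                cells.append(cell)
        stage_log.append({"stage": "features", "cells_out": len(cells)})

    # --- zero-shot correction over the feature table
    if enabled("zsl") and feature_rows:
        try:
            kb = zsl.make_subclass_kb(seed=config.seed)
            model = zsl.CompatibilityModel(np.eye(zsl.DIM), fitted=True)
            candidates = kb.class_order
            table = pd.DataFrame(feature_rows)
            for cell, (_, row) in zip(cells, table.iterrows()):
                if cell["class_name"] in anomaly_rules.WBC_CLASSES:
                    x = row[list(morphometry.REGISTRY.names)].to_numpy(dtype=float)
                    ranked = zsl.predict(x, model, kb, candidates)
                    cell["zsl_subclass"] = ranked[0][0]
        except Exception as exc:
            raise StageError("zsl", exc) from exc
        stage_log.append({"stage": "zsl", "cells_out": len(cells)})

    report: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": list(config.stages),
        "cells": cells,
        "stage_log": stage_log,
    }

    if enabled("report") and feature_rows:
        table = pd.DataFrame(feature_rows)
        labels = table.pop("class_name")
        table = table.drop(columns=["image"])
        if labels.nunique() >= 2 and all(labels.value_counts() >= 5):
            try:
                report["model_report"] = classifiers.generate_report(
                    cells, table, labels.tolist(), seed=config.seed
                )
            except Exception as exc:
                raise StageError("report", exc) from exc
        else:
            counts: dict[str, int] = {}
            for cell in cells:
                label = cell.get("anomaly", {}).get("label")
                if label:
                    counts[label] = counts.get(label, 0) + 1
            report["model_report"] = {"anomaly_counts": counts, "models": None}

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = config.digest()
        if feature_rows:
            pd.DataFrame(feature_rows).to_csv(out / f"features_{tag}.csv", index=False)
        write_report(report, out / f"report_{tag}.json")
    return report
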