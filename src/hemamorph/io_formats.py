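"""Readers and writers for the formats the pipeline speaks.

Images are RGB arrays in [0, 1]. Object annotations use the YOLO text
dialect: one ``.txt`` file per image, one line per object, five
whitespace-separated fields ``class_id x_center y_center width height``
with coordinates normalized to [0, 1] relative to the image dimensions.
Pixel origin is top-left; boxes are stored in normalized center format.
Reports are deterministic JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

#: The ten instance classes, in fixed alphabetical order; the list index
#: is the class id (basophil = 0, eosinophil = 1, ...).
CLASS_NAMES: tuple[str, ...] = (
    "basophil",
    "eosinophil",
    "erythroblast",
    "intrusion",
    "lymphocyte",
    "monocyte",
    "myelocyte",
    "neutrophil",
    "platelet",
    "rbc",
)

N_CLASSES = len(CLASS_NAMES)


class LabelSchema:
    """Fixed mapping between the ten cell-class names and ids 0..9."""

    names: tuple[str, ...] = CLASS_NAMES

    @classmethod
    def id_of(cls, name: str) -> int:
        try:
            return cls.names.index(name)
        except ValueError:
            raise KeyError(f"unknown class name {name!r}") from None

    @classmethod
    def name_of(cls, class_id: int) -> str:
        if not 0 <= class_id < len(cls.names):
            raise KeyError(f"class id {class_id} outside schema 0..{len(cls.names) - 1}")
        return cls.names[class_id]

    @classmethod
    def __len__(cls) -> int:  # pragma: no cover - convenience
        return len(cls.names)


class YoloFormatError(ValueError):
    """Raised for malformed or out-of-range YOLO annotation data."""


@dataclass(frozen=True)
class YoloRecord:
    """One annotated object: class id plus a normalized center-format box."""

    class_id: int
    x_center: float
    y_center: float
    width: float
    height: float

    def validate(self, index: int | None = None) -> None:
        where = "" if index is None else f" (record {index})"
        if not 0 <= self.class_id < N_CLASSES:
            raise YoloFormatError(f"class_id {self.class_id} outside schema{where}")
        for field in ("x_center", "y_center", "width", "height"):
            v = getattr(self, field)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise YoloFormatError(f"{field}={v} not in [0, 1]{where}")
        if self.width <= 0 or self.height <= 0:
            raise YoloFormatError(f"non-positive box extent{where}")

    def to_pixels(self, height: int, width: int) -> tuple[int, int, int, int]:
        """Denormalize to integer pixel bounds (r0, c0, r1, c1), r1/c1 exclusive."""
        cx, cy = self.x_center * width, self.y_center * height
        w, h = self.width * width, self.height * height
        c0 = int(round(cx - w / 2))
        r0 = int(round(cy - h / 2))
        c1 = int(round(cx + w / 2))
        r1 = int(round(cy + h / 2))
        return r0, c0, max(r1, r0 + 1), max(c1, c0 + 1)


def box_from_mask(mask: np.ndarray) -> tuple[float, float, float, float]:
    """Tight normalized center-format box (x_c, y_c, w, h) of a binary mask."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        raise ValueError("empty mask has no box")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    H, W = mask.shape
    w = (c1 - c0 + 1) / W
    h = (r1 - r0 + 1) / H
    return ((c0 + c1 + 1) / 2 / W, (r0 + r1 + 1) / 2 / H, w, h)


@dataclass(frozen=True)
class Calibration:
    """Physical pixel size of the imaging setup."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be finite and positive")


def write_yolo_labels(records: Sequence[YoloRecord]) -> str:
    """Serialize records, one line each, six decimal places, input order."""
    lines = []
    for i, rec in enumerate(records):
        rec.validate(index=i)
        lines.append(
            f"{rec.class_id} {rec.x_center:.6f} {rec.y_center:.6f} "
            f"{rec.width:.6f} {rec.height:.6f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_yolo_labels(text: str) -> list[YoloRecord]:
    """Parse YOLO label text; blank lines are ignored."""
    records: list[YoloRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 5:
            raise YoloFormatError(
                f"line {lineno}: expected 5 fields, got {len(fields)}"
            )
        try:
            class_id = int(fields[0])
            coords = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise YoloFormatError(f"line {lineno}: non-numeric field") from exc
        rec = YoloRecord(class_id, *coords)
        try:
            rec.validate()
        except YoloFormatError as exc:
            raise YoloFormatError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as float RGB in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float RGB array in [0, 1] as an 8-bit image file."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)


def write_report(results: dict, path: str | Path | None = None) -> str:
    """Serialize a pipeline result bundle to deterministic JSON.

    ``results`` carries per-cell classes, anomaly calls and model metrics;
    summary counts are (re)computed here so the report is self-consistent.
    Identical inputs always produce byte-identical output (sorted keys, no
    timestamps).
    """
    cells = results.get("cells", [])
    anomalies = [c for c in cells if c.get("anomaly", {}).get("label") not in (None, "Normal")]
    report = dict(results)
    report["summary"] = {
        "cells": len(cells),
        "anomalies": len(anomalies),
        **results.get("summary", {}),
    }
    text = json.dumps(report, sort_keys=True, indent=2, default=_jsonable) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_label_file(records: Iterable[YoloRecord], path: str | Path) -> None:
    Path(path).write_text(write_yolo_labels(list(records)))


def read_label_file(path: str | Path) -> list[YoloRecord]:
    return read_yolo_labels(Path(path).read_text())
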