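"""Instance detection: contract, classical baseline, and evaluation.

A detector is any callable ``image -> list[Detection]`` producing the
triple (box, mask, class) with a confidence.  The in-repo baseline is a
classical pipeline (background-subtracted luminance → Otsu threshold →
connected components → distance-transform watershed) meant as a
deterministic stand-in behind the same contract that a trained neural
detector would use.

Evaluation implements greedy IoU matching, precision/recall/F1, per-class
average precision at IoU 0.5 (continuous area under the interpolated
precision–recall curve) with mAP@50 and mAP@50:95, and normalized
confusion matrices with an explicit background row/column.

Empty-set conventions: with no predictions and some truths, precision is
0 (and recall 0); with both sets empty all metrics are 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import N_CLASSES, box_from_mask


@dataclass
class Detection:
    """One detected instance: normalized (x, y, w, h) box, mask, class, score."""

    box: tuple[float, float, float, float]   # x_center, y_center, w, h in [0,1]
    mask: np.ndarray
    class_id: int
    confidence: float = 1.0

    def validate(self) -> None:
        if not self.mask.any():
            raise ValueError("detection mask is empty")
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError(f"class id {self.class_id} outside schema")


@dataclass
class MatchResult:
    """Greedy matching outcome for one image."""

    matches: list[tuple[int, int, float]]    # (pred index, truth index, IoU)
    unmatched_preds: list[int]               # false positives
    unmatched_truths: list[int]              # false negatives
    pred_classes: list[int] = field(default_factory=list)
    truth_classes: list[int] = field(default_factory=list)
    pred_confidences: list[float] = field(default_factory=list)


def iou(boxA: tuple, boxB: tuple) -> float:
    """Intersection over union of two (x, y, w, h) boxes (corner origin)."""
    ax, ay, aw, ah = boxA
    bx, by, bw, bh = boxB
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("degenerate zero-area box")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def center_to_corner(box: tuple) -> tuple:
    x, y, w, h = box
    return (x - w / 2, y - h / 2, w, h)


def mask_iou(mA: np.ndarray, mB: np.ndarray) -> float:
    mA, mB = np.asarray(mA, bool), np.asarray(mB, bool)
    if not mA.any() or not mB.any():
        raise ValueError("degenerate empty mask")
    inter = np.logical_and(mA, mB).sum()
    union = np.logical_or(mA, mB).sum()
    return float(inter / union)


def match_detections(
    preds: list[Detection],
    truths: list,
    iou_threshold: float = 0.5,
    class_aware: bool = True,
    use_masks: bool = True,
) -> MatchResult:
    """Greedy one-to-one matching in descending confidence order.

    Ties in confidence break toward higher IoU, then lower prediction
    index.  ``truths`` are ground-truth instances exposing ``mask``,
    ``class_id`` and a normalized center-format box.
    """
    order = sorted(
        range(len(preds)), key=lambda i: (-preds[i].confidence, i)
    )
    truth_used = [False] * len(truths)
    matches: list[tuple[int, int, float]] = []
    for pi in order:
        p = preds[pi]
        best_j, best_iou = -1, -1.0
        for j, t in enumerate(truths):
            if truth_used[j]:
                continue
            if class_aware and p.class_id != t.class_id:
                continue
            if use_masks:
                val = mask_iou(p.mask, t.mask)
            else:
                tb = t.box
                tbox = (tb.x_center, tb.y_center, tb.width, tb.height)
                val = iou(center_to_corner(p.box), center_to_corner(tbox))
            if val >= iou_threshold and val > best_iou:
                best_j, best_iou = j, val
        if best_j >= 0:
            truth_used[best_j] = True
            matches.append((pi, best_j, best_iou))
    matched_preds = {m[0] for m in matches}
    return MatchResult(
        matches=matches,
        unmatched_preds=[i for i in range(len(preds)) if i not in matched_preds],
        unmatched_truths=[j for j in range(len(truths)) if not truth_used[j]],
        pred_classes=[p.class_id for p in preds],
        truth_classes=[t.class_id for t in truths],
        pred_confidences=[p.confidence for p in preds],
    )


def detection_metrics(results: list[MatchResult]) -> dict:
    """Dataset-level precision, recall, F1, macro-F1 and mAP@50.

    Average precision per class integrates the interpolated
    precision–recall curve over the confidence sweep at IoU 0.5; mAP
    averages over classes present in the ground truth.
    """
    if not results:
        raise ValueError("no match results")
    tp = sum(len(r.matches) for r in results)
    fp = sum(len(r.unmatched_preds) for r in results)
    fn = sum(len(r.unmatched_truths) for r in results)
    if tp + fp == 0 and tp + fn == 0:
        precision = recall = f1 = 1.0
    else:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )

    # confidence sweep per class for AP@50
    truth_classes = [c for r in results for c in r.truth_classes]
    classes = sorted(set(truth_classes))
    aps, per_class_f1 = [], []
    for cls in classes:
        scored: list[tuple[float, bool]] = []
        n_truth = truth_classes.count(cls)
        for r in results:
            matched_preds = {pi: True for pi, _, _ in r.matches}
            for pi, c in enumerate(r.pred_classes):
                if c == cls:
                    scored.append((r.pred_confidences[pi], pi in matched_preds))
        # conservative deterministic tie-break: at equal confidence, misses
        # precede hits, which keeps metrics permutation-invariant over images
        scored.sort(key=lambda s: (-s[0], s[1]))
        hits = np.array([h for _, h in scored], dtype=float)
        if n_truth == 0:
            continue
        if len(hits) == 0:
            aps.append(0.0)
            per_class_f1.append(0.0)
            continue
        cum_tp = np.cumsum(hits)
        prec = cum_tp / np.arange(1, len(hits) + 1)
        rec = cum_tp / n_truth
        # interpolated precision envelope, continuous integration
        env = np.maximum.accumulate(prec[::-1])[::-1]
        ap = float(np.sum(np.diff(np.concatenate([[0.0], rec])) * env))
        aps.append(ap)
        p_c = prec[-1]
        r_c = rec[-1]
        per_class_f1.append(2 * p_c * r_c / (p_c + r_c) if p_c + r_c else 0.0)
    map50 = float(np.mean(aps)) if aps else 1.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_f1": float(np.mean(per_class_f1)) if per_class_f1 else 1.0,
        "mAP50": map50,
    }


def confusion_matrix(
    preds_per_image: list[list[Detection]],
    truths_per_image: list[list],
    iou_threshold: float = 0.5,
    normalize: str | None = "row",
) -> np.ndarray:
    """(K+1)x(K+1) confusion matrix including a background row/column.

    Matching is class-agnostic at the IoU threshold first; the matched
    pair's classes fill the K x K block, unmatched truths count toward the
    background column, unmatched predictions toward the background row.
    With ``normalize='row'`` every non-empty row sums to 1.
    """
    K = N_CLASSES
    mat = np.zeros((K + 1, K + 1))
    for preds, truths in zip(preds_per_image, truths_per_image):
        r = match_detections(preds, truths, iou_threshold, class_aware=False)
        for pi, tj, _ in r.matches:
            mat[truths[tj].class_id, preds[pi].class_id] += 1
        for tj in r.unmatched_truths:
            mat[truths[tj].class_id, K] += 1
        for pi in r.unmatched_preds:
            mat[K, preds[pi].class_id] += 1
    if normalize == "row":
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            mat = np.where(sums > 0, mat / sums, 0.0)
    return mat


# ---------------------------------------------------------------------------
# Baseline detector
# ---------------------------------------------------------------------------

def baseline_detector(image: np.ndarray, min_area_px: int = 30) -> list[Detection]:
    """Classical cell detector: Otsu + connected components + watershed.

    Steps: luminance → large-scale median background subtraction → Otsu
    foreground threshold → connected components → distance-transform
    watershed to split touching cells → per-component class by a
    size/color heuristic.  Deterministic.
    """
    from skimage.color import rgb2gray
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed
    from skimage.feature import peak_local_max

    gray = rgb2gray(image)
    # plasma is the brightest broad region; a high quantile is robust even
    # when cells cover most of the frame (a median would not be)
    background = np.percentile(gray, 90)
    signal = background - gray  # cells are darker than plasma
    vals = signal.ravel()
    if vals.max() - vals.min() < 1e-6:
        return []
    t = threshold_otsu(vals)
    # floor well above the background texture amplitude so a blank frame
    # yields no foreground
    fg = signal > max(t, 0.1)
    fg = ndimage.binary_opening(fg, iterations=1)
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return []

    dist = ndimage.distance_transform_edt(fg)
    coords = peak_local_max(dist, labels=fg, min_distance=8, exclude_border=False)
    markers = np.zeros(fg.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labeled, _ = ndimage.label(fg)
    else:
        labeled = watershed(-dist, markers, mask=fg)

    detections: list[Detection] = []
    for lab in range(1, labeled.max() + 1):
        mask = labeled == lab
        area = int(mask.sum())
        if area < min_area_px:
            continue
        x_c, y_c, w, h = box_from_mask(mask)
        class_id = _classify_component(image, mask)
        conf = min(1.0, area / 500.0) * 0.5 + 0.5
        detections.append(Detection((x_c, y_c, w, h), mask, class_id, conf))
    detections.sort(key=lambda d: -d.confidence)
    return detections


def _classify_component(image: np.ndarray, mask: np.ndarray) -> int:
    """Size/color heuristic over the schema's ten classes.

    Blue-dominant (basophilic) blobs are leukocyte-lineage or platelets by
    size; reddish blobs are erythroid; desaturated gray is an artifact.
    """
    from .io_formats import LabelSchema

    rgb = image[mask].mean(axis=0)
    r, g, b = rgb
    area = mask.sum()
    blueness = b - (r + g) / 2
    redness = r - (g + b) / 2
    if redness > 0.05:
        return LabelSchema.id_of("rbc")
    if blueness > 0.03:
        if area < 1200:
            return LabelSchema.id_of("platelet")
        if area < 3500:
            return LabelSchema.id_of("lymphocyte")
        return LabelSchema.id_of("monocyte")
    return LabelSchema.id_of("intrusion")


def detect_cells(image: np.ndarray, detector=baseline_detector) -> list[Detection]:
    """Run a detector satisfying the contract; validate and sort its output."""
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("image must be normalized to [0, 1]")
    try:
        detections = detector(image)
    except Exception as exc:  # propagate with context
        raise RuntimeError(f"detector {getattr(detector, '__name__', detector)!r} failed") from exc
    for d in detections:
        d.validate()
        # contract: box is the tight box of the mask
        d.box = box_from_mask(d.mask)
    detections.sort(key=lambda d: -d.confidence)
    return detections


def oracle_detector_from_truth(truths: list) -> list[Detection]:
    """Pass ground truth through the detector contract (evaluation oracle)."""
    return [
        Detection(
            (t.box.x_center, t.box.y_center, t.box.width, t.box.height),
            t.mask,
            t.class_id,
            1.0,
        )
        for t in truths
    ]
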