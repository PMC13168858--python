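"""Segmentation evaluation: overlap scores, instance matching, detection metrics.

Implements Dice / IoU with an explicit empty-vs-empty convention,
maximum-total-IoU (Hungarian) instance matching with an IoU cutoff,
COCO-style AP/AR with 101-point precision interpolation averaged over
IoU thresholds 0.50:0.05:0.95, macro/micro aggregation across anatomical
structures, plus a geometric threshold segmenter used as a stand-in
predictor on rendered synthetic frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage import measure
from skimage.draw import polygon as draw_polygon

STRUCTURES = ("palpebral_fissure", "iris", "pupil")
COCO_CATEGORY_IDS = {"palpebral_fissure": 1, "iris": 2, "pupil": 3}

MaskKey = tuple[str, str]  # (structure, eye)


@dataclass
class FrameMasks:
    """Binary masks for one frame, keyed by (structure, eye).

    ``confidences`` default to 1.0 (geometric predictions carry no score).
    """

    frame_index: int
    masks: dict[MaskKey, np.ndarray]
    confidences: dict[MaskKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks must share one image shape, got {shapes}")
        for key in self.masks:
            self.masks[key] = np.asarray(self.masks[key], dtype=bool)
            self.confidences.setdefault(key, 1.0)

    def get(self, structure: str, eye: str) -> np.ndarray | None:
        return self.masks.get((structure, eye))


@dataclass
class SegmentationScore:
    """Scores in percent, as conventionally tabulated."""

    dice: float
    iou: float
    ap50: float = float("nan")
    ap50_95: float = float("nan")
    ar50_95: float = float("nan")
    aggregation_mode: str = "macro"


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


def overlap_scores(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Return ``(dice, iou)`` as fractions.

    Both scores are 1.0 when both masks are empty (mutual absence counts
    as agreement) and 0.0 when exactly one is empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    inter = int((a & b).sum())
    dice = 2.0 * inter / (na + nb)
    iou = inter / (na + nb - inter)
    return dice, iou


@dataclass
class OverlapCounts:
    """Raw pixel counts for one (structure, eye) pair on one image."""

    intersection: int
    pred_pixels: int
    truth_pixels: int

    @property
    def dice(self) -> float:
        if self.pred_pixels + self.truth_pixels == 0:
            return 1.0
        return 2.0 * self.intersection / (self.pred_pixels + self.truth_pixels)

    @property
    def iou(self) -> float:
        union = self.pred_pixels + self.truth_pixels - self.intersection
        if union == 0:
            return 1.0
        return self.intersection / union


def score_frame(pred: FrameMasks, truth: FrameMasks) -> dict[MaskKey, OverlapCounts]:
    """Pixel-count comparison over the union of keys of both frames."""
    out: dict[MaskKey, OverlapCounts] = {}
    keys = set(pred.masks) | set(truth.masks)
    shape = next(iter((pred.masks or truth.masks).values())).shape
    empty = np.zeros(shape, dtype=bool)
    for key in keys:
        p = pred.masks.get(key, empty)
        t = truth.masks.get(key, empty)
        if p.shape != t.shape:
            raise ValueError("prediction/truth image shapes differ")
        out[key] = OverlapCounts(
            intersection=int((p & t).sum()),
            pred_pixels=int(p.sum()),
            truth_pixels=int(t.sum()),
        )
    return out


# ---------------------------------------------------------------------------
# instance matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (pred index, truth index, iou)
    unmatched_pred: list[int]
    unmatched_truth: list[int]

    @property
    def total_iou(self) -> float:
        return sum(iou for _, _, iou in self.pairs)


def match_instances(
    predicted: list[np.ndarray],
    truth: list[np.ndarray],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """One-to-one assignment maximizing total IoU, then cut below threshold.

    Unmatched predictions are false positives; unmatched truths false
    negatives.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    if not predicted or not truth:
        return MatchResult([], list(range(len(predicted))), list(range(len(truth))))
    iou_mat = np.zeros((len(predicted), len(truth)))
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            iou_mat[i, j] = overlap_scores(p, t)[1]
    rows, cols = linear_sum_assignment(-iou_mat)
    pairs = [
        (int(i), int(j), float(iou_mat[i, j]))
        for i, j in zip(rows, cols)
        if iou_mat[i, j] >= iou_threshold
    ]
    matched_p = {i for i, _, _ in pairs}
    matched_t = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[i for i in range(len(predicted)) if i not in matched_p],
        unmatched_truth=[j for j in range(len(truth)) if j not in matched_t],
    )


# ---------------------------------------------------------------------------
# COCO-style detection metrics
# ---------------------------------------------------------------------------

IOU_THRESHOLDS = np.arange(0.50, 0.96, 0.05)
RECALL_GRID = np.linspace(0.0, 1.0, 101)


def _ap_and_recall(
    order: list[int],
    ious: np.ndarray,
    image_ids: list,
    truth_images: list,
    thr: float,
) -> tuple[float, float]:
    """Greedy confidence-ordered matching at one IoU threshold."""
    n_truth = len(truth_images)
    matched = np.zeros(n_truth, dtype=bool)
    tp = np.zeros(len(order))
    for rank, pi in enumerate(order):
        best, best_iou = -1, thr
        for ti in range(n_truth):
            if matched[ti] or truth_images[ti] != image_ids[pi]:
                continue
            if ious[pi, ti] >= best_iou:
                best, best_iou = ti, ious[pi, ti]
        if best >= 0:
            matched[best] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.arange(1, len(order) + 1)
    # monotone precision envelope, then 101-point interpolation
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = 0.0
    for r in RECALL_GRID:
        idx = np.searchsorted(recall, r, side="left")
        ap += precision[idx] if idx < len(precision) else 0.0
    ap /= len(RECALL_GRID)
    return ap, float(matched.sum()) / n_truth


@dataclass
class DetectionMetrics:
    ap50: float
    ap50_95: float
    ar50_95: float


def coco_detection_metrics(
    predictions: list[tuple[object, np.ndarray, float]],
    truths: list[tuple[object, np.ndarray]],
) -> DetectionMetrics:
    """AP@0.50, AP@0.50-0.95 and AR@0.50-0.95 in percent.

    ``predictions`` are ``(image_id, mask, confidence)`` tuples;
    ``truths`` are ``(image_id, mask)``.  Returns NaNs when no truths
    exist (undefined).  Confidence ties are broken by larger mask area.
    """
    if not truths:
        return DetectionMetrics(float("nan"), float("nan"), float("nan"))
    if not predictions:
        return DetectionMetrics(0.0, 0.0, 0.0)
    truth_images = [t[0] for t in truths]
    image_ids = [p[0] for p in predictions]
    ious = np.zeros((len(predictions), len(truths)))
    for i, (img_i, pmask, _) in enumerate(predictions):
        for j, (img_j, tmask) in enumerate(truths):
            if img_i == img_j:
                ious[i, j] = overlap_scores(pmask, tmask)[1]
    areas = [int(np.asarray(p[1], dtype=bool).sum()) for p in predictions]
    order = sorted(range(len(predictions)), key=lambda i: (-predictions[i][2], -areas[i]))
    aps, recalls = [], []
    for thr in IOU_THRESHOLDS:
        ap, rec = _ap_and_recall(order, ious, image_ids, truth_images, float(thr))
        aps.append(ap)
        recalls.append(rec)
    return DetectionMetrics(
        ap50=100.0 * aps[0],
        ap50_95=100.0 * float(np.mean(aps)),
        ar50_95=100.0 * float(np.mean(recalls)),
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_structure_scores(
    per_image_scores: list[dict[MaskKey, OverlapCounts]],
    detection: dict[str, DetectionMetrics] | None = None,
) -> dict:
    """Aggregate per-image overlap counts into structure and overall scores.

    Per-structure values are macro-averaged across eyes and images.  The
    overall macro score is the unweighted mean across structures; the
    overall micro score re-computes Dice/IoU from pixel counts pooled over
    all structures and images.
    """
    if not per_image_scores:
        raise ValueError("need at least one scored image")
    detection = detection or {}
    per_structure: dict[str, SegmentationScore] = {}
    pooled = OverlapCounts(0, 0, 0)
    structure_means = []
    for structure in STRUCTURES:
        dices, ious = [], []
        for frame_scores in per_image_scores:
            for (s, _eye), counts in frame_scores.items():
                if s != structure:
                    continue
                dices.append(counts.dice)
                ious.append(counts.iou)
                pooled.intersection += counts.intersection
                pooled.pred_pixels += counts.pred_pixels
                pooled.truth_pixels += counts.truth_pixels
        if not dices:
            continue
        det = detection.get(structure)
        per_structure[structure] = SegmentationScore(
            dice=100.0 * float(np.mean(dices)),
            iou=100.0 * float(np.mean(ious)),
            ap50=det.ap50 if det else float("nan"),
            ap50_95=det.ap50_95 if det else float("nan"),
            ar50_95=det.ar50_95 if det else float("nan"),
            aggregation_mode="macro",
        )
        structure_means.append((float(np.mean(dices)), float(np.mean(ious))))
    macro = SegmentationScore(
        dice=100.0 * float(np.mean([d for d, _ in structure_means])),
        iou=100.0 * float(np.mean([i for _, i in structure_means])),
        aggregation_mode="macro",
    )
    micro = SegmentationScore(
        dice=100.0 * pooled.dice,
        iou=100.0 * pooled.iou,
        aggregation_mode="micro",
    )
    return {"per_structure": per_structure, "macro": macro, "micro": micro}


def scores_to_frame(aggregated: dict) -> pd.DataFrame:
    rows = []
    for name, score in aggregated["per_structure"].items():
        rows.append(
            {
                "structure": name,
                "dice": score.dice,
                "iou": score.iou,
                "ap50": score.ap50,
                "ap50_95": score.ap50_95,
                "ar50_95": score.ar50_95,
                "aggregation": score.aggregation_mode,
            }
        )
    for label in ("macro", "micro"):
        s = aggregated[label]
        rows.append(
            {
                "structure": f"overall_{label}",
                "dice": s.dice,
                "iou": s.iou,
                "ap50": s.ap50,
                "ap50_95": s.ap50_95,
                "ar50_95": s.ar50_95,
                "aggregation": s.aggregation_mode,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometric stand-in segmenter
# ---------------------------------------------------------------------------


def geometric_segment_frame(frame: np.ndarray, eye: str = "left", frame_index: int = 0) -> FrameMasks:
    """Threshold-based segmentation of a rendered grayscale eye frame.

    Intensity is normalized after clipping overexposed pixels; the
    darkest connected blob becomes the pupil, the mid-intensity region
    around it the iris disk, and the union of non-background intensities
    the palpebral aperture.  All three masks are empty for closed or
    featureless frames.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    shape = img.shape
    empty = {
        ("palpebral_fissure", eye): np.zeros(shape, dtype=bool),
        ("iris", eye): np.zeros(shape, dtype=bool),
        ("pupil", eye): np.zeros(shape, dtype=bool),
    }
    full_scale = 1.0 if img.max() <= 1.0 else 255.0
    if np.ptp(img) < 0.04 * full_scale:  # featureless (closed eye / blank)
        return FrameMasks(frame_index=frame_index, masks=empty)
    clipped = np.clip(img, None, np.percentile(img, 99.5))
    if np.ptp(clipped) == 0:  # only a sub-0.5% speck differed from background
        return FrameMasks(frame_index=frame_index, masks=empty)
    norm = (clipped - clipped.min()) / np.ptp(clipped)

    fissure_px = (norm < 0.62) | (norm > 0.85)
    fissure = _largest_component(fissure_px)
    dark = norm < 0.25
    pupil = _largest_component(dark & fissure)
    iris = _component_containing((norm < 0.62) & fissure, pupil)
    return FrameMasks(
        frame_index=frame_index,
        masks={
            ("palpebral_fissure", eye): fissure,
            ("iris", eye): iris | pupil,
            ("pupil", eye): pupil,
        },
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _component_containing(mask: np.ndarray, seed: np.ndarray) -> np.ndarray:
    if not seed.any():
        return _largest_component(mask)
    labels = measure.label(mask)
    seed_labels = np.unique(labels[seed])
    seed_labels = seed_labels[seed_labels > 0]
    if len(seed_labels) == 0:
        return _largest_component(mask)
    return labels == seed_labels[0]


# ---------------------------------------------------------------------------
# COCO-format JSON round trip
# ---------------------------------------------------------------------------


def mask_stack_to_coco(stack: list[FrameMasks], image_shape: tuple[int, int]) -> dict:
    """Serialize a mask stack to a COCO-style dict with polygon segmentations."""
    h, w = image_shape
    images = []
    annotations = []
    ann_id = 1
    for fm in stack:
        images.append({"id": fm.frame_index, "height": h, "width": w})
        for (structure, eye), mask in fm.masks.items():
            if not mask.any():
                continue
            polys = []
            for contour in measure.find_contours(mask.astype(float), 0.5):
                if len(contour) < 3:
                    continue
                # contour is (row, col); COCO wants x,y interleaved
                xy = np.empty(2 * len(contour))
                xy[0::2] = contour[:, 1]
                xy[1::2] = contour[:, 0]
                polys.append([round(float(v), 2) for v in xy])
            if not polys:
                continue
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": fm.frame_index,
                    "category_id": COCO_CATEGORY_IDS[structure],
                    "segmentation": polys,
                    "area": int(mask.sum()),
                    "iscrowd": 0,
                    "attributes": {"eye": eye},
                }
            )
            ann_id += 1
    categories = [
        {"id": cid, "name": name} for name, cid in COCO_CATEGORY_IDS.items()
    ]
    return {"images": images, "annotations": annotations, "categories": categories}


def coco_to_mask_stack(obj: dict) -> list[FrameMasks]:
    """Rasterize a COCO-style dict (polygon segmentations) to a mask stack."""
    id_to_structure = {c["id"]: c["name"] for c in obj["categories"]}
    shapes = {img["id"]: (img["height"], img["width"]) for img in obj["images"]}
    frames: dict[int, dict[MaskKey, np.ndarray]] = {
        img_id: {} for img_id in shapes
    }
    for ann in obj["annotations"]:
        shape = shapes[ann["image_id"]]
        mask = np.zeros(shape, dtype=bool)
        for poly in ann["segmentation"]:
            xs = np.asarray(poly[0::2])
            ys = np.asarray(poly[1::2])
            rr, cc = draw_polygon(ys, xs, shape=shape)
            mask[rr, cc] = True
        eye = ann.get("attributes", {}).get("eye", "left")
        key = (id_to_structure[ann["category_id"]], eye)
        prev = frames[ann["image_id"]].get(key)
        frames[ann["image_id"]][key] = mask if prev is None else (prev | mask)
    return [
        FrameMasks(frame_index=img_id, masks=masks)
        for img_id, masks in sorted(frames.items())
    ]


def write_coco_json(stack: list[FrameMasks], image_shape: tuple[int, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(mask_stack_to_coco(stack, image_shape)))


def read_coco_json(path: str | Path) -> list[FrameMasks]:
    return coco_to_mask_stack(json.loads(Path(path).read_text()))
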