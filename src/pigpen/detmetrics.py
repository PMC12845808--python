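"""Single-class detection evaluation: IoU, matching, precision/recall/F1, AP50.

Boxes are axis-aligned ``(x1, y1, x2, y2)`` in continuous half-open pixel
coordinates with the origin at the top-left.  A detection counts as a true
positive when its IoU with an unmatched ground-truth box is at least the
threshold (0.5 by default), under one-to-one matching in descending
confidence order.  AP50 is the area under the precision-recall curve with
all-point interpolation: ``p_interp(r) = max{p(r') : r' >= r}`` and
``AP = sum_k (r_k - r_{k-1}) * p_interp(r_k)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Detection",
    "MatchResult",
    "EvalReport",
    "iou",
    "match_detections",
    "precision_recall_f1",
    "ap50",
    "evaluate",
    "load_detections_json",
    "save_detections_json",
]

Box = tuple[float, float, float, float]


@dataclass(frozen=True)
class Detection:
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    ap50: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)


def iou(b: Box, g: Box) -> float:
    """Intersection over union of two boxes in continuous coordinates."""
    bx1, by1, bx2, by2 = b
    gx1, gy1, gx2, gy2 = g
    if bx2 <= bx1 or by2 <= by1 or gx2 <= gx1 or gy2 <= gy1:
        raise ValueError("degenerate box")
    iw = min(bx2, gx2) - max(bx1, gx1)
    ih = min(by2, gy2) - max(by1, gy1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (bx2 - bx1) * (by2 - by1) + (gx2 - gx1) * (gy2 - gy1) - inter
    return inter / union


def match_detections(
    dets: list[Detection], gts: list[Box], iou_thr: float = 0.5
) -> MatchResult:
    """One-to-one greedy matching in descending confidence order.

    Each detection (ties broken by input order) claims the unmatched
    ground-truth box with the highest IoU, provided it reaches ``iou_thr``.
    """
    if not 0.0 < iou_thr <= 1.0:
        raise ValueError("iou_thr must be in (0, 1]")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    for di in order:
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(gts):
            if taken[gi]:
                continue
            v = iou(dets[di].box, g)
            if v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi >= 0 and best_iou >= iou_thr:
            taken[best_gi] = True
            pairs.append((di, best_gi, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp, matched_pairs=pairs)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Standard ratios with the 0-when-denominator-0 convention."""
    p = m.tp / (m.tp + m.fp) if m.tp + m.fp else 0.0
    r = m.tp / (m.tp + m.fn) if m.tp + m.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _tp_flags_by_image(
    dets_by_image: dict, gts_by_image: dict, iou_thr: float
) -> tuple[list[tuple[float, int, bool]], int]:
    """Per-detection (confidence, order, is_tp) flags plus the total gt count."""
    flagged: list[tuple[float, int, bool]] = []
    n_gt = 0
    order = 0
    for image, gts in gts_by_image.items():
        n_gt += len(gts)
    for image, dets in dets_by_image.items():
        gts = gts_by_image.get(image, [])
        m = match_detections(dets, gts, iou_thr)
        matched = {di for di, _, _ in m.matched_pairs}
        for di, d in enumerate(dets):
            flagged.append((d.confidence, order, di in matched))
            order += 1
    return flagged, n_gt


def _ap_from_flags(flagged: list[tuple[float, int, bool]], n_gt: int) -> tuple[float, list]:
    if n_gt == 0:
        raise ValueError("ap50 requires at least one ground-truth box")
    if not flagged:
        return 0.0, []
    flagged = sorted(flagged, key=lambda t: (-t[0], t[1]))
    tps = np.cumsum([f for _, _, f in flagged])
    fps = np.cumsum([not f for _, _, f in flagged])
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    # all-point interpolation: running max of precision from the right
    p_interp = np.maximum.accumulate(precisions[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    curve = []
    for r, p in zip(recalls, p_interp):
        ap += (r - prev_r) * p
        prev_r = r
        curve.append((float(r), float(p)))
    return float(ap), curve


def ap50(dets: list[Detection], gts: list[Box], iou_thr: float = 0.5) -> float:
    """All-point-interpolated average precision at the given IoU threshold."""
    if not gts:
        raise ValueError("ap50 requires nonempty ground truth")
    flagged, n_gt = _tp_flags_by_image({"_": dets}, {"_": gts}, iou_thr)
    return _ap_from_flags(flagged, n_gt)[0]


def evaluate(
    dets_by_image: dict[str, list[Detection]],
    gts_by_image: dict[str, list[Box]],
    iou_thr: float = 0.5,
) -> EvalReport:
    """Pooled evaluation over an image set.

    Matching runs per image; the precision-recall sweep pools all
    detections by confidence.  Precision/recall/F1 are reported at the
    operating point that uses every supplied detection.
    """
    flagged, n_gt = _tp_flags_by_image(dets_by_image, gts_by_image, iou_thr)
    ap, curve = _ap_from_flags(flagged, n_gt)
    tp = sum(1 for _, _, f in flagged if f)
    m = MatchResult(tp=tp, fp=len(flagged) - tp, fn=n_gt - tp)
    p, r, f1 = precision_recall_f1(m)
    return EvalReport(precision=p, recall=r, f1=f1, ap50=ap, pr_curve=curve)


def save_detections_json(path: str | Path, dets_by_image: dict[str, list[Detection]]) -> None:
    """Detections as a JSON list of {image, x1, y1, x2, y2, score}."""
    records = [
        {"image": image, "x1": d.box[0], "y1": d.box[1], "x2": d.box[2], "y2": d.box[3],
         "score": d.confidence}
        for image, dets in dets_by_image.items()
        for d in dets
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_detections_json(path: str | Path) -> dict[str, list[Detection]]:
    out: dict[str, list[Detection]] = {}
    for rec in json.loads(Path(path).read_text()):
        out.setdefault(rec["image"], []).append(
            Detection(box=(rec["x1"], rec["y1"], rec["x2"], rec["y2"]), confidence=rec["score"])
        )
    return out
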