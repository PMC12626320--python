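"""Detection-quality and tracking-continuity evaluation.

Detection evaluation follows standard practice: detections are greedily
matched to ground truth in descending score order at a fixed IoU threshold
(best IoU breaks ties), yielding TP/FP/FN counts; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean; AP is the area under the
all-point-interpolated precision-recall curve (precision envelope), and
mAP50 is AP at IoU 0.5 averaged over classes — identical to AP for this
single-class (worm) problem.

Tracking continuity is scored by associating each ground-truth identity to
tracker output per frame by best IoU: an id switch is a frame where a truth
identity's matched track id changes; a fragmentation is an interruption of
its coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigError
from .geometry import BoundingBox, Detection, iou

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "match_to_ground_truth",
    "precision_recall_f1",
    "f1_score",
    "average_precision",
    "mean_ap",
    "fps",
    "tracking_continuity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation run's detection and continuity scores.

    ``fps`` is wall-clock throughput, reported for logging only (hardware
    dependent). Undefined ratios (zero denominators) are None.
    """

    precision: float | None
    recall: float | None
    f1: float | None
    ap: float | None
    map50: float | None
    fps: float | None = None
    id_switches: int = 0
    fragmentation: int = 0
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap": self.ap,
            "map50": self.map50,
            "fps": self.fps,
            "id_switches": self.id_switches,
            "fragmentation": self.fragmentation,
        }


def _group_by_frame(items: Iterable[Detection]) -> dict[int, list[Detection]]:
    out: dict[int, list[Detection]] = {}
    for d in items:
        out.setdefault(d.frame, []).append(d)
    return out


def match_to_ground_truth(
    detections: Iterable[Detection],
    truths: Iterable[Detection],
    iou_threshold: float = 0.5,
) -> ConfusionCounts:
    """Greedy score-ordered matching of detections to ground truth per frame.

    Each truth is matched to at most one detection with IoU >= threshold;
    within a frame, detections claim truths in descending score order, each
    taking its best-IoU available truth. Unmatched detections count FP,
    unmatched truths FN.
    """
    if iou_threshold < 0:
        raise ConfigError(f"iou_threshold must be >= 0, got {iou_threshold}")
    det_by_frame = _group_by_frame(detections)
    truth_by_frame = _group_by_frame(truths)
    tp = fp = fn = 0
    for frame in sorted(set(det_by_frame) | set(truth_by_frame)):
        dets = sorted(det_by_frame.get(frame, []), key=lambda d: -d.score)
        gts = truth_by_frame.get(frame, [])
        taken = [False] * len(gts)
        for det in dets:
            best_j, best_iou = -1, iou_threshold
            for j, gt in enumerate(gts):
                if taken[j]:
                    continue
                v = iou(det.box, gt.box)
                if v >= best_iou and v > 0:
                    best_j, best_iou = j, v
            if best_j >= 0:
                taken[best_j] = True
                tp += 1
            else:
                fp += 1
        fn += taken.count(False)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def precision_recall_f1(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, f1); None where a denominator is zero."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    elif precision == 0.0 or recall == 0.0:
        f1 = 0.0
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    detections: Iterable[Detection],
    truths: Iterable[Detection],
    iou_threshold: float = 0.5,
) -> float | None:
    """Area under the all-point-interpolated precision-recall curve.

    The score-ranked detection list is swept globally (across frames); each
    detection greedily claims its best-IoU unmatched truth in its frame at
    the given threshold. Precision at each recall level is replaced by the
    running maximum to its right (the precision envelope) before
    integrating. None when there is no ground truth.
    """
    truth_by_frame = _group_by_frame(truths)
    n_truth = sum(len(v) for v in truth_by_frame.values())
    if n_truth == 0:
        return None
    taken = {f: [False] * len(v) for f, v in truth_by_frame.items()}
    dets = sorted(detections, key=lambda d: -d.score)
    is_tp = np.zeros(len(dets), dtype=bool)
    for i, det in enumerate(dets):
        gts = truth_by_frame.get(det.frame, [])
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(gts):
            if taken[det.frame][j]:
                continue
            v = iou(det.box, gt.box)
            if v >= best_iou and v > 0:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[det.frame][best_j] = True
            is_tp[i] = True
    if len(dets) == 0:
        return 0.0
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then integrate over recall
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[env[0] if len(env) else 0.0], env])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def mean_ap(per_class_ap: Mapping[int, float] | Iterable[float]) -> float:
    """Arithmetic mean of per-class APs; equals AP for a single class."""
    values = list(per_class_ap.values()) if isinstance(per_class_ap, Mapping) else list(per_class_ap)
    if not values:
        raise ValueError("mean_ap requires at least one class")
    return float(np.mean(values))


def fps(total_time: float, n_frames: int) -> float:
    """Frames processed per second of wall-clock time."""
    if total_time <= 0:
        raise ValueError(f"total_time must be positive, got {total_time}")
    return n_frames / total_time


def tracking_continuity(
    tracks: Mapping[int, Mapping[int, BoundingBox]],
    truth_tracks: Mapping[int, Mapping[int, BoundingBox]],
    iou_threshold: float = 0.3,
) -> tuple[int, int]:
    """(id_switches, fragmentation) of tracker output against ground truth.

    Both arguments map identity -> {frame -> box}. Per frame, each truth box
    is associated to the best-IoU track box at or above ``iou_threshold``.
    For each truth identity, an id switch is counted whenever the matched
    track id differs from the previously matched one, and a fragmentation
    whenever coverage resumes after one or more unmatched frames inside the
    identity's lifespan.
    """
    id_switches = 0
    fragmentation = 0
    for gt_id, gt_frames in truth_tracks.items():
        last_track: int | None = None
        covered_prev = False
        started = False
        for frame in sorted(gt_frames):
            gt_box = gt_frames[frame]
            best_track, best_iou = None, iou_threshold
            for track_id, track_frames in tracks.items():
                box = track_frames.get(frame)
                if box is None:
                    continue
                v = iou(gt_box, box)
                if v >= best_iou and v > 0:
                    best_track, best_iou = track_id, v
            if best_track is not None:
                if started and not covered_prev:
                    fragmentation += 1
                if last_track is not None and best_track != last_track:
                    id_switches += 1
                last_track = best_track
                covered_prev = True
                started = True
            else:
                covered_prev = False
    return id_switches, fragmentation
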