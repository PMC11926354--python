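"""Detection/segmentation metrics: IoU, Dice, mAP50, Cohen's kappa.

The mAP implementation follows COCO API semantics — greedy matching of
predictions in descending score order, detections pooled across images,
101-point interpolated precision — so third-party COCO tooling reproduces
the numbers on exported annotation files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ArrayOrBox = "np.ndarray | tuple"


def _is_box(x) -> bool:
    return not isinstance(x, np.ndarray) and len(x) == 4


def box_intersection(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    return iw * ih


def iou(a, b) -> float:
    """Intersection over union of two masks or two half-open boxes.

    An empty union is defined to have IoU 0.
    """
    if _is_box(a) and _is_box(b):
        inter = box_intersection(a, b)
        area_a = max(0.0, a[2] - a[0]) * max(0.0, a[3] - a[1])
        area_b = max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])
        union = area_a + area_b - inter
    else:
        a = np.asarray(a, dtype=bool)
        b = np.asarray(b, dtype=bool)
        inter = float(np.count_nonzero(a & b))
        union = float(np.count_nonzero(a | b))
    return inter / union if union > 0 else 0.0


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); two empty masks -> 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    total = int(np.count_nonzero(a)) + int(np.count_nonzero(b))
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / total


@dataclass
class MatchResult:
    """Greedy score-ordered matching of predictions to ground truths."""

    tp: list = field(default_factory=list)   # (pred_idx, truth_idx, score, iou)
    fp: list = field(default_factory=list)   # (pred_idx, score)
    fn: list = field(default_factory=list)   # unmatched truth indices

    @property
    def precision(self) -> float:
        n = len(self.tp) + len(self.fp)
        return len(self.tp) / n if n else 0.0

    @property
    def recall(self) -> float:
        n = len(self.tp) + len(self.fn)
        return len(self.tp) / n if n else 0.0


def match_instances(preds, scores, truths, iou_threshold: float = 0.5) -> MatchResult:
    """Match predictions to ground truths greedily by descending score.

    Each ground truth is matched at most once; a prediction matches the
    free ground truth of highest IoU, provided IoU >= threshold.
    """
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    taken = [False] * len(truths)
    res = MatchResult()
    for pi in order:
        best_iou, best_t = 0.0, -1
        for ti, t in enumerate(truths):
            if taken[ti]:
                continue
            v = iou(preds[pi], t)
            if v > best_iou:
                best_iou, best_t = v, ti
        if best_t >= 0 and best_iou >= iou_threshold:
            taken[best_t] = True
            res.tp.append((int(pi), best_t, float(scores[pi]), best_iou))
        else:
            res.fp.append((int(pi), float(scores[pi])))
    res.fn = [ti for ti, t in enumerate(taken) if not t]
    return res


def average_precision_101(scores, is_tp, n_truth: int) -> float:
    """COCO 101-point interpolated AP from pooled scored detections."""
    if n_truth == 0:
        raise ValueError("AP undefined with no ground truths")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    tp = np.asarray(is_tp, dtype=bool)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope, then sample at 101 recall points
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    pts = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, pts, side="left")
    sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(sampled.mean())


def map50(preds_per_image, scores_per_image, truths_per_image,
          iou_threshold: float = 0.5) -> float:
    """mAP at a fixed IoU threshold, detections pooled across images.

    ``preds_per_image`` / ``truths_per_image`` are lists (one entry per
    image) of lists of masks or boxes; scores parallel the predictions.
    """
    all_scores: list[float] = []
    all_tp: list[bool] = []
    n_truth = 0
    for preds, scores, truths in zip(preds_per_image, scores_per_image,
                                     truths_per_image):
        n_truth += len(truths)
        res = match_instances(preds, scores, truths, iou_threshold)
        for _, _, s, _ in res.tp:
            all_scores.append(s)
            all_tp.append(True)
        for _, s in res.fp:
            all_scores.append(s)
            all_tp.append(False)
    if n_truth == 0:
        raise ValueError("mAP undefined with no ground truths")
    return average_precision_101(all_scores, all_tp, n_truth)


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a k x k confusion matrix of counts.

    Degenerate case: when chance agreement p_e equals 1 (all mass in one
    row-column pair), kappa is defined as 1 if observed agreement is also
    1, else 0.
    """
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(c) / n
    pe = float((c.sum(axis=0) / n) @ (c.sum(axis=1) / n))
    if abs(1.0 - pe) < 1e-15:
        return 1.0 if abs(po - 1.0) < 1e-15 else 0.0
    return (po - pe) / (1.0 - pe)
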