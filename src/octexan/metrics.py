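"""Segmentation metrics: pixel-level for the ROI, blob-level for EX-AN.

Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R) — on pixel
sets F1 coincides with the Dice similarity coefficient. Blob-level
scoring matches each predicted blob against the ground-truth mask: a
prediction is a true positive iff it overlaps the ground truth by
strictly more than the overlap threshold (default 0.30, the same rule
used to label training candidates); a ground-truth blob counts as missed
(FN) when no true-positive prediction touches it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tn: int = 0
    matched_pairs: list[tuple[int, float]] = field(default_factory=list)


def counts_to_metrics(tp: int, fp: int, fn: int) -> dict[str, float]:
    """Zero-denominator conventions: a metric is 0 when its denominator is 0
    and the other set is nonempty; all metrics are 1 when pred and gt are
    both empty."""
    if tp == 0 and fp == 0 and fn == 0:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


def pixel_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> dict[str, float]:
    """Per-pixel precision/recall/F1 of a binary mask against ground truth."""
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    return counts_to_metrics(tp, fp, fn)


def blob_metrics(pred_blobs, gt_mask: np.ndarray,
                 overlap_threshold: float = 0.30) -> tuple[MatchResult, dict[str, float]]:
    """Blob-level matching under the strict >threshold overlap rule.

    Each predicted blob is scored independently; several true positives
    may cover one ground-truth component, which is then "found" once.
    """
    if not 0.0 < overlap_threshold < 1.0:
        raise ValueError("overlap_threshold must lie in (0, 1)")
    gt = np.asarray(gt_mask, dtype=bool)
    gt_lab = cc_label(gt, connectivity=2)
    n_gt = int(gt_lab.max())
    covered = np.zeros(n_gt + 1, dtype=bool)
    tp = fp = 0
    pairs = []
    for i, blob in enumerate(pred_blobs):
        ys, xs = blob.pixel_set[:, 0], blob.pixel_set[:, 1]
        frac = float(gt[ys, xs].sum()) / blob.area
        pairs.append((i, frac))
        if frac > overlap_threshold:
            tp += 1
            covered[np.unique(gt_lab[ys, xs])] = True
        else:
            fp += 1
    fn = int(n_gt - covered[1:].sum())
    result = MatchResult(tp=tp, fp=fp, fn=fn, matched_pairs=pairs)
    return result, counts_to_metrics(tp, fp, fn)
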