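"""Detection performance against ground truth.

Matching is greedy in descending prediction score; a (truth,
prediction) pair is valid when the centroid distance is at most
max(5 px, 0.5 * r_truth) and the relative radius error is at most 25%.
Unmatched predictions count as false positives, unmatched truths as
false negatives.

For a detection task there are no true negatives, so "accuracy" is
defined here as tp / (tp + fp + fn) (the Jaccard-style intersection
over union of the detection sets); precision, recall and F1 are always
reported alongside so results are interpretable regardless of the
accuracy convention.
"""

from __future__ import annotations

import math

import numpy as np

from .types import MatchResult, ParticleRecord

__all__ = [
    "match_particles",
    "detection_metrics",
    "size_error_report",
    "subsample_image_ids",
]


def _truth_tuple(t, pixel_size: float):
    """(y_px, x_px, radius_px, diameter_nm, class_name) from a truth record."""
    if isinstance(t, ParticleRecord):
        return (t.y, t.x, t.radius_px, t.diameter_nm, t.class_name)
    # simulator ParticleTruth
    r_px = (t.diameter_nm / 2.0) / pixel_size
    return (t.y, t.x, r_px, t.diameter_nm, t.class_name)


def match_particles(predicted: list, truth: list, pixel_size: float,
                    max_center_dist_px: float = 5.0,
                    max_radius_rel_err: float = 0.25) -> MatchResult:
    """Greedily pair predictions with ground-truth particles.

    ``predicted`` are ParticleRecords (excluded ones are ignored);
    ``truth`` may be ParticleRecords or simulator ParticleTruth entries.
    ``pixel_size`` (nm/px) must refer to the grid the predictions'
    pixel coordinates live on; truths in the same grid are assumed.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    preds = [p for p in predicted if not p.excluded]
    order = sorted(range(len(preds)),
                   key=lambda i: (-preds[i].score, preds[i].y, preds[i].x))
    truths = [_truth_tuple(t, pixel_size) for t in truth]

    taken = [False] * len(truths)
    pairs = []
    errors = []
    classes = []
    for pi in order:
        p = preds[pi]
        best = None
        for ti, (ty, tx, tr, td, tc) in enumerate(truths):
            if taken[ti]:
                continue
            dist = math.hypot(p.y - ty, p.x - tx)
            if dist > max(max_center_dist_px, 0.5 * tr):
                continue
            if tr > 0 and abs(p.radius_px - tr) / tr > max_radius_rel_err:
                continue
            if best is None or dist < best[0]:
                best = (dist, ti)
        if best is not None:
            ti = best[1]
            taken[ti] = True
            pairs.append((ti, pi))
            errors.append(p.diameter_nm - truths[ti][3])
            classes.append(truths[ti][4])
    tp = len(pairs)
    return MatchResult(pairs=pairs, tp=tp, fp=len(preds) - tp,
                       fn=len(truths) - tp,
                       diameter_errors=np.array(errors, dtype=np.float64),
                       truth_classes=classes)


def detection_metrics(match: MatchResult) -> dict:
    """Precision, recall, F1 and set-level accuracy from a match result.

    All-zero counts give a flagged 'undefined' result rather than NaNs.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp + fn == 0:
        return {"precision": None, "recall": None, "f1": None,
                "accuracy": None, "defined": False}
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision and recall:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == 0 or recall == 0:
        f1 = 0.0
    else:
        f1 = None
    accuracy = tp / (tp + fp + fn)
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy, "defined": True,
            "tp": tp, "fp": fp, "fn": fn}


def size_error_report(match: MatchResult) -> dict:
    """Per-class and overall bias (mean predicted - true) and RMSE of the
    matched diameters, in nm."""
    if match.tp < 1:
        raise ValueError("need at least one matched pair")
    errs = match.diameter_errors
    report = {"overall": {"bias_nm": float(errs.mean()),
                          "rmse_nm": float(np.sqrt((errs**2).mean())),
                          "n": int(len(errs))}}
    classes = match.truth_classes or []
    for c in sorted(set(classes)):
        e = errs[[i for i, cc in enumerate(classes) if cc == c]]
        report[c] = {"bias_nm": float(e.mean()),
                     "rmse_nm": float(np.sqrt((e**2).mean())),
                     "n": int(len(e))}
    return report


def subsample_image_ids(image_ids: list, fraction: float, seed: int) -> list:
    """Seeded random subset of images for inspection-style evaluation
    (the protocol of spot-checking a few percent of a large dataset)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * len(image_ids))))
    idx = rng.choice(len(image_ids), size=n, replace=False)
    return [image_ids[i] for i in sorted(idx)]
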