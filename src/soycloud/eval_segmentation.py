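"""Scoring of individual-plant segmentation against ground truth.

Predicted instances are matched one-to-one to true plants greedily by
descending point overlap.  A true plant is *truly segmented* when its
matched prediction covers more than half of the plant's points **and** the
plant contributes more than half of the prediction's points (dual-majority
rule).  A prediction fed by two or more plants, each contributing more than
30% of its points, marks those plants *merged*; everything else unmatched is
*missed*.

Plot-level accuracy A is the fraction of plants truly segmented.  Point-level
precision/recall/F1 are computed per truly-segmented plant from the matched
prediction's point counts (TPC true, FPC foreign, FNC missing points).
Method comparison uses paired two-sided t-tests per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .segment import SegmentationResult

__all__ = [
    "MatchResult",
    "match_instances",
    "plot_accuracy",
    "point_prf",
    "compare_methods",
]


@dataclass
class MatchResult:
    """Outcome of matching predicted instances to true plants."""

    mapping: dict[int, int]        # predicted instance -> true plant (injective)
    status: dict[int, str]         # true plant -> truly_segmented | merged | missed
    counts: dict[int, tuple[int, int, int]]  # true plant -> (TPC, FPC, FNC)
    n_true: int
    n_pred: int


def match_instances(
    pred: SegmentationResult | np.ndarray, truth: np.ndarray
) -> MatchResult:
    """Match predicted instances against true instance labels.

    ``truth`` uses -1 for non-plant points (they can only contribute FPC).
    """
    pred_labels = (
        pred.instance_label if isinstance(pred, SegmentationResult) else np.asarray(pred)
    )
    truth = np.asarray(truth)
    if pred_labels.shape != truth.shape:
        raise ValueError(
            f"label arrays differ in length: {pred_labels.shape} vs {truth.shape}"
        )
    true_ids = np.unique(truth[truth >= 0])
    pred_ids = np.unique(pred_labels[pred_labels >= 0])
    true_sizes = {int(t): int(np.count_nonzero(truth == t)) for t in true_ids}
    pred_sizes = {int(p): int(np.count_nonzero(pred_labels == p)) for p in pred_ids}

    # overlap contingency over plant points only
    overlaps: dict[tuple[int, int], int] = {}
    mask = (truth >= 0) & (pred_labels >= 0)
    if mask.any():
        pair = truth[mask].astype(np.int64) * (pred_labels.max() + 1) + pred_labels[mask]
        vals, cnts = np.unique(pair, return_counts=True)
        for v, c in zip(vals, cnts):
            t = int(v // (pred_labels.max() + 1))
            p = int(v % (pred_labels.max() + 1))
            overlaps[(t, p)] = int(c)

    # greedy one-to-one matching by descending overlap (ties: lowest ids)
    order = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping: dict[int, int] = {}
    matched_true: set[int] = set()
    for (t, p), _ in order:
        if p not in mapping and t not in matched_true:
            mapping[p] = t
            matched_true.add(t)

    status: dict[int, str] = {}
    counts: dict[int, tuple[int, int, int]] = {}
    inv = {t: p for p, t in mapping.items()}
    for t in (int(v) for v in true_ids):
        p = inv.get(t)
        if p is None:
            status[t] = "missed"
            counts[t] = (0, 0, true_sizes[t])
            continue
        tpc = overlaps.get((t, p), 0)
        fpc = pred_sizes[p] - tpc
        fnc = true_sizes[t] - tpc
        counts[t] = (tpc, fpc, fnc)
        if tpc > 0.5 * true_sizes[t] and tpc > 0.5 * pred_sizes[p]:
            status[t] = "truly_segmented"
        else:
            status[t] = "missed"

    # merge detection: a prediction fed >30% by each of >= 2 plants
    for p in (int(v) for v in pred_ids):
        feeders = [
            t
            for t in (int(v) for v in true_ids)
            if overlaps.get((t, p), 0) > 0.3 * pred_sizes[p]
        ]
        if len(feeders) >= 2:
            for t in feeders:
                status[t] = "merged"
    return MatchResult(
        mapping=mapping,
        status=status,
        counts=counts,
        n_true=len(true_ids),
        n_pred=len(pred_ids),
    )


def plot_accuracy(match: MatchResult) -> float:
    """A = (# truly segmented plants) / (# true plants)."""
    if match.n_true == 0:
        raise ValueError("no true plants to score")
    n_ok = sum(1 for s in match.status.values() if s == "truly_segmented")
    return n_ok / match.n_true


def point_prf(match: MatchResult) -> tuple[dict[int, tuple[float, float, float]], tuple[float, float, float]]:
    """Per-plant (P, R, F1) over truly segmented plants, plus their means.

    Zero denominators yield metric 0.  Returns ``({plant: (P, R, F1)},
    (mean_P, mean_R, mean_F1))``; means are nan when no plant qualifies.
    """
    per_plant: dict[int, tuple[float, float, float]] = {}
    for t, s in match.status.items():
        if s != "truly_segmented":
            continue
        tpc, fpc, fnc = match.counts[t]
        p = tpc / (tpc + fpc) if tpc + fpc else 0.0
        r = tpc / (tpc + fnc) if tpc + fnc else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        per_plant[t] = (p, r, f1)
    if per_plant:
        arr = np.array(list(per_plant.values()))
        means = tuple(arr.mean(axis=0))
    else:
        means = (float("nan"),) * 3
    return per_plant, means


def compare_methods(
    scores_a: np.ndarray | dict[str, np.ndarray],
    scores_b: np.ndarray | dict[str, np.ndarray] | None = None,
) -> dict:
    """Paired two-sided t-test(s) between per-plant metric lists.

    Accepts either two arrays (one metric) or two dicts of metric name ->
    array.  Zero-variance differences give a missing p-value.  Each result
    carries ``significant`` at the 0.05 level.
    """
    if isinstance(scores_a, dict):
        if not isinstance(scores_b, dict):
            raise ValueError("both sides must be dicts of metric arrays")
        return {m: compare_methods(scores_a[m], scores_b[m]) for m in scores_a}
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired scores per side")
    diff = a - b
    if np.std(diff, ddof=1) < 1e-15:
        if np.allclose(diff, 0):
            return {"t": 0.0, "p": 1.0, "significant": False}
        return {"t": float("inf"), "p": None, "significant": False}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < 0.05)}
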