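"""Image-level evaluation: confusion counts, precision/recall/accuracy,
11-point interpolated average precision, F1, best-F thresholding, errors at
100% recall, repeated k-fold cross-validation and the positive-sample-count
sensitivity sweep.

Positive samples are images with visible defects. A score at or above the
threshold predicts defective (ties inclusive). The 11-point AP averages, over
recall levels r in {0.0, 0.1, ..., 1.0}, the maximum precision among
operating points whose recall is >= r.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold


class InputError(ValueError):
    pass


class UndefinedRateError(ZeroDivisionError):
    pass


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    ap: float
    f1: float
    best_f_threshold: float
    fp_at_best_f: int
    fn_at_best_f: int
    fp_at_full_recall: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0 or scores.shape != labels.shape:
        raise InputError("scores and labels must be equal-length and nonempty")
    return scores, labels


def confusion(scores: Sequence[float], labels: Sequence[int],
              threshold: float) -> ConfusionCounts:
    """Counts at one threshold; score >= threshold predicts defective."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def basic_rates(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, recall); zero denominators raise rather than
    silently returning 0."""
    if c.total == 0:
        raise UndefinedRateError("accuracy undefined: no samples")
    accuracy = (c.TP + c.TN) / c.total
    if c.TP + c.FP == 0:
        raise UndefinedRateError("precision undefined: no positive predictions")
    precision = c.TP / (c.TP + c.FP)
    if c.TP + c.FN == 0:
        raise UndefinedRateError("recall undefined: no positive samples")
    recall = c.TP / (c.TP + c.FN)
    return accuracy, precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean; (0, 0) is defined as 0."""
    if precision + recall == 0:
        import warnings

        warnings.warn("F1 of (0, 0) defined as 0", stacklevel=2)
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _pr_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float, float]]:
    """(threshold, precision, recall) at every distinct score cutoff."""
    points = []
    n_pos = int(np.sum(labels == 1))
    for t in np.unique(scores):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        if tp + fp == 0:
            continue
        points.append((float(t), tp / (tp + fp), tp / n_pos))
    return points


def ap_11point(scores: Sequence[float], labels: Sequence[int]) -> float:
    """11-point interpolated average precision."""
    scores, labels = _validate(scores, labels)
    if np.sum(labels == 1) == 0:
        raise InputError("average precision undefined without positive samples")
    points = _pr_points(scores, labels)
    total = 0.0
    for r in np.linspace(0.0, 1.0, 11):
        eligible = [p for (_, p, rec) in points if rec >= r - 1e-12]
        total += max(eligible) if eligible else 0.0
    return total / 11.0


def best_f_threshold(scores: Sequence[float], labels: Sequence[int]
                     ) -> tuple[float, ConfusionCounts]:
    """Distinct-score threshold maximizing F1 (ties -> lowest threshold),
    with the confusion counts there."""
    scores, labels = _validate(scores, labels)
    if np.sum(labels == 1) == 0 or np.sum(labels == 0) == 0:
        raise InputError("best-F threshold needs both classes present")
    best = None
    for t in np.unique(scores):  # ascending, so ties keep the lowest t
        c = confusion(scores, labels, float(t))
        if c.TP + c.FP == 0:
            continue
        prec = c.TP / (c.TP + c.FP)
        rec = c.TP / (c.TP + c.FN)
        score_f = f1(prec, rec) if prec + rec > 0 else 0.0
        if best is None or score_f > best[0] + 1e-12:
            best = (score_f, float(t), c)
    assert best is not None
    return best[1], best[2]


def errors_at_full_recall(scores: Sequence[float], labels: Sequence[int]) -> int:
    """False-positive count at the highest threshold that still reaches
    recall 1 (the minimum positive score under the >= comparator), i.e. the
    fewest errors compatible with 100% recall."""
    scores, labels = _validate(scores, labels)
    pos = scores[labels == 1]
    if pos.size == 0:
        raise InputError("full recall undefined without positive samples")
    t = float(pos.min())
    return confusion(scores, labels, t).FP


def evaluate_scores(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.5) -> MetricsReport:
    """Full image-level report. Plain accuracy/precision/recall use the
    softmax argmax threshold 0.5; AP, best-F and full-recall statistics sweep
    all distinct thresholds."""
    scores, labels = _validate(scores, labels)
    c = confusion(scores, labels, threshold)
    accuracy = (c.TP + c.TN) / c.total
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP else float("nan")
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else float("nan")
    ap = ap_11point(scores, labels)
    t_best, c_best = best_f_threshold(scores, labels)
    prec_b = c_best.TP / (c_best.TP + c_best.FP)
    rec_b = c_best.TP / (c_best.TP + c_best.FN)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        ap=ap,
        f1=f1(prec_b, rec_b),
        best_f_threshold=t_best,
        fp_at_best_f=c_best.FP,
        fn_at_best_f=c_best.FN,
        fp_at_full_recall=errors_at_full_recall(scores, labels),
    )


# ---------------------------------------------------------------------------
# experiment harnesses


def kfold_cv(labels: Sequence[int],
             run_fold: Callable[[np.ndarray, np.ndarray, int], float],
             k: int = 10, repeats: int = 10, seed: int = 0) -> dict:
    """Repeated k-fold cross-validation with a fresh random split per repeat.

    ``run_fold(train_idx, test_idx, fold_seed)`` trains a fresh model and
    returns the fold's metric. Records the best fold metric per repeat and
    the grand mean of those best values.
    """
    labels = np.asarray(labels)
    n_def = int(np.sum(labels == 1))
    if n_def < k:
        raise InputError(f"k-fold needs at least k={k} defective images "
                         f"(got {n_def}) so every training split can sample")
    per_repeat = []
    all_folds = []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        fold_metrics = []
        for fold, (train_idx, test_idx) in enumerate(kf.split(labels)):
            if np.sum(labels[train_idx] == 1) == 0 or np.sum(labels[test_idx] == 1) == 0:
                continue  # a fold without positives cannot be scored
            fold_metrics.append(run_fold(train_idx, test_idx,
                                         seed * 10_000 + rep * 100 + fold))
        per_repeat.append(max(fold_metrics))
        all_folds.append(fold_metrics)
    return {
        "per_repeat_best": per_repeat,
        "mean_of_best": float(np.mean(per_repeat)),
        "folds": all_folds,
    }


def sensitivity_sweep(labels: Sequence[int], positive_counts: Sequence[int],
                      run_subset: Callable[[np.ndarray, int], float],
                      seed: int = 0) -> dict[int, float]:
    """Retrain with randomly subsampled defective training images.

    ``run_subset(train_indices, run_seed)`` trains from scratch on the given
    training indices (the test split is fixed by the caller) and returns the
    metric. Returns {positive_count: metric}.
    """
    labels = np.asarray(labels)
    defective = np.flatnonzero(labels == 1)
    normal = np.flatnonzero(labels == 0)
    if max(positive_counts) > defective.size:
        raise InputError("positive count exceeds available defective images")
    rng = np.random.default_rng(seed)
    results = {}
    for count in positive_counts:
        keep = rng.choice(defective, size=count, replace=False)
        train_idx = np.sort(np.concatenate([keep, normal]))
        results[int(count)] = run_subset(train_idx, seed + count)
    return results
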