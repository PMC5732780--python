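"""Evaluation: LOOCV over known interactions and the metric suite.

Each known positive pair is held out in turn (jackknife), the model is
retrained on the remaining positives with a fold-specific seed, and the
held-out pair is scored with the smoothed predictor.  Unknown (zero) pairs
form the negative background; they are scored once by the model trained on
all positives.  AUC and AUPR are computed over held-out-positive scores
versus background scores; threshold metrics (ACC/SEN/PRE/F1) are reported
at the F1-maximizing threshold unless one is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .exceptions import InputError
from .kernels import SimilarityMatrix
from .model import Hyperparameters, InteractionMatrix, LatentModel, fit, predict

#: iterations used per fold by the warm-start fast LOOCV mode
FAST_LOOCV_ITERS = 10


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise InputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class ThresholdMetrics:
    ACC: float
    SEN: float
    PRE: float
    F1: float
    undefined: list[str] = field(default_factory=list)


@dataclass
class EvaluationReport:
    pair_scores: list[tuple[str, str, int, float]]
    auc: float
    aupr: float
    threshold: float
    metrics: ThresholdMetrics
    counts: ConfusionCounts
    roc_points: np.ndarray  # columns: FPR, TPR
    pr_points: np.ndarray  # columns: recall, precision
    n_folds: int


def binary_metrics(counts: ConfusionCounts) -> ThresholdMetrics:
    """ACC, SEN (recall), PRE (precision), F1 from a confusion table.

    A ratio with zero denominator (e.g. PRE with no positive predictions)
    is reported as 0 and flagged in ``undefined`` rather than NaN.
    """
    if counts.total == 0:
        raise InputError("confusion table is empty")
    undefined = []
    acc = (counts.TP + counts.TN) / counts.total
    if counts.TP + counts.FN > 0:
        sen = counts.TP / (counts.TP + counts.FN)
    else:
        sen = 0.0
        undefined.append("SEN")
    if counts.TP + counts.FP > 0:
        pre = counts.TP / (counts.TP + counts.FP)
    else:
        pre = 0.0
        undefined.append("PRE")
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom > 0:
        f1 = 2 * counts.TP / denom
    else:
        f1 = 0.0
        undefined.append("F1")
    if undefined:
        warnings.warn(f"metrics with zero denominator reported as 0: {undefined}")
    return ThresholdMetrics(ACC=acc, SEN=sen, PRE=pre, F1=f1, undefined=undefined)


def _check_labels_scores(labels, scores):
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise InputError("labels and scores must be 1-D and the same length")
    if not np.isin(labels, (0, 1)).all():
        raise InputError("labels must be binary")
    return labels, scores


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUC: probability a random positive outscores a random negative,
    ties counted 1/2 (equals trapezoidal area under the ROC curve)."""
    labels, scores = _check_labels_scores(labels, scores)
    if labels.min() == labels.max():
        raise InputError("AUC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, scores))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve, step-wise non-interpolated
    rule over descending score thresholds."""
    labels, scores = _check_labels_scores(labels, scores)
    if labels.sum() == 0:
        raise InputError("AUPR needs at least one positive label")
    return float(average_precision_score(labels, scores))


def confusion_at_threshold(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> ConfusionCounts:
    """Counts with prediction rule: score >= threshold -> positive."""
    labels, scores = _check_labels_scores(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int((pred & pos).sum()),
        FP=int((pred & ~pos).sum()),
        TN=int((~pred & ~pos).sum()),
        FN=int((~pred & pos).sum()),
    )


def f1_maximizing_threshold(labels, scores) -> float:
    """The score threshold maximizing F1 under the >= prediction rule."""
    labels, scores = _check_labels_scores(labels, scores)
    candidates = np.unique(scores)
    best_thr, best_f1 = candidates[0], -1.0
    pos = labels == 1
    for thr in candidates:
        pred = scores >= thr
        tp = int((pred & pos).sum())
        denom = 2 * tp + int((pred & ~pos).sum()) + int((~pred & pos).sum())
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1:
            best_thr, best_f1 = thr, f1
    return float(best_thr)


def fold_seed(base_seed: int, fold: int) -> int:
    """Deterministic per-fold seed: counter scheme through SeedSequence,
    kept below 2**31.  Counter 0 is reserved for the background
    (all-positives) model; fold k uses counter k+1."""
    if fold < 0:
        raise InputError("fold counter must be nonnegative")
    return int(
        np.random.SeedSequence([abs(int(base_seed)), int(fold)]).generate_state(1)[0]
        % (2**31)
    )


def evaluate_scores(
    pair_scores: list[tuple[str, str, int, float]],
    threshold: Optional[float] = None,
    n_folds: int = 0,
) -> EvaluationReport:
    """Build a full report (AUC, AUPR, curves, threshold metrics) from
    labelled per-pair scores."""
    labels = np.array([p[2] for p in pair_scores], dtype=int)
    scores = np.array([p[3] for p in pair_scores], dtype=float)
    auc_val = roc_auc(labels, scores)
    aupr_val = aupr(labels, scores)
    if threshold is None:
        threshold = f1_maximizing_threshold(labels, scores)
    counts = confusion_at_threshold(labels, scores, threshold)
    metrics = binary_metrics(counts)
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return EvaluationReport(
        pair_scores=pair_scores,
        auc=auc_val,
        aupr=aupr_val,
        threshold=float(threshold),
        metrics=metrics,
        counts=counts,
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        n_folds=n_folds,
    )


def loocv(
    Y: InteractionMatrix,
    S_l: SimilarityMatrix,
    S_p: SimilarityMatrix,
    hp: Hyperparameters,
    fast: bool = False,
    threshold: Optional[float] = None,
) -> EvaluationReport:
    """Leave-one-out cross-validation over the known positives.

    One fold per known positive: that entry is zeroed, the model retrained
    (seeded deterministically per fold), and the held-out pair's smoothed
    score recorded.  ``fast=True`` warm-starts each fold from the
    all-positives model and runs only a few iterations.  The report is
    fully determined by the inputs and ``hp.seed``.
    """
    positives = Y.positive_pairs()
    if len(positives) < 2:
        raise InputError("LOOCV needs at least 2 known positives")

    full_model = fit(Y, S_l, S_p, replace(hp, seed=fold_seed(hp.seed, 0)))
    background = predict(full_model, Y).values

    pair_scores: list[tuple[str, str, int, float]] = []
    for i, j in np.argwhere(Y.Y == 0):
        pair_scores.append(
            (Y.lncrna_ids[i], Y.protein_ids[j], 0, float(background[i, j]))
        )

    for k, (i, j) in enumerate(positives):
        Y_fold = InteractionMatrix(
            lncrna_ids=Y.lncrna_ids, protein_ids=Y.protein_ids, Y=Y.Y.copy()
        )
        Y_fold.Y[i, j] = 0.0
        hp_fold = replace(hp, seed=fold_seed(hp.seed, k + 1))
        if fast:
            hp_fold = replace(hp_fold, max_iters=FAST_LOOCV_ITERS)
            model = fit(
                Y_fold, S_l, S_p, hp_fold, init=(full_model.U, full_model.V)
            )
        else:
            model = fit(Y_fold, S_l, S_p, hp_fold)
        score = predict(model, Y_fold).values[i, j]
        pair_scores.append((Y.lncrna_ids[i], Y.protein_ids[j], 1, float(score)))

    return evaluate_scores(pair_scores, threshold=threshold, n_folds=len(positives))
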