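"""Ranking metrics and the cross-validation protocols.

AUC and AUPR are computed from an explicit threshold sweep: every distinct
score is a threshold, tied scores are grouped (equivalent to midrank
handling), ROC area uses the trapezoid rule and PR area the conservative
rectangular recall-step rule with the curve anchored at recall 0.

Two protocols evaluate link prediction:

* five-fold cross-validation partitions *all* disease-miRNA pairs (positives
  and negatives together) into folds; per fold, the test positives are
  zeroed in the training matrix, the GIP kernels and the WKNKN completion
  are recomputed from the masked matrix (no leakage), the pipeline is
  re-run and the metrics are taken over the held-out pairs;
* global leave-one-out masks each known association in turn and records its
  score, with the never-known pairs scored once by the full-data model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, PipelineParams, SimilarityMatrix
from .errors import InputError
from .pipeline import score_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "CvReport",
    "roc_auc",
    "pr_aupr",
    "evaluate_scores",
    "degree_product_scores",
    "pair_folds",
    "five_fold_cv",
    "global_loocv",
]


@dataclass
class EvalResult:
    auc: float
    aupr: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int


@dataclass
class CvReport:
    """Per-fold and aggregated cross-validation metrics."""

    fold_auc: list[float]
    fold_aupr: list[float]
    pooled_auc: list[float]
    pooled_aupr: list[float]
    mean_auc: float
    sd_auc: float
    mean_aupr: float
    sd_aupr: float
    skipped_folds: list[tuple[int, int]]
    n_folds: int
    n_repeats: int
    seed: int


def _sweep(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if scores.shape != labels.shape or scores.size == 0:
        raise InputError("scores and labels must be equal-length and non-empty")
    if not np.all((labels == 0) | (labels == 1)):
        raise InputError("labels must be binary")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # last index of every tied-score group
    last = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tp = np.cumsum(y)[last]
    fp = np.cumsum(1.0 - y)[last]
    return tp, fp, float(labels.sum()), float(labels.size - labels.sum())


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """Trapezoid ROC area over the threshold sweep; returns (auc, points)."""
    tp, fp, n_pos, n_neg = _sweep(scores, labels)
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC-AUC is undefined without both classes")
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def pr_aupr(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """Rectangular (recall-step) PR area; returns (aupr, points).

    The curve is anchored at recall 0 with the first attainable precision;
    each recall increment contributes its right-endpoint precision.
    """
    tp, fp, n_pos, _ = _sweep(scores, labels)
    if n_pos == 0:
        raise InputError("AUPR is undefined without positives")
    recall = tp / n_pos
    precision = tp / (tp + fp)
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    points = [(0.0, float(precision[0]))] + list(
        zip(recall.tolist(), precision.tolist())
    )
    return aupr, points


def evaluate_scores(scores, labels) -> EvalResult:
    auc, roc_points = roc_auc(scores, labels)
    aupr, pr_points = pr_aupr(scores, labels)
    labels = np.asarray(labels).ravel()
    n_pos = int(labels.sum())
    return EvalResult(auc, aupr, roc_points, pr_points, n_pos, labels.size - n_pos)


def degree_product_scores(A: AssociationMatrix) -> np.ndarray:
    """Degree-product link-prediction baseline (outer product of degrees)."""
    return np.outer(A.disease_degrees(), A.mirna_degrees())


def pair_folds(n_pairs: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of pair indices into folds whose sizes differ by <= 1."""
    return np.array_split(rng.permutation(n_pairs), n_folds)


def five_fold_cv(
    A: AssociationMatrix,
    DSS: SimilarityMatrix,
    MFS: SimilarityMatrix,
    params: PipelineParams | None = None,
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    use_wknkn: bool = True,
    score_fn=None,
) -> CvReport:
    """Repeated k-fold cross-validation over all disease-miRNA pairs.

    ``score_fn(A_train) -> score matrix`` overrides the pipeline scorer so
    baselines and ablations can be evaluated on exactly the same seeded
    folds.  Folds with a single class in the test pairs are skipped with a
    warning and recorded in the report.
    """
    params = params or PipelineParams()
    if A.values.sum() < n_folds:
        raise InputError(f"need at least {n_folds} positives for {n_folds}-fold CV")
    if score_fn is None:
        def score_fn(A_train):
            return score_pairs(A_train, DSS, MFS, params, use_wknkn=use_wknkn).scores

    rng = np.random.default_rng(seed)
    n_d, n_m = A.values.shape
    fold_auc: list[float] = []
    fold_aupr: list[float] = []
    pooled_auc: list[float] = []
    pooled_aupr: list[float] = []
    skipped: list[tuple[int, int]] = []

    for rep in range(n_repeats):
        folds = pair_folds(n_d * n_m, n_folds, rng)
        rep_scores: list[np.ndarray] = []
        rep_labels: list[np.ndarray] = []
        for f, test_idx in enumerate(folds):
            test_mask = np.zeros(n_d * n_m, dtype=bool)
            test_mask[test_idx] = True
            test_mask = test_mask.reshape(n_d, n_m)
            train_values = np.where(test_mask, 0.0, A.values)
            if train_values.sum() == 0:
                logger.warning("repeat %d fold %d: empty training matrix, skipped", rep, f)
                skipped.append((rep, f))
                continue
            A_train = AssociationMatrix(
                train_values, list(A.disease_ids), list(A.mirna_ids)
            )
            scores = np.asarray(score_fn(A_train), dtype=float)
            t_scores = scores[test_mask]
            t_labels = A.values[test_mask]
            if t_labels.sum() == 0 or t_labels.sum() == t_labels.size:
                logger.warning("repeat %d fold %d: single-class test fold, skipped", rep, f)
                skipped.append((rep, f))
                continue
            auc, _ = roc_auc(t_scores, t_labels)
            aupr, _ = pr_aupr(t_scores, t_labels)
            fold_auc.append(auc)
            fold_aupr.append(aupr)
            rep_scores.append(t_scores)
            rep_labels.append(t_labels)
        if rep_scores:
            s = np.concatenate(rep_scores)
            y = np.concatenate(rep_labels)
            pooled_auc.append(roc_auc(s, y)[0])
            pooled_aupr.append(pr_aupr(s, y)[0])

    if not fold_auc:
        raise InputError("every fold was skipped; no metrics to report")
    return CvReport(
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        pooled_auc=pooled_auc,
        pooled_aupr=pooled_aupr,
        mean_auc=float(np.mean(fold_auc)),
        sd_auc=float(np.std(fold_auc, ddof=1)) if len(fold_auc) > 1 else 0.0,
        mean_aupr=float(np.mean(fold_aupr)),
        sd_aupr=float(np.std(fold_aupr, ddof=1)) if len(fold_aupr) > 1 else 0.0,
        skipped_folds=skipped,
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )


def global_loocv(
    A: AssociationMatrix,
    DSS: SimilarityMatrix,
    MFS: SimilarityMatrix,
    params: PipelineParams | None = None,
    use_wknkn: bool = True,
) -> EvalResult:
    """Leave-one-association-out evaluation over all known pairs.

    Each known pair is masked and rescored by a full pipeline re-run; the
    never-known pairs are scored once by the full-data model and serve as
    the negative pool.
    """
    params = params or PipelineParams()
    pos = np.argwhere(A.values == 1)
    if len(pos) < 2:
        raise InputError("need at least 2 positives for leave-one-out")
    full = score_pairs(A, DSS, MFS, params, use_wknkn=use_wknkn).scores
    neg_mask = A.values == 0
    pos_scores = np.empty(len(pos))
    for k, (i, j) in enumerate(pos):
        masked = A.values.copy()
        masked[i, j] = 0.0
        A_masked = AssociationMatrix(masked, list(A.disease_ids), list(A.mirna_ids))
        pos_scores[k] = score_pairs(A_masked, DSS, MFS, params, use_wknkn=use_wknkn).scores[i, j]
    scores = np.concatenate([pos_scores, full[neg_mask]])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(int(neg_mask.sum()))])
    return evaluate_scores(scores, labels)
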