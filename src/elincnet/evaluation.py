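"""Model evaluation: ROC / precision-recall curves and 10-fold CV.

The ROC curve sweeps thresholds over the distinct scores, plotting the true
positive rate against the false positive rate; its AUC is computed by the
trapezoid rule, which equals the Mann-Whitney rank statistic
P(score+ > score-) + 0.5 * P(tie). The PR curve plots precision against
recall; its AUC uses step-wise interpolation (sum of recall increments
times the precision reached there). Accuracy uses the sign rule: score > 0
predicts the elincRNA class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import regnet

POSITIVE = "elinc"


@dataclass
class EvalResult:
    accuracy: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auc_roc: float
    auc_pr: float
    confusion: dict[str, int]  # TP / FP / TN / FN

    @property
    def n(self) -> int:
        return sum(self.confusion.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "auc_roc", "auc_pr", "TP", "FP", "TN", "FN"],
                "value": [
                    self.accuracy,
                    self.auc_roc,
                    self.auc_pr,
                    *[self.confusion[k] for k in ("TP", "FP", "TN", "FN")],
                ],
            }
        )


def _binary(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if l == POSITIVE else 0 for l in labels], dtype=int)


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) points over the threshold sweep and the trapezoid AUC."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # process tied scores as a block
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


def pr_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """(recall, precision) points and step-interpolated AUC."""
    y = _binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = []
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        points.append((tp / n_pos, tp / (tp + fp)))
        i = j
    auc = 0.0
    prev_recall = 0.0
    for recall, precision in points:
        auc += (recall - prev_recall) * precision
        prev_recall = recall
    return points, float(auc)


def confusion_counts(scores: Sequence[float], labels: Sequence[str]) -> dict[str, int]:
    y = _binary(labels)
    pred = (np.asarray(scores, dtype=float) > 0).astype(int)
    return {
        "TP": int(np.sum((pred == 1) & (y == 1))),
        "FP": int(np.sum((pred == 1) & (y == 0))),
        "TN": int(np.sum((pred == 0) & (y == 0))),
        "FN": int(np.sum((pred == 0) & (y == 1))),
    }


def evaluate_scores(scores: Sequence[float], labels: Sequence[str]) -> EvalResult:
    roc_pts, a_roc = roc_auc(scores, labels)
    pr_pts, a_pr = pr_auc(scores, labels)
    conf = confusion_counts(scores, labels)
    acc = (conf["TP"] + conf["TN"]) / sum(conf.values())
    return EvalResult(acc, roc_pts, pr_pts, a_roc, a_pr, conf)


def cross_validate(
    X,
    y_labels: Sequence[str],
    fit_config: Mapping | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[EvalResult, list[EvalResult]]:
    """Stratified k-fold CV of the regularized regression classifier.

    For each fold, lambda (and alpha, when ``fit_config['alpha']`` is
    ``'auto'``) is selected by inner CV on the training portion only; the
    held-out transcripts are scored by that fold's model. Out-of-fold scores
    are pooled for the overall metrics; per-fold results are also returned.
    """
    cfg = dict(fit_config or {})
    alpha = cfg.pop("alpha", "auto")
    alphas = cfg.pop("alphas", (0.0, 0.25, 0.5, 0.75, 1.0))
    inner_k = cfg.pop("inner_k", min(k, 10))
    n_lambda = cfg.pop("n_lambda", 100)

    Xarr, _ = regnet._as_matrix(X)
    y = regnet.response_vector(y_labels)
    if len(y) < k:
        raise ValueError(f"need at least k={k} observations, got {len(y)}")
    folds = regnet._stratified_folds(y, k, seed)

    pooled_scores = np.empty(len(y))
    per_fold = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model, _ = regnet.train(
            Xarr[train_mask],
            y[train_mask],
            alpha=alpha,
            alphas=alphas,
            k=inner_k,
            n_lambda=n_lambda,
            seed=seed + 1 + f,
            **cfg,
        )
        fold_scores = model.beta0 + Xarr[test_idx] @ model.betas.to_numpy()
        pooled_scores[test_idx] = fold_scores
        fold_labels = [y_labels[i] for i in test_idx]
        if len(set(fold_labels)) == 2:
            per_fold.append(evaluate_scores(fold_scores, fold_labels))
    pooled = evaluate_scores(pooled_scores, list(y_labels))
    return pooled, per_fold


def write_metrics_tsv(result: EvalResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_curve_points(result: EvalResult, roc_path, pr_path) -> None:
    pd.DataFrame(result.roc_points, columns=["fpr", "tpr"]).to_csv(roc_path, index=False)
    pd.DataFrame(result.pr_points, columns=["recall", "precision"]).to_csv(
        pr_path, index=False
    )
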