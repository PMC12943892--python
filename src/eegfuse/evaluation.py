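"""Leave-one-subject-out evaluation and the classification metric suite.

Metrics are computed from confusion-count matrices by their definitions:
accuracy (trace over total), the generalized multiclass Matthews
correlation coefficient (R_k statistic), and macro-averaged F1. A paired
two-sided t-test compares per-fold scores of two systems. The LOSO driver
holds out each subject once, audits that no held-out trial leaks into
training, and reports per-fold and aggregate metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .attention import EmotionNet, TrainConfig, predict, train_model

__all__ = ["FoldResult", "loso_folds", "confusion_counts", "metrics",
           "paired_t_test", "run_loso"]

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    """One held-out subject's outcome (metrics as fractions in [0, 1])."""

    subject_id: int
    confusion: np.ndarray
    accuracy: float
    mcc: float
    f1_macro: float

    def as_percent(self) -> dict[str, float]:
        return {"accuracy": 100.0 * self.accuracy,
                "mcc": 100.0 * self.mcc,
                "f1": 100.0 * self.f1_macro}


def loso_folds(subject_ids: np.ndarray) -> list[tuple[list[int], int]]:
    """One (train subjects, test subject) pair per distinct subject."""
    subjects = sorted(set(int(s) for s in np.asarray(subject_ids).ravel()))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != held], held) for held in subjects]


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """C x C count matrix, rows = true class, columns = predicted class."""
    c = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true, int), np.asarray(y_pred, int)):
        c[t, p] += 1
    return c


def metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, MCC, macro-F1) from a confusion-count matrix.

    MCC uses the generalized R_k formula
        (s c - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    with c the diagonal sum, s the total, t_k/p_k the true/predicted
    marginals; a zero denominator yields 0. Macro-F1 averages per-class F1
    with classes lacking both instances and predictions contributing 0
    (logged).
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(conf < 0):
        raise ValueError("confusion counts must be non-negative")
    total = conf.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")

    correct = np.trace(conf)
    accuracy = correct / total

    t_k = conf.sum(axis=1)   # true-class marginals
    p_k = conf.sum(axis=0)   # predicted-class marginals
    cov = correct * total - float(t_k @ p_k)
    denom = np.sqrt(max(total**2 - float(p_k @ p_k), 0.0)) * np.sqrt(
        max(total**2 - float(t_k @ t_k), 0.0))
    mcc = cov / denom if denom > 0 else 0.0

    f1s = []
    for c in range(conf.shape[0]):
        tp = conf[c, c]
        denom_f1 = 2 * tp + (t_k[c] - tp) + (p_k[c] - tp)
        if denom_f1 == 0:
            logger.info("class %d has no instances and no predictions; F1=0", c)
            f1s.append(0.0)
        else:
            f1s.append(2 * tp / denom_f1)
    return float(accuracy), float(mcc), float(np.mean(f1s))


def paired_t_test(scores_a: np.ndarray, scores_b: np.ndarray
                  ) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise score differences."""
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length score vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def run_loso(features: np.ndarray, labels: np.ndarray,
             subject_ids: np.ndarray,
             train_config: TrainConfig = TrainConfig(),
             n_classes: int | None = None) -> list[FoldResult]:
    """Train/evaluate the full model once per held-out subject.

    Each fold gets a fresh model seeded from ``train_config.seed`` plus the
    fold index, trained on all other subjects' trials. An identity audit
    asserts the held-out subject's trials never enter training.
    """
    y = np.asarray(labels, dtype=int)
    subj = np.asarray(subject_ids, dtype=int)
    n_cls = n_classes if n_classes is not None else int(y.max()) + 1
    results = []
    for i, (train_subjects, held) in enumerate(loso_folds(subj)):
        train_mask = np.isin(subj, train_subjects)
        test_mask = subj == held
        if np.any(train_mask & test_mask):
            raise AssertionError("LOSO leakage: overlapping train/test trials")
        assert not set(subj[train_mask]) & {held}
        fold_cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            label_smoothing=train_config.label_smoothing,
            seed=train_config.seed + i,
        )
        model, _ = train_model(features[train_mask], y[train_mask],
                               fold_cfg, n_classes=n_cls)
        preds = predict(model, features[test_mask])
        conf = confusion_counts(y[test_mask], preds, n_cls)
        acc, mcc, f1 = metrics(conf)
        results.append(FoldResult(held, conf, acc, mcc, f1))
        logger.info("fold %d (subject %d): acc %.3f mcc %.3f f1 %.3f",
                    i, held, acc, mcc, f1)
    return results
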