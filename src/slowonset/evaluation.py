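"""ROC-AUC and thresholded confusion metrics.

ROC-AUC is computed by the rank (Mann-Whitney) method — the fraction of
(positive, negative) pairs in which the positive scores higher, ties counted
one half — so tie handling is exact rather than approximated by curve
integration.  The decision threshold rule is strict: a score of exactly 0.5
is classified negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The metric is undefined for single-class input."""


@dataclass
class EvalReport:
    roc_auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability that a random positive outscores a random negative."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "ROC-AUC needs at least one positive and one negative")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_metrics(labels: Sequence[int], scores: Sequence[float],
                      threshold: float = 0.5) -> EvalReport:
    """Sensitivity/specificity/accuracy under the strict ``> threshold``
    rule (a score equal to the threshold is negative)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input")
    pred = s > threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0:
        log.warning("no positives: sensitivity undefined")
        sens = math.nan
    else:
        sens = tp / n_pos
    if n_neg == 0:
        log.warning("no negatives: specificity undefined")
        spec = math.nan
    else:
        spec = tn / n_neg
    try:
        auc = roc_auc(y, s)
    except UndefinedMetricError:
        auc = math.nan
    return EvalReport(roc_auc=auc, sensitivity=sens, specificity=spec,
                      accuracy=(tp + tn) / (n_pos + n_neg),
                      n_pos=n_pos, n_neg=n_neg, threshold=threshold)


def evaluate(model, val_windows, stats=None,
             train_windows=None) -> EvalReport:
    """Score population-z-scored validation windows and assemble the report.

    ``stats`` are the training-population statistics; they may instead be
    derived on the fly from ``train_windows``.
    """
    from .augment import compute_population_stats, population_zscore
    from .data_model import stack_windows

    if stats is None:
        if train_windows is None:
            raise ValueError("provide stats or train_windows")
        stats = compute_population_stats(train_windows)
    vw = population_zscore(val_windows, stats)
    values, labels, _ = stack_windows(vw)
    scores = np.concatenate([
        model.predict_proba(values[i:i + 32])
        for i in range(0, values.shape[0], 32)
    ])
    return confusion_metrics(labels, scores)
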