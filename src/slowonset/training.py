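"""Discounted binary cross-entropy training with SGD and momentum.

The loss down-weights ambiguous positives — windows whose positive fraction
``p`` covers less than the first second after the onset — via a piecewise
discount factor, and slightly discounts all negatives to keep the balanced
classes unbiased:

    alpha(p) = 0.95        if p = 0
               10 p        if 0 < p <= 0.1
               1           if p > 0.1

The optimizer is classical momentum SGD (velocity form, no Nesterov):
``v <- beta v - eta grad; w <- w + v``, with the learning rate halved every
15 epochs from 1e-4.  An L2 penalty ``lambda sum(beta^2)`` over all
convolution kernels is added to the cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .augment import (MiniBatch, batch_zscore, compute_population_stats,
                      per_sequence_zscore, population_zscore)
from .data_model import Window, stack_windows
from .evaluation import EvalReport, confusion_metrics, roc_auc
from .network import ResNet1D, TrainingFlags
from .nn import sigmoid

log = logging.getLogger(__name__)

BCE_EPS = 1e-7


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 75
    lr_initial: float = 1e-4
    lr_halve_every: int = 15
    momentum: float = 0.9
    l2_lambda: float = 0.01
    discount_enabled: bool = True
    zscore: str = "batch"       # "batch" | "per_sequence"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.lr_initial <= 0:
            raise ValueError("batch_size, epochs >= 1 and lr_initial > 0")

    @classmethod
    def from_flags(cls, flags: TrainingFlags, **kw) -> "TrainConfig":
        return cls(batch_size=flags.batch_size,
                   l2_lambda=flags.l2_lambda,
                   discount_enabled=flags.discount,
                   zscore=flags.zscore, **kw)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    roc_auc: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def best(self) -> EpochRecord:
        """Epoch with the maximal validation ROC-AUC."""
        return max(self.records, key=lambda r: r.roc_auc)


def discount_factor(p: float | np.ndarray) -> float | np.ndarray:
    """Piecewise loss discount as a function of the positive fraction."""
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    alpha = np.where(p_arr == 0, 0.95,
                     np.where(p_arr <= 0.1, 10.0 * p_arr, 1.0))
    return float(alpha) if np.isscalar(p) or p_arr.ndim == 0 else alpha


def bce(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    yp = np.clip(y_pred, BCE_EPS, 1.0 - BCE_EPS)
    yt = np.asarray(y_true, dtype=np.float64)
    return -(yt * np.log(yp) + (1.0 - yt) * np.log(1.0 - yp))


def training_loss(y_true, y_pred, p, kernels: Sequence[np.ndarray] = (),
                  lam: float = 0.0) -> float:
    """Discounted cross-entropy plus the L2 kernel penalty (scalar cost)."""
    alpha = discount_factor(p)
    cost = float(np.mean(alpha * bce(np.atleast_1d(y_true),
                                     np.atleast_1d(y_pred))))
    cost += lam * sum(float((np.asarray(k) ** 2).sum()) for k in kernels)
    return cost


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Initial rate halved every ``lr_halve_every`` epochs."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.lr_initial * 2.0 ** (-(epoch // cfg.lr_halve_every))


class MomentumSGD:
    """v <- beta v - eta grad;  w <- w + v."""

    def __init__(self, params, momentum: float):
        self.params = list(params)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= lr * p.grad
            p.value += v


def _validation_matrix(val_windows: Sequence[Window], train_windows,
                       zscore: str) -> tuple[np.ndarray, np.ndarray]:
    if zscore == "batch":
        stats = compute_population_stats(train_windows)
        vw = population_zscore(val_windows, stats)
        values, labels, _ = stack_windows(vw)
    else:
        values, labels, _ = stack_windows(val_windows)
        values = per_sequence_zscore(values)
    return values, labels


def _predict_in_batches(model: ResNet1D, values: np.ndarray,
                        batch: int = 32) -> np.ndarray:
    return np.concatenate([
        model.predict_proba(values[i:i + batch])
        for i in range(0, values.shape[0], batch)
    ])


def train(model: ResNet1D, train_windows: Sequence[Window],
          val_windows: Sequence[Window],
          cfg: Optional[TrainConfig] = None) -> TrainHistory:
    """Run the full training loop; all randomness derives from ``cfg.seed``.

    Every epoch the training windows are reshuffled; batches of
    ``cfg.batch_size`` are normalized per the configured mode (global
    batch-wise z-scoring for the full method, per-sequence for the
    ablation), the last incomplete batch is dropped, and validation metrics
    are computed on population-z-scored validation windows.
    """
    cfg = cfg or TrainConfig()
    if not train_windows:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7EA1)))
    values, labels, pfrac = stack_windows(train_windows)
    if cfg.zscore == "per_sequence":
        values = per_sequence_zscore(values)
    val_values, val_labels = _validation_matrix(
        val_windows, train_windows, cfg.zscore)

    opt = MomentumSGD(model.params(), cfg.momentum)
    n = values.shape[0]
    n_batches = n // cfg.batch_size
    if n_batches == 0:
        raise ValueError(
            f"{n} windows cannot fill one batch of {cfg.batch_size}")
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for bi in range(n_batches):
            idx = order[bi * cfg.batch_size:(bi + 1) * cfg.batch_size]
            xb = values[idx]
            if cfg.zscore == "batch":
                mb = batch_zscore(MiniBatch(values=xb, labels=labels[idx],
                                            p=pfrac[idx]))
                xb = mb.values
            yb = labels[idx].astype(np.float64)
            alpha = (discount_factor(pfrac[idx]) if cfg.discount_enabled
                     else np.ones_like(pfrac[idx]))

            model.zero_grad()
            logits = model.forward_logits(xb, training=True)
            probs = sigmoid(logits)
            loss = float(np.mean(alpha * bce(yb, probs)))
            loss += model.l2_penalty(cfg.l2_lambda)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {bi}")
            dlogit = alpha * (probs - yb) / cfg.batch_size
            model.backward_logits(dlogit)
            if cfg.l2_lambda:
                for prm in model.params():
                    if prm.l2:
                        prm.grad += 2.0 * cfg.l2_lambda * prm.value
            opt.step(lr)
            losses.append(loss)

        scores = _predict_in_batches(model, val_values)
        auc = roc_auc(val_labels, scores)
        rep = confusion_metrics(val_labels, scores)
        history.records.append(EpochRecord(
            epoch=epoch, lr=lr, train_loss=float(np.mean(losses)),
            roc_auc=auc, sensitivity=rep.sensitivity,
            specificity=rep.specificity, accuracy=rep.accuracy))
        log.info("epoch %d lr=%.2e loss=%.4f val_auc=%.4f",
                 epoch, lr, history.records[-1].train_loss, auc)
    return history


def run_experiment(variants: Sequence[str],
                   train_windows: Sequence[Window],
                   val_windows: Sequence[Window],
                   cfg_builder,
                   n_seeds: int = 10,
                   seeds: Optional[Sequence[int]] = None,
                   epochs: int = 75) -> dict[str, dict]:
    """Train every variant over the same shared seeds; summarize best epochs.

    ``cfg_builder(variant, seed)`` must return a ``(model, TrainConfig)``
    pair.  For each variant the per-seed best-epoch metrics (maximal
    validation ROC-AUC) are aggregated into mean and standard deviation.
    """
    if not variants:
        raise ValueError("variant list is empty")
    seeds = list(seeds) if seeds is not None else list(range(n_seeds))
    table: dict[str, dict] = {}
    for variant in variants:
        rows = []
        for seed in seeds:
            model, cfg = cfg_builder(variant, seed)
            hist = train(model, train_windows, val_windows, cfg)
            b = hist.best
            rows.append((b.roc_auc, b.sensitivity, b.specificity,
                         b.accuracy))
        arr = np.array(rows)
        table[variant] = {
            "roc_auc": (arr[:, 0].mean(), arr[:, 0].std()),
            "sensitivity": (arr[:, 1].mean(), arr[:, 1].std()),
            "specificity": (arr[:, 2].mean(), arr[:, 2].std()),
            "accuracy": (arr[:, 3].mean(), arr[:, 3].std()),
            "best_roc_auc": float(arr[:, 0].max()),
            "seeds": seeds,
        }
    return table
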