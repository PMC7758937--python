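"""Crop-resample augmentation and global z-scoring.

The crop-resample augmentation perturbs the temporal scale of a window: a
crop of ``round(u * L)`` samples anchored at the window's first timestep is
linearly interpolated back to length ``L``, multiplying every apparent
frequency by ``u`` (``u`` uniform on [0.9, 1.1]; half of the training set is
augmented, once, before training).

Global batch-wise z-scoring reduces a whole mini-batch — batch, time and
channel axes — to a single mean and standard deviation, so that every batch
presents the network with a different overall scale and offset.  Validation
data are instead z-scored with the training-set population statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional, Sequence

import numpy as np

from .data_model import Recording, Window, stack_windows

log = logging.getLogger(__name__)

#: guard against division by zero in z-scoring
ZSCORE_EPS = 1e-8


@dataclass
class MiniBatch:
    """A stack of windows with labels, positive fractions, and the
    normalization statistics that were applied to it (for audit)."""

    values: np.ndarray          # (B, L, 10)
    labels: np.ndarray          # (B,)
    p: np.ndarray               # (B,)
    mu: Optional[float] = None
    sigma: Optional[float] = None

    @classmethod
    def from_windows(cls, windows: Sequence[Window]) -> "MiniBatch":
        values, labels, p = stack_windows(windows)
        return cls(values=values, labels=labels, p=p)

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class PopulationStats:
    """Scalar mean/sd of the training population (all samples, all axes)."""

    mu_pop: float
    sigma_pop: float

    def __post_init__(self) -> None:
        if self.sigma_pop <= 0:
            raise ValueError("sigma_pop must be positive")


def _window_label_track(win: Window) -> np.ndarray:
    """Reconstruct the 0/1 label per timestep inside the window.

    Recordings have a single 0->1 transition, so the window's positive
    timesteps are exactly its trailing ``round(p * L)`` samples.
    """
    L = win.length
    n_pos = int(round(win.p * L))
    track = np.zeros(L, dtype=np.int8)
    if n_pos:
        track[L - n_pos:] = 1
    return track


def crop_resample(win: Window, u: float,
                  source: Optional[Recording] = None) -> Window:
    """Crop ``round(u * L)`` samples and linearly resample back to ``L``.

    For ``u <= 1`` the crop is the window's own leading samples.  For
    ``u > 1`` the crop extends beyond the window's last timestep into the
    source recording when one is supplied and long enough; otherwise the
    window is extended by reflecting its own tail (logged).  Signal values
    are linearly interpolated; the label track is resampled
    nearest-neighbor and ``p``/``label`` recomputed from it.
    """
    if not 0.9 <= u <= 1.1:
        raise ValueError(f"u={u} outside [0.9, 1.1]")
    L = win.length
    n = int(round(u * L))
    if n == L:
        return _dc_replace(win, values=win.values.copy())

    if n < L:
        crop = win.values[:n]
        crop_labels = _window_label_track(win)[:n]
    else:
        ext_end = win.t_i + n - 1
        if source is not None and ext_end <= source.n_samples - 1:
            crop = source.signal[win.t_i:win.t_i + n]
            crop_labels = source.labels[win.t_i:win.t_i + n]
        else:
            extra = n - L
            crop = np.concatenate(
                [win.values, win.values[-2:-2 - extra:-1]], axis=0)
            track = _window_label_track(win)
            crop_labels = np.concatenate([track, track[-2:-2 - extra:-1]])
            log.debug("crop_resample u=%g: no source context, reflected "
                      "window tail by %d samples", u, extra)

    src_pos = np.linspace(0.0, n - 1, L)
    base = np.arange(n, dtype=np.float64)
    out = np.empty((L, win.values.shape[1]))
    for c in range(win.values.shape[1]):
        out[:, c] = np.interp(src_pos, base, crop[:, c])
    lab = crop_labels[np.clip(np.round(src_pos).astype(int), 0, n - 1)]
    p = float(lab.sum()) / L
    return Window(values=out, label=int(p > 0), p=p,
                  t_i=win.t_i, t_f=win.t_f, patient_id=win.patient_id)


def augment_training_set(windows: Sequence[Window], fraction: float = 0.5,
                         rng_seed: int = 0,
                         sources: Optional[dict[str, Recording]] = None
                         ) -> list[Window]:
    """Replace a seeded ``round(fraction * N)`` subset by crop-resampled
    versions with ``u ~ Uniform[0.9, 1.1]``.  Applied once, offline."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    windows = list(windows)
    n_aug = int(round(fraction * len(windows)))
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(windows), size=n_aug, replace=False)
    out = list(windows)
    for i in chosen:
        u = float(rng.uniform(0.9, 1.1))
        src = sources.get(windows[i].patient_id) if sources else None
        out[i] = crop_resample(windows[i], u, source=src)
    return out


def batch_zscore(batch: MiniBatch) -> MiniBatch:
    """Normalize a whole batch with one scalar mean and standard deviation."""
    if batch.size == 0:
        raise ValueError("empty batch")
    mu = float(batch.values.mean())
    sigma = float(batch.values.std())
    if sigma < ZSCORE_EPS:
        log.warning("degenerate batch (sigma=%g < %g): centering only",
                    sigma, ZSCORE_EPS)
        sigma = ZSCORE_EPS
    values = (batch.values - mu) / sigma
    return MiniBatch(values=values, labels=batch.labels, p=batch.p,
                     mu=mu, sigma=sigma)


def per_sequence_zscore(values: np.ndarray) -> np.ndarray:
    """Normalize each sequence by its own scalar mean/sd (ablation mode)."""
    mu = values.mean(axis=(1, 2), keepdims=True)
    sigma = values.std(axis=(1, 2), keepdims=True)
    return (values - mu) / np.maximum(sigma, ZSCORE_EPS)


def compute_population_stats(windows: Sequence[Window]) -> PopulationStats:
    """Scalar mean/sd over every sample of every training window."""
    values, _, _ = stack_windows(windows)
    return PopulationStats(mu_pop=float(values.mean()),
                           sigma_pop=float(values.std()))


def population_zscore(windows: Sequence[Window],
                      stats: PopulationStats) -> list[Window]:
    """Transform every window with the same training-population statistics."""
    out = []
    for w in windows:
        out.append(Window(
            values=(w.values - stats.mu_pop) / stats.sigma_pop,
            label=w.label, p=w.p, t_i=w.t_i, t_f=w.t_f,
            patient_id=w.patient_id,
        ))
    return out
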