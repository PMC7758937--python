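"""Training-set construction: strided positive enumeration, balanced negatives.

For each patient with an onset, every ten-second window ending on the stride
grid anchored at the onset is a positive example — from the window that just
touches the onset with its final timestep to the all-positive window whose
first timestep reaches the onset.  Negatives are drawn with replacement,
uniformly, from every window ending strictly before the onset, capped at the
positive count so each patient contributes a balanced set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import WINDOW_LEN, Recording, Window
from .synth import Cohort

log = logging.getLogger(__name__)


@dataclass
class WindowSetSpec:
    """Window extraction parameters.

    ``max_pos_per_patient`` optionally subsamples each patient's positive set
    (seeded, uniform without replacement) to bound the training-set size for
    small-compute experiments; ``None`` keeps the full enumeration.
    """

    window_len: int = WINDOW_LEN
    stride: int = 5
    rng_seed: int = 0
    max_pos_per_patient: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def enumerate_positive_windows(rec: Recording,
                               spec: WindowSetSpec) -> list[Window]:
    """All positive windows on the stride grid anchored at the onset.

    Window end indices are ``t_f = onset + k * stride`` for integer
    ``k >= 0``, subject to the two boundary conditions ``t_f >= onset`` and
    ``t_i = t_f - L + 1 <= onset``, clipped to windows lying fully inside
    the recording.  Every returned window overlaps the onset, so has
    ``p > 0`` and label 1.
    """
    L, stride = spec.window_len, spec.stride
    if rec.onset_index is None:
        return []
    onset = rec.onset_index
    T = rec.n_samples
    out: list[Window] = []
    t_f = onset
    while t_f - L + 1 <= onset:
        t_i = t_f - L + 1
        if t_i >= 0 and t_f <= T - 1:
            out.append(Window.from_recording(rec, t_i, L))
        t_f += stride
    if not out:
        log.warning("patient %s: onset too close to the recording edges, "
                    "no positive window fits", rec.patient_id)
    return out


def sample_negative_windows(rec: Recording, n_max: int,
                            spec: WindowSetSpec,
                            rng: Optional[np.random.Generator] = None
                            ) -> list[Window]:
    """Draw ``n_max`` negative windows with replacement.

    Candidates are every window (stride 1) with ``t_f < onset``; for an
    onset-free recording, every window.  Returns an empty list when no
    candidate exists.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    L = spec.window_len
    rng = rng or np.random.default_rng(spec.rng_seed)
    hi = (rec.onset_index - 1 if rec.onset_index is not None
          else rec.n_samples - 1)
    lo = L - 1
    if hi < lo or n_max == 0:
        if n_max > 0:
            log.warning("patient %s: no negative window candidates",
                        rec.patient_id)
        return []
    ends = rng.integers(lo, hi + 1, size=n_max)
    return [Window.from_recording(rec, int(t_f) - L + 1, L) for t_f in ends]


def build_training_set(cohort: Cohort | Sequence[Recording],
                       spec: WindowSetSpec) -> list[Window]:
    """Per-patient positives plus an equal number of sampled negatives."""
    recs = cohort.train if isinstance(cohort, Cohort) else list(cohort)
    if not recs:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 1)))
    out: list[Window] = []
    for rec in recs:
        pos = enumerate_positive_windows(rec, spec)
        if (spec.max_pos_per_patient is not None
                and len(pos) > spec.max_pos_per_patient):
            keep = rng.choice(len(pos), size=spec.max_pos_per_patient,
                              replace=False)
            pos = [pos[i] for i in sorted(keep)]
        neg = sample_negative_windows(rec, len(pos), spec, rng=rng)
        out.extend(pos)
        out.extend(neg)
    return out
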