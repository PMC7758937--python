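"""Core data model: the bipolar montage, labeled recordings, and fixed-length windows.

A recording is one patient's multichannel EEG trace sampled at 200 Hz over ten
bipolar derivations, with a per-timestep binary label marking postictal slow
activity.  A window is a fixed-length (2000 x 10) slice of a recording used as
a training or validation example.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: The ten bipolar derivations, in canonical order.  Every array in the
#: pipeline uses this channel order.
MONTAGE: tuple[str, ...] = (
    "fp1-f7", "f7-t7", "t7-p7", "p7-o1",
    "fp2-f8", "f8-t8", "t8-p8", "p8-o2",
    "fz-cz", "cz-pz",
)

#: Sampling rate of the recordings, Hz.
SAMPLING_RATE = 200

#: Window length in timesteps: ten seconds at 200 Hz.
WINDOW_LEN = 10 * SAMPLING_RATE  # 2000

N_CHANNELS = len(MONTAGE)


class MontageError(ValueError):
    """A required derivation is absent or the channel set is malformed."""


class RateError(ValueError):
    """Sampling rate differs from the expected 200 Hz in strict mode."""


class FormatError(ValueError):
    """File contents violate the recording format contract."""


def _canon(name: str) -> str:
    """Canonicalize a channel name: lowercase, any separator run -> '-'."""
    return re.sub(r"[\s_−–—-]+", "-", name.strip().lower())


def validate_montage(names: Sequence[str], strict_order: bool = True) -> bool:
    """Check that *names* is the canonical ten-derivation bipolar montage.

    Comparison is case-insensitive and tolerant of separator variants
    ("FP1-F7", "fp1_f7" and "fp1 - f7" all match).  With ``strict_order``
    (default) the ten names must appear in the canonical order; otherwise any
    permutation of the full set passes.
    """
    canon = [_canon(n) for n in names]
    if strict_order:
        return canon == list(MONTAGE)
    return sorted(canon) == sorted(MONTAGE)


@dataclass
class ChannelSet:
    """An ordered set of ten derivation labels."""

    names: tuple[str, ...] = MONTAGE

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(self.names) != N_CHANNELS:
            raise MontageError(
                f"expected {N_CHANNELS} derivations, got {len(self.names)}"
            )

    def validate_strict(self) -> None:
        """Raise unless the names equal the canonical montage."""
        if not validate_montage(self.names):
            missing = [m for m in MONTAGE if m not in
                       {_canon(n) for n in self.names}]
            raise MontageError(
                f"channel set is not the canonical montage; missing or "
                f"misordered: {missing or 'order differs'}"
            )


@dataclass
class Recording:
    """One patient's labeled EEG trace.

    Attributes
    ----------
    patient_id : str
        Stable identifier for the source patient.
    signal : ndarray, shape (T, 10)
        Amplitudes in microvolts, one column per montage derivation.
    fs : float
        Sampling rate in Hz (200 for the study recordings).
    labels : ndarray of {0, 1}, shape (T,)
        Per-timestep slow-activity label.
    onset_index : int or None
        First positive timestep (0-based), or ``None`` when the recording
        contains no slow activity.
    """

    patient_id: str
    signal: np.ndarray
    fs: float
    labels: np.ndarray
    onset_index: Optional[int] = None
    channels: ChannelSet = field(default_factory=ChannelSet)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def validate(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[1] != N_CHANNELS:
            raise FormatError(
                f"signal must be (T, {N_CHANNELS}), got {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite samples")
        if self.labels.shape != (self.signal.shape[0],):
            raise FormatError(
                f"label length {self.labels.shape} does not match signal "
                f"length {self.signal.shape[0]}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise FormatError("labels must be 0/1")
        if self.fs <= 0:
            raise RateError(f"sampling rate must be positive, got {self.fs}")
        pos = np.flatnonzero(self.labels)
        if self.onset_index is None:
            if pos.size:
                raise FormatError(
                    "labels contain positives but onset_index is None"
                )
        else:
            if not pos.size or pos[0] != self.onset_index:
                raise FormatError(
                    f"onset_index={self.onset_index} does not match first "
                    f"positive label "
                    f"{pos[0] if pos.size else 'absent'}"
                )
            # single 0 -> 1 transition: labels are 1 from onset to the end
            if not self.labels[self.onset_index:].all():
                raise FormatError(
                    "labels must stay 1 from onset_index to the end"
                )

    @classmethod
    def from_labels(cls, patient_id: str, signal: np.ndarray, fs: float,
                    labels: np.ndarray,
                    channels: Optional[ChannelSet] = None) -> "Recording":
        """Build a Recording inferring ``onset_index`` from the label track."""
        labels = np.asarray(labels, dtype=np.int8)
        pos = np.flatnonzero(labels)
        onset = int(pos[0]) if pos.size else None
        return cls(patient_id=patient_id, signal=signal, fs=fs,
                   labels=labels, onset_index=onset,
                   channels=channels or ChannelSet())


@dataclass
class Window:
    """A fixed-length training or validation example.

    ``t_i``/``t_f`` are the first and last source timesteps (0-based,
    inclusive), so ``t_f - t_i + 1`` equals the window length.  ``p`` is the
    fraction of the window's timesteps labeled positive; the binary label is
    1 iff ``p > 0``.
    """

    values: np.ndarray           # (L, 10)
    label: int
    p: float
    t_i: int
    t_f: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise FormatError(
                f"window values must be (L, {N_CHANNELS}), "
                f"got {self.values.shape}"
            )
        if self.t_f - self.t_i + 1 != self.values.shape[0]:
            raise FormatError(
                f"t_f - t_i + 1 = {self.t_f - self.t_i + 1} does not equal "
                f"window length {self.values.shape[0]}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise FormatError(f"p={self.p} outside [0, 1]")
        if self.label != int(self.p > 0):
            raise FormatError("label must be 1 iff p > 0")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_recording(cls, rec: Recording, t_i: int,
                       length: int = WINDOW_LEN) -> "Window":
        """Cut the window ``[t_i, t_i + length - 1]`` out of *rec*."""
        t_f = t_i + length - 1
        if t_i < 0 or t_f >= rec.n_samples:
            raise IndexError(
                f"window [{t_i}, {t_f}] outside recording of "
                f"length {rec.n_samples}"
            )
        seg = rec.labels[t_i:t_f + 1]
        p = float(seg.sum()) / length
        return cls(values=rec.signal[t_i:t_f + 1],
                   label=int(p > 0), p=p, t_i=t_i, t_f=t_f,
                   patient_id=rec.patient_id)


def stack_windows(windows: Sequence[Window]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into ``(values (B,L,10), labels (B,), p (B,))`` arrays."""
    values = np.stack([w.values for w in windows]).astype(np.float64)
    labels = np.array([w.label for w in windows], dtype=np.int8)
    p = np.array([w.p for w in windows], dtype=np.float64)
    return values, labels, p
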