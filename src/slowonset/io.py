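"""Reading and writing labeled EEG recordings.

Two on-disk formats are supported:

* ``columnar`` — a plain-text dialect: one header line with the ten channel
  names plus ``label``, tab-separated, then one sample per row.  Lossless for
  practical purposes (floats printed with 17 significant digits).
* ``edf`` — European Data Format, 16-bit quantized.  The per-sample binary
  label track does not fit EDF's event-based annotation model, so labels are
  stored in a sidecar text file (``<path>.labels``, one 0/1 per line), which
  is the canonical label source on read.

EDF reading goes through :mod:`mne`; writing uses a minimal EDF writer
implemented here (header + int16 data records, 1-second records, zero-padded
final record truncated on read to the sidecar length).
"""

from __future__ import annotations

import datetime as _dt
import os
from pathlib import Path
from typing import Optional

import numpy as np

from .data_model import (
    MONTAGE, N_CHANNELS, SAMPLING_RATE,
    ChannelSet, FormatError, MontageError, RateError, Recording, _canon,
)

_LABEL_SUFFIX = ".labels"


# ---------------------------------------------------------------------------
# columnar dialect
# ---------------------------------------------------------------------------

def _write_columnar(rec: Recording, path: Path) -> None:
    header = "\t".join(list(rec.channels.names) + ["label"])
    data = np.column_stack([rec.signal, rec.labels.astype(np.float64)])
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write(f"# patient_id={rec.patient_id}\n")
        fh.write(header + "\n")
        np.savetxt(fh, data,
                   fmt=["%.17g"] * N_CHANNELS + ["%d"], delimiter="\t")


def _read_columnar(path: Path, strict: bool) -> Recording:
    fs: float = float(SAMPLING_RATE)
    patient_id = path.stem
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "patient_id":
                patient_id = val
            line = fh.readline()
        names = [c.strip() for c in line.rstrip("\n").split("\t")]
        if not names or _canon(names[-1]) != "label":
            raise FormatError(f"{path}: last column must be 'label'")
        channel_names = names[:-1]
        _check_montage(channel_names)
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed data rows: {exc}") from exc
    if data.shape[1] != N_CHANNELS + 1:
        raise FormatError(
            f"{path}: expected {N_CHANNELS + 1} columns, got {data.shape[1]}"
        )
    if strict and fs != SAMPLING_RATE:
        raise RateError(f"{path}: fs={fs}, expected {SAMPLING_RATE}")
    labels = data[:, -1]
    if not np.isin(labels, (0.0, 1.0)).all():
        raise FormatError(f"{path}: label column must contain only 0/1")
    return Recording.from_labels(
        patient_id=patient_id, signal=data[:, :-1], fs=fs,
        labels=labels.astype(np.int8),
        channels=ChannelSet(tuple(channel_names)),
    )


def _check_montage(names: list[str]) -> None:
    canon = {_canon(n) for n in names}
    missing = [m for m in MONTAGE if m not in canon]
    if missing:
        raise MontageError(f"missing derivation(s): {', '.join(missing)}")
    if len(names) != N_CHANNELS:
        raise MontageError(
            f"expected {N_CHANNELS} channels, got {len(names)}"
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 16-bit, 1-second data records, zero-padded tail."""
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise RateError(f"EDF writer requires an integer rate, got {rec.fs}")
    T = rec.n_samples
    n_rec = int(np.ceil(T / fs))
    sig = rec.signal
    phys_min = np.floor(sig.min(axis=0))
    phys_max = np.ceil(sig.max(axis=0))
    flat = phys_max - phys_min < 1e-9
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"X X X {rec.patient_id}", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(_dt.datetime(2000, 1, 1).strftime("%d.%m.%y"), 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + N_CHANNELS)), 8),
        _edf_field("", 44),
        _edf_field(str(n_rec), 8),
        _edf_field("1", 8),
        _edf_field(str(N_CHANNELS), 4),
    ])
    per_sig = [
        b"".join(_edf_field(n, 16) for n in rec.channels.names),
        b"".join(_edf_field("EEG bipolar", 80) for _ in range(N_CHANNELS)),
        b"".join(_edf_field("uV", 8) for _ in range(N_CHANNELS)),
        b"".join(_edf_field(f"{v:g}", 8) for v in phys_min),
        b"".join(_edf_field(f"{v:g}", 8) for v in phys_max),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(N_CHANNELS)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(N_CHANNELS)),
        b"".join(_edf_field("", 80) for _ in range(N_CHANNELS)),
        b"".join(_edf_field(str(fs), 8) for _ in range(N_CHANNELS)),
        b"".join(_edf_field("", 32) for _ in range(N_CHANNELS)),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    padded = np.zeros((n_rec * fs, N_CHANNELS))
    padded[:T] = sig
    digital = np.round(
        (padded - phys_min) * scale + dig_min
    ).clip(dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.writelines(per_sig)
        for r in range(n_rec):
            block = digital[r * fs:(r + 1) * fs]  # (fs, C)
            fh.write(block.T.tobytes())  # per-signal sequential


def _read_edf(path: Path, strict: bool) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if strict and abs(fs - SAMPLING_RATE) > 1e-6:
        raise RateError(f"{path}: fs={fs}, expected {SAMPLING_RATE}")
    names = list(raw.ch_names)
    canon_map = {_canon(n): i for i, n in enumerate(names)}
    if all(m in canon_map for m in MONTAGE):
        idx = [canon_map[m] for m in MONTAGE]
        data = raw.get_data()[idx].T  # (T, 10), volts for EEG kinds
        channel_names = MONTAGE
    else:
        # raw electrodes: form the ten bipolar derivations by subtraction
        pairs = [m.split("-") for m in MONTAGE]
        missing = [m for m, (a, b) in zip(MONTAGE, pairs)
                   if a not in canon_map or b not in canon_map]
        if missing:
            raise MontageError(
                f"missing derivation(s): {', '.join(missing)}"
            )
        full = raw.get_data()
        data = np.stack(
            [full[canon_map[a]] - full[canon_map[b]] for a, b in pairs]
        ).T
        channel_names = MONTAGE
    # mne scales recognized EEG units to volts; recover microvolts
    data = data * 1e6

    label_path = Path(str(path) + _LABEL_SUFFIX)
    if not label_path.exists():
        raise FormatError(
            f"{path}: label sidecar {label_path.name} not found"
        )
    labels = np.loadtxt(label_path, dtype=np.int8, ndmin=1)
    if labels.shape[0] > data.shape[0]:
        raise FormatError(
            f"{path}: sidecar has {labels.shape[0]} labels but the EDF "
            f"holds only {data.shape[0]} samples"
        )
    data = data[:labels.shape[0]]  # drop final-record zero padding
    patient_id = path.stem
    return Recording.from_labels(
        patient_id=patient_id, signal=data, fs=fs, labels=labels,
        channels=ChannelSet(channel_names),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_recording(path: str | os.PathLike, format: Optional[str] = None,
                   strict: bool = True) -> Recording:
    """Read a labeled recording.

    Parameters
    ----------
    path : path-like
        Source file.  For EDF, a ``<path>.labels`` sidecar must exist.
    format : {"edf", "columnar"}, optional
        Inferred from the file extension when omitted (``.edf`` -> edf).
    strict : bool
        Enforce the 200 Hz study rate and canonical montage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "columnar"
    if format == "edf":
        rec = _read_edf(path, strict)
    elif format == "columnar":
        rec = _read_columnar(path, strict)
    else:
        raise ValueError(f"unknown format {format!r}")
    if strict:
        rec.channels.validate_strict()
    rec.validate()
    return rec


def write_recording(rec: Recording, path: str | os.PathLike,
                    format: Optional[str] = None) -> None:
    """Write *rec* to *path*; EDF output also writes the label sidecar."""
    path = Path(path)
    rec.validate()
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "columnar"
    if format == "edf":
        _write_edf(rec, path)
        np.savetxt(str(path) + _LABEL_SUFFIX, rec.labels, fmt="%d")
    elif format == "columnar":
        _write_columnar(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
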