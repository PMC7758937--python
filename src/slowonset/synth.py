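"""Seeded synthetic cohorts of labeled EEG-like recordings.

The study data are protected health information and unavailable, so this
module generates surrogate recordings that carry the two statistical cues the
detector is designed to exploit:

* a spectral shift at onset — pre-onset activity is a mixture of faster
  oscillations (alpha/beta range), post-onset activity is dominated by a
  high-amplitude slow (delta-range) oscillation;
* a cross-channel correlation shift — the post-onset slow component is
  largely shared across the ten derivations ("global" slow activity), with a
  configurable shared-component weight.

Per-patient log-normal channel gains and normal channel biases create the
scale/offset diversity that batch-wise z-scoring is meant to absorb.  Every
output is a pure function of ``(seed, config)``; patient-level seeds are
derived with a splittable scheme so changing the cohort size never reshuffles
earlier patients.

These are surrogates, not physiologically realistic EEG: there is no 1/f
background fit, no artifact model, and all amplitude scales are package
choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .data_model import SAMPLING_RATE, WINDOW_LEN, N_CHANNELS, Recording, Window


class GenerationError(ValueError):
    """The requested recording cannot be generated under the config."""


class SamplingError(ValueError):
    """A window sample with the requested properties cannot be drawn."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Amplitudes are in the (arbitrary) microvolt scale of the generator;
    frequencies in Hz.
    """

    n_train_patients: int = 134
    n_val_patients: int = 34
    duration_range: tuple[float, float] = (60.0, 180.0)
    onset_fraction_range: tuple[float, float] = (0.4, 0.8)
    pre_bands: tuple[tuple[float, float], ...] = ((10.0, 1.0), (22.0, 0.6))
    slow_band: tuple[float, float] = (1.5, 3.0)
    cross_corr: float = 0.9
    channel_gain_sd: float = 0.3
    channel_bias_sd: float = 5.0
    noise_sd: float = 0.5
    #: residual fast activity after onset, as a fraction of pre_bands amplitude
    post_fast_atten: float = 0.3
    fs: float = float(SAMPLING_RATE)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cross_corr <= 1.0:
            raise ValueError("cross_corr must lie in [0, 1]")
        lo, hi = self.onset_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("onset_fraction_range must lie within (0, 1)")
        for f, a in tuple(self.pre_bands) + (self.slow_band,):
            if a < 0 or f <= 0:
                raise ValueError("band amplitudes must be >= 0, freqs > 0")
        if min(self.channel_gain_sd, self.channel_bias_sd,
               self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class Cohort:
    train: list[Recording]
    val: list[Recording]
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def _patient_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def child_seed(cohort_seed: int, index: int) -> int:
    """Patient-level seed: splittable, stable under cohort-size changes."""
    return int(np.random.SeedSequence((cohort_seed, index))
               .generate_state(1)[0])


def _synth_signal(rng: np.random.Generator, cfg: GeneratorConfig,
                  T: int, onset: int, *, cross_corr: float,
                  slow_sign: np.ndarray, range_scale: float) -> np.ndarray:
    fs = cfg.fs
    t = np.arange(T) / fs
    pre_mask = (np.arange(T) < onset).astype(np.float64)[:, None]
    post_mask = 1.0 - pre_mask

    sig = np.zeros((T, N_CHANNELS))
    # fast oscillations: full amplitude pre-onset, attenuated residual after
    for f, a in cfg.pre_bands:
        phases = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        osc = a * np.sin(2 * np.pi * f * t[:, None] + phases[None, :])
        sig += osc * (pre_mask + cfg.post_fast_atten * post_mask)

    # slow component: shared across channels with weight cross_corr
    f_slow, a_slow = cfg.slow_band
    shared_phase = rng.uniform(0, 2 * np.pi)
    shared = np.sin(2 * np.pi * f_slow * t + shared_phase)
    indep_phases = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    indep = np.sin(2 * np.pi * f_slow * t[:, None] + indep_phases[None, :])
    slow = (cross_corr * shared[:, None] + (1.0 - cross_corr) * indep)
    slow = a_slow * range_scale * slow * slow_sign[None, :]
    sig += slow * post_mask

    sig += rng.normal(0.0, cfg.noise_sd, size=(T, N_CHANNELS))

    gains = np.exp(rng.normal(0.0, cfg.channel_gain_sd, size=N_CHANNELS))
    biases = rng.normal(0.0, cfg.channel_bias_sd, size=N_CHANNELS)
    return sig * gains[None, :] + biases[None, :]


def _draw_geometry(rng: np.random.Generator,
                   cfg: GeneratorConfig) -> tuple[int, int]:
    duration = rng.uniform(*cfg.duration_range)
    T = int(round(duration * cfg.fs))
    frac = rng.uniform(*cfg.onset_fraction_range)
    onset = int(round(frac * T))
    if onset < WINDOW_LEN or T - onset < WINDOW_LEN:
        raise GenerationError(
            f"duration {duration:.1f}s with onset fraction {frac:.2f} "
            f"cannot host a {WINDOW_LEN}-sample window on each side of "
            f"the onset"
        )
    return T, onset


def make_patient(seed: int, cfg: Optional[GeneratorConfig] = None,
                 patient_id: Optional[str] = None) -> Recording:
    """Generate one labeled recording with a single slow-activity onset."""
    cfg = cfg or GeneratorConfig()
    rng = _patient_rng(seed)
    T, onset = _draw_geometry(rng, cfg)
    sig = _synth_signal(rng, cfg, T, onset, cross_corr=cfg.cross_corr,
                        slow_sign=np.ones(N_CHANNELS), range_scale=1.0)
    labels = np.zeros(T, dtype=np.int8)
    labels[onset:] = 1
    return Recording(patient_id=patient_id or f"synth-{seed:010d}",
                     signal=sig, fs=cfg.fs, labels=labels, onset_index=onset)


def make_ambiguous_patient(seed: int, cfg: Optional[GeneratorConfig] = None,
                           patient_id: Optional[str] = None) -> Recording:
    """A hard case: weak cross-channel coupling of the slow component.

    The shared-component weight is capped at 0.3, a random subset of
    channels carries a sign-flipped slow component, and the slow amplitude
    is compressed — emulating onsets with low dynamic range and mixed
    positive/negative channel correlation.
    """
    cfg = cfg or GeneratorConfig()
    rng = _patient_rng(seed)
    T, onset = _draw_geometry(rng, cfg)
    slow_sign = np.where(rng.random(N_CHANNELS) < 0.4, -1.0, 1.0)
    sig = _synth_signal(
        rng, cfg, T, onset,
        cross_corr=min(cfg.cross_corr, 0.3),
        slow_sign=slow_sign, range_scale=0.4,
    )
    labels = np.zeros(T, dtype=np.int8)
    labels[onset:] = 1
    return Recording(patient_id=patient_id or f"synth-amb-{seed:010d}",
                     signal=sig, fs=cfg.fs, labels=labels, onset_index=onset)


def make_cohort(cfg: Optional[GeneratorConfig] = None) -> Cohort:
    """Generate the train/validation cohort from independent child seeds."""
    cfg = cfg or GeneratorConfig()
    train, val = [], []
    for i in range(cfg.n_train_patients):
        train.append(make_patient(child_seed(cfg.seed, i), cfg,
                                  patient_id=f"train-{i:04d}"))
    for j in range(cfg.n_val_patients):
        val.append(make_patient(child_seed(cfg.seed, cfg.n_train_patients + j),
                                cfg, patient_id=f"val-{j:04d}"))
    return Cohort(train=train, val=val, config=cfg)


def make_validation_windows(cohort: Cohort, n_windows: int,
                            pos_prevalence: float,
                            seed: Optional[int] = None) -> list[Window]:
    """Sample fixed-length validation windows at a requested prevalence.

    Positives contain at least one positive timestep; negatives end strictly
    before the onset (or come from onset-free recordings).  Sampling is with
    replacement, uniform over (patient, admissible end index).
    """
    if not 0.0 <= pos_prevalence <= 1.0:
        raise ValueError("pos_prevalence must lie in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence((cohort.config.seed if seed is None else seed,
                                0x5EED))
    )
    n_pos = int(round(n_windows * pos_prevalence))
    n_neg = n_windows - n_pos
    L = WINDOW_LEN

    pos_pool: list[tuple[Recording, int, int]] = []   # (rec, lo_tf, hi_tf)
    neg_pool: list[tuple[Recording, int, int]] = []
    for rec in cohort.val:
        T = rec.n_samples
        if rec.onset_index is not None:
            lo = max(rec.onset_index, L - 1)
            if lo <= T - 1:
                pos_pool.append((rec, lo, T - 1))
            hi = rec.onset_index - 1
            if hi >= L - 1:
                neg_pool.append((rec, L - 1, hi))
        else:
            if T >= L:
                neg_pool.append((rec, L - 1, T - 1))

    if n_pos > 0 and not pos_pool:
        raise SamplingError("no validation recording can supply a positive "
                            "window")
    if n_neg > 0 and not neg_pool:
        raise SamplingError("no validation recording can supply a negative "
                            "window")

    def draw(pool: list[tuple[Recording, int, int]], n: int) -> list[Window]:
        counts = np.array([hi - lo + 1 for _, lo, hi in pool], dtype=float)
        probs = counts / counts.sum()
        out = []
        for k in rng.choice(len(pool), size=n, p=probs):
            rec, lo, hi = pool[k]
            t_f = int(rng.integers(lo, hi + 1))
            out.append(Window.from_recording(rec, t_f - L + 1))
        return out

    windows = draw(pos_pool, n_pos) + draw(neg_pool, n_neg)
    for w in windows[:n_pos]:
        assert w.p > 0
    for w in windows[n_pos:]:
        assert w.p == 0
    return windows


def config_manifest(cfg: GeneratorConfig) -> dict:
    """JSON-serializable record of every generator parameter."""
    d = asdict(cfg)
    d["note"] = ("synthetic surrogate parameters chosen by this package; "
                 "not estimates of any clinical data")
    return d
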