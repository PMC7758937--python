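import numpy as np
import pytest

from slowonset.data_model import N_CHANNELS, Recording
from slowonset.network import NetworkConfig
from slowonset.synth import GeneratorConfig, make_cohort


@pytest.fixture(scope="session")
def tiny_net_cfg() -> NetworkConfig:
    """Reference layout shrunk to width 4 and 64 input samples for fast
    gradient and shape tests."""
    return NetworkConfig(base_width=4, stage_widths=(4, 8, 16),
                         input_shape=(64, 10))


@pytest.fixture(scope="session")
def small_cohort():
    """Three train + two val synthetic patients, short recordings."""
    cfg = GeneratorConfig(n_train_patients=3, n_val_patients=2,
                          duration_range=(25.0, 40.0),
                          onset_fraction_range=(0.45, 0.55), seed=11)
    return make_cohort(cfg)


def label_track(T: int, onset) -> np.ndarray:
    labels = np.zeros(T, dtype=np.int8)
    if onset is not None:
        labels[onset:] = 1
    return labels


@pytest.fixture
def make_recording():
    """Factory for small synthetic recordings with arbitrary onset."""

    def _make(T: int, onset, seed: int = 0, fs: float = 200.0) -> Recording:
        rng = np.random.default_rng(seed)
        return Recording(
            patient_id=f"t{T}-o{onset}",
            signal=rng.normal(size=(T, N_CHANNELS)),
            fs=fs, labels=label_track(T, onset), onset_index=onset,
        )

    return _make
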