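import numpy as np
import pandas as pd
import pytest

from thetareset import EpochSet, SimulationConfig, simulate_epoch_set
from thetareset.timefreq import Spectrogram


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def reset_epochs():
    """One-subject reset dataset, 100 trials, default noise (session-shared)."""
    cfg = SimulationConfig(n_subjects=1, n_trials_per_condition=50,
                           include_nomaze=False, seed=11)
    return simulate_epoch_set(cfg)


def make_epochs(data: np.ndarray, fs: float = 250.0,
                t0_ms: float = None) -> EpochSet:
    """Wrap a [trial, time] array as a single-channel EpochSet."""
    n_trials, n_time = data.shape
    if t0_ms is None:
        t0_ms = -(n_time // 2) * 1000.0 / fs
    t = t0_ms + np.arange(n_time) * 1000.0 / fs
    return EpochSet(data[:, None, :], t, fs,
                    pd.DataFrame({"trial_id": np.arange(n_trials)}),
                    ("ch",), None)


def make_phase_spectrogram(phases: np.ndarray, fs: float = 250.0,
                           freqs=None) -> Spectrogram:
    """Build a unit-amplitude spectrogram directly from phase angles.

    ``phases`` has shape [trial, freq, time]; amplitudes are 1 so ITC and
    phase extraction can be checked against closed forms.
    """
    n_trials, n_freqs, n_time = phases.shape
    t = np.arange(n_time) * 1000.0 / fs
    freqs = np.arange(1, n_freqs + 1, dtype=float) if freqs is None \
        else np.asarray(freqs, float)
    return Spectrogram(np.exp(1j * phases), freqs, t, fs,
                       pd.DataFrame({"trial_id": np.arange(n_trials)}),
                       np.zeros(n_freqs, bool))
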