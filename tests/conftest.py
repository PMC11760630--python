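import numpy as np
import pandas as pd
import pytest

from predistract import build_experiment
from predistract.epochs import EpochSet


@pytest.fixture(scope="session")
def plan():
    """Full-size experiment plan shared by read-only tests."""
    return build_experiment(7)


@pytest.fixture(scope="session")
def small_plan():
    return build_experiment(11, n_trials_per_block=12)


def make_epochs(n_trials=4, channels=("FCz", "Cz", "TP9", "TP10"), sfreq=250.0,
                tmin=-1.0, tmax=1.0, fill=0.0, metadata=None):
    """Small epoch container with constant data, for arithmetic checks."""
    n_samples = int(round((tmax - tmin) * sfreq))
    times = tmin + np.arange(n_samples) / sfreq
    data = np.full((n_trials, len(channels), n_samples), float(fill))
    if metadata is None:
        metadata = pd.DataFrame({
            "block": np.arange(n_trials) // 2 + 1,
            "trial": np.arange(n_trials) % 2 + 1,
            "memory_load": 1,
        })
    return EpochSet(data, times, list(channels), sfreq, metadata)


@pytest.fixture
def const_epochs():
    return make_epochs()
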