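"""Shared fixtures: a desk-scale synthetic world reused across tests.

The session-scoped epoch set keeps the generator's default signal
parameters (stage structure, SNR, gains) but scales the trial count,
channel count and epoch length down so the cross-validated decoders run
in seconds.
"""

import numpy as np
import pandas as pd
import pytest

from meegdecode import (
    BaselineSpec,
    ObserverModel,
    SignalRecipe,
    assign_folds,
    baseline_zscore,
    decode_timecourse,
    generate_epochs,
    simulate_behavior,
)
from meegdecode.epochs import EpochSet, make_channel_table

STAGES = {"stage1": (0.0, 115.0), "stage2": (115.0, 162.0),
          "stage3": (162.0, 271.0), "stage4": (271.0, 800.0)}


def toy_epochs(data: np.ndarray, sfreq: float = 64.0, t0: float = -500.0,
               locations=None, seen=None) -> EpochSet:
    """Wrap a raw (trials, channels, time) array in a valid EpochSet."""
    n_tr, n_ch, n_t = data.shape
    times = t0 + np.arange(n_t) * 1000.0 / sfreq
    channels = make_channel_table(n_ch, n_eog=min(2, n_ch - 1))
    loc = np.asarray(locations) if locations is not None else (np.arange(n_tr) % 8) + 1
    seen_arr = np.asarray(seen, dtype=bool) if seen is not None else np.ones(n_tr, dtype=bool)
    trials = pd.DataFrame({
        "trial": np.arange(n_tr), "location": loc, "seen": seen_arr,
        "response": loc, "correct": True, "target_present": True,
    })
    return EpochSet(data, times, sfreq, channels, trials)


@pytest.fixture(scope="session")
def small_epochs() -> EpochSet:
    """Default-recipe world at desk scale: 128 trials, 16 channels, -200..850 ms."""
    behavior = simulate_behavior(ObserverModel(), 131.0, 128, seed=11)
    recipe = SignalRecipe(n_trials=128, n_channels=16, epoch_window=(-200.0, 850.0), seed=12)
    epochs = generate_epochs(recipe, behavior)
    return baseline_zscore(epochs, BaselineSpec((-200.0, 0.0)))


@pytest.fixture(scope="session")
def small_decode(small_epochs):
    """Cross-validated 8-class decoding of the session epochs (k=10)."""
    labels = small_epochs.trials["location"].to_numpy()
    folds = assign_folds(small_epochs.n_trials, 10, seed=13)
    return decode_timecourse(small_epochs, labels, folds), labels
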