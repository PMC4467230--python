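"""Epoch container and fixture I/O.

The universal currency of the pipeline is the :class:`EpochSet`: a
``trials x channels x time`` tensor together with a per-trial behavioral
table and per-channel metadata.  Fixtures are stored in a small HDF5
container (datasets ``/data``, ``/times``, ``/channels``, ``/trials``)
with a lossless round trip; the trial table can also be exported as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "ParseError",
    "TRIAL_COLUMNS",
    "make_channel_table",
    "write_fixture",
    "read_fixture",
    "trials_to_tsv",
    "trials_from_tsv",
]

#: canonical trial-table columns, in export order
TRIAL_COLUMNS = ["trial", "location", "seen", "response", "correct", "target_present"]

CHANNEL_TYPES = ("mag", "grad", "eeg", "eog")


class ParseError(ValueError):
    """Raised when a fixture container is malformed; names the offending field."""


def make_channel_table(n_channels: int, n_eog: int = 2, roi: str | None = None) -> pd.DataFrame:
    """Default channel metadata: mag/grad/eeg round-robin plus trailing EOG channels."""
    if n_channels <= n_eog:
        raise ValueError("n_channels must exceed n_eog")
    rows = []
    for i in range(n_channels - n_eog):
        ctype = ("mag", "grad", "eeg")[i % 3]
        rows.append((f"{ctype.upper()}{i:03d}", ctype, roi or ""))
    for j in range(n_eog):
        rows.append((f"EOG{j:03d}", "eog", ""))
    return pd.DataFrame(rows, columns=["name", "type", "roi"])


@dataclass
class EpochSet:
    """Trials x channels x time tensor with aligned metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
    times : ndarray
        Sample times in ms, strictly increasing, uniform at 1000/sfreq.
    sfreq : float
        Sampling rate in Hz.
    channels : DataFrame with columns name, type, roi
    trials : DataFrame with the behavioral columns of :data:`TRIAL_COLUMNS`
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if len(self.times) != n_t:
            raise ValueError("times length does not match data")
        if len(self.channels) != n_ch:
            raise ValueError("channel table length does not match data")
        if len(self.trials) != n_tr:
            raise ValueError("trial table length does not match data")
        if n_t >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sfreq, rtol=0, atol=1e-6):
                raise ValueError("times must be uniform at 1/sfreq spacing")
        present = self.trials["target_present"].to_numpy(dtype=bool)
        loc = self.trials["location"].to_numpy()
        resp = self.trials["response"].to_numpy()
        if present.any():
            if not (np.isin(loc[present], range(1, 9)).all() and np.isin(resp[present], range(1, 9)).all()):
                raise ValueError("location/response must be in 1..8 on target-present trials")
            corr = self.trials["correct"].to_numpy(dtype=bool)
            if not np.array_equal(corr[present], loc[present] == resp[present]):
                raise ValueError("correct flag must equal (response == location)")

    # -- convenience -------------------------------------------------------
    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask for the half-open window [a, b) in ms."""
        a, b = window_ms
        return (self.times >= a) & (self.times < b)

    def sel(self, trial_idx=None, channel_idx=None, time_mask=None) -> "EpochSet":
        """Subset along any axis, keeping metadata aligned."""
        data = self.data
        trials = self.trials
        channels = self.channels
        times = self.times
        if trial_idx is not None:
            trial_idx = np.asarray(trial_idx)
            data = data[trial_idx]
            trials = trials.iloc[trial_idx].reset_index(drop=True)
        if channel_idx is not None:
            channel_idx = np.asarray(channel_idx)
            data = data[:, channel_idx]
            channels = channels.iloc[channel_idx].reset_index(drop=True)
        if time_mask is not None:
            data = data[:, :, time_mask]
            times = times[time_mask]
        return EpochSet(data.copy(), times.copy(), self.sfreq, channels.copy(), trials.copy())

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.times.copy(), self.sfreq, self.channels.copy(), self.trials.copy()
        )

    def equals(self, other: "EpochSet") -> bool:
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.times, other.times)
            and self.sfreq == other.sfreq
            and self.channels.equals(other.channels)
            and self.trials.reset_index(drop=True).equals(other.trials.reset_index(drop=True))
        )


# -- fixture container -----------------------------------------------------

def write_fixture(epochs: EpochSet, path) -> None:
    """Write an EpochSet to the HDF5 fixture container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = float(epochs.sfreq)
        ch = f.create_group("channels")
        for col in ("name", "type", "roi"):
            ch.create_dataset(col, data=epochs.channels[col].astype(str).to_numpy(dtype="S64"))
        tr = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            tr.create_dataset(col, data=epochs.trials[col].to_numpy(dtype=np.int64))


def read_fixture(path) -> EpochSet:
    """Read an EpochSet back; raises :class:`ParseError` naming any bad field."""
    with h5py.File(path, "r") as f:
        for key in ("data", "times", "channels", "trials"):
            if key not in f:
                raise ParseError(f"fixture missing field '{key}'")
        data = np.asarray(f["data"], dtype=np.float64)
        if data.ndim != 3:
            raise ParseError("field 'data' must be 3-dimensional")
        times = np.asarray(f["times"], dtype=np.float64)
        if len(times) != data.shape[2]:
            raise ParseError("field 'times' length does not match 'data'")
        if "sfreq" not in f.attrs:
            raise ParseError("fixture missing field 'sfreq'")
        sfreq = float(f.attrs["sfreq"])
        ch = {}
        for col in ("name", "type", "roi"):
            if col not in f["channels"]:
                raise ParseError(f"fixture missing field 'channels/{col}'")
            ch[col] = [s.decode() for s in f["channels"][col][()]]
        channels = pd.DataFrame(ch)
        if len(channels) != data.shape[1]:
            raise ParseError("field 'channels' length does not match 'data'")
        tr = {}
        for col in TRIAL_COLUMNS:
            if col not in f["trials"]:
                raise ParseError(f"fixture missing field 'trials/{col}'")
            arr = np.asarray(f["trials"][col], dtype=np.int64)
            if len(arr) != data.shape[0]:
                raise ParseError(f"field 'trials/{col}' length does not match 'data'")
            tr[col] = arr
        trials = pd.DataFrame(tr)
    for col in ("seen", "correct", "target_present"):
        trials[col] = trials[col].astype(bool)
    return EpochSet(data, times, sfreq, channels, trials)


def trials_to_tsv(trials: pd.DataFrame, path) -> None:
    out = trials[TRIAL_COLUMNS].copy()
    for col in ("seen", "correct", "target_present"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def trials_from_tsv(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ParseError(f"trial TSV missing columns {sorted(missing)}")
    for col in ("seen", "correct", "target_present"):
        trials[col] = trials[col].astype(bool)
    return trials
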