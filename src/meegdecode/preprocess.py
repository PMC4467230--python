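"""Normalization and subsetting of epoch sets.

The normalization deliberately follows the original recipe to the
letter: each channel is divided by a single scalar, the SD of its
baseline samples pooled across *all* trials, with no mean subtraction
(a ``demean`` flag is available but off by default).  This makes the
units of every channel type (magnetometer, gradiometer, EEG)
commensurable before they are fed jointly to the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet
from .errors import ConfigurationError

__all__ = ["BaselineSpec", "baseline_zscore", "resample_lowpass", "select_subset"]


@dataclass
class BaselineSpec:
    """Baseline window in ms (half-open), default the full pre-stimulus period."""

    window: tuple[float, float] = (-500.0, 0.0)


def baseline_zscore(epochs: EpochSet, spec: BaselineSpec | None = None, demean: bool = False) -> EpochSet:
    """Divide each channel by its pooled baseline SD.

    The SD is computed per channel over all trials' baseline samples
    jointly.  Raises if the baseline has fewer than 2 samples or if any
    channel's baseline SD is zero (the error names the channel).
    """
    spec = spec or BaselineSpec()
    mask = epochs.time_mask(spec.window)
    if mask.sum() < 2:
        raise ConfigurationError("baseline window must contain at least 2 samples")
    base = epochs.data[:, :, mask]  # trials x channels x base-samples
    pooled = base.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    sd = pooled.std(axis=1, ddof=0)
    mean = pooled.mean(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(epochs.channels["name"].iloc[zero])
        raise ValueError(f"zero baseline SD on channel(s): {names}")
    out = epochs.copy()
    if demean:
        out.data -= mean[None, :, None]
    out.data /= sd[None, :, None]
    return out


def resample_lowpass(epochs: EpochSet, cutoff_hz: float = 30.0, target_sfreq: float = 64.0) -> EpochSet:
    """Zero-phase FIR low-pass then polyphase resampling to ``target_sfreq``.

    Filter: Hamming-window FIR with transition bandwidth 25% of the
    cutoff, applied forward-backward (zero phase).  The trial table is
    unchanged; times are re-derived from the epoch start at the new rate.
    """
    if target_sfreq > epochs.sfreq:
        raise ConfigurationError("target_sfreq must not exceed the current rate")
    if cutoff_hz >= target_sfreq / 2:
        raise ConfigurationError("cutoff must be below the target Nyquist frequency")
    trans_bw = 0.25 * cutoff_hz
    numtaps = int(np.ceil(3.3 / (trans_bw / epochs.sfreq)))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    numtaps = min(numtaps, max(3, 2 * (epochs.n_times // 3) - 1))
    taps = signal.firwin(numtaps, cutoff_hz, window="hamming", fs=epochs.sfreq)
    filtered = signal.filtfilt(taps, [1.0], epochs.data, axis=2, padtype="even")

    if target_sfreq == epochs.sfreq:
        data = filtered
        times = epochs.times.copy()
    else:
        frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
        data = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=2)
        times = epochs.times[0] + np.arange(data.shape[2]) * 1000.0 / target_sfreq
    return EpochSet(data, times, target_sfreq, epochs.channels.copy(), epochs.trials.copy())


def select_subset(
    epochs: EpochSet,
    channel_filter=None,
    trial_filter=None,
    balance: list[str] | None = None,
    seed: int | None = None,
):
    """Subset channels/trials, optionally balancing factor cells.

    Parameters
    ----------
    channel_filter : None, dict, callable or sequence of names
        ``{"type": "eog"}`` keeps channels whose metadata column matches;
        a callable receives the channel table and returns a boolean mask.
    trial_filter : None, boolean mask, or callable on the trial table
    balance : list of trial-table column names
        When given, trials are subsampled without replacement (seeded)
        so that every cell of the factor crossing has the minimum cell
        count.  An empty cell raises, listing the cell.
    seed : int
        Required when ``balance`` is given.

    Returns
    -------
    (EpochSet, index_map) where index_map records the original trial and
    channel indices of everything kept.
    """
    ch_idx = np.arange(epochs.n_channels)
    if channel_filter is not None:
        if callable(channel_filter):
            mask = np.asarray(channel_filter(epochs.channels), dtype=bool)
        elif isinstance(channel_filter, dict):
            mask = np.ones(epochs.n_channels, dtype=bool)
            for col, val in channel_filter.items():
                mask &= (epochs.channels[col] == val).to_numpy()
        else:
            mask = epochs.channels["name"].isin(list(channel_filter)).to_numpy()
        ch_idx = np.flatnonzero(mask)
        if ch_idx.size == 0:
            raise ValueError("channel filter selected no channels")

    tr_idx = np.arange(epochs.n_trials)
    if trial_filter is not None:
        if callable(trial_filter):
            mask = np.asarray(trial_filter(epochs.trials), dtype=bool)
        else:
            mask = np.asarray(trial_filter, dtype=bool)
        tr_idx = np.flatnonzero(mask)

    if balance:
        if seed is None:
            raise ValueError("balancing requires a seed")
        sub = epochs.trials.iloc[tr_idx]
        groups = sub.groupby(balance, sort=True, observed=True).indices
        if not groups:
            raise ValueError("no trials to balance")
        # the full crossing of observed factor levels must be populated
        from itertools import product

        levels = [sorted(sub[col].unique(), key=str) for col in balance]
        expected = [c[0] if len(balance) == 1 else c for c in product(*levels)]
        empty = [c for c in expected if c not in groups]
        if empty:
            raise ValueError(f"empty balancing cell(s): {empty}")
        n_min = min(len(v) for v in groups.values())
        rng = np.random.default_rng(seed)
        keep = []
        for key in sorted(groups, key=str):
            local = np.sort(np.asarray(groups[key]))
            keep.append(np.sort(rng.choice(local, size=n_min, replace=False)))
        tr_idx = tr_idx[np.sort(np.concatenate(keep))]

    subset = epochs.sel(trial_idx=tr_idx, channel_idx=ch_idx)
    index_map = {"trials": tr_idx, "channels": ch_idx}
    return subset, index_map
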