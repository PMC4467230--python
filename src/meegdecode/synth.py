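"""Synthetic behavior and epoch generation.

This module emulates the world the analysis assumes so that every
downstream stage is testable without external recordings:

* a masked-localization observer with eight circularly arranged target
  locations, a logistic psychometric function for subjective visibility
  as a function of mask contrast, and blindsight-style forced-choice
  accuracy on unseen trials (far above the 1/8 guessing rate);
* sensor-level epochs in which a location-specific spatial pattern ramps
  up early (peaking ~147 ms), persists at reduced amplitude through a
  transition period, and then either (seen trials) hands over to an
  amplified chain of metastable, mutually decodable-distinct codes or
  (unseen trials) lingers as a single slowly decaying code;
* ROI-restricted variants in which each region's location information
  switches on at a region-specific latency, with the late amplification
  confined to "workspace" regions (superior parietal / superior frontal).

Noise is i.i.d. Gaussian per channel-sample (no 1/f structure); this
keeps analytic oracles tractable and is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .epochs import EpochSet, make_channel_table
from .errors import ConfigurationError, DomainError

__all__ = [
    "ObserverModel",
    "SignalRecipe",
    "simulate_behavior",
    "behavior_confusion",
    "generate_epochs",
    "generate_roi_epochs",
    "hemifield_of",
]

N_LOCATIONS = 8
CHANCE_8 = 1.0 / N_LOCATIONS

#: default first-information latency per region of interest (ms)
DEFAULT_ROI_ONSETS = {
    "pericalcarine": 115.0,
    "superior parietal": 115.0,
    "superior frontal": 194.0,
    "rostral medial frontal": 365.0,
}
DEFAULT_WORKSPACE_ROIS = ("superior parietal", "superior frontal")


@dataclass
class ObserverModel:
    """Behavioral observer: visibility psychometric + localization accuracy.

    ``contrast_threshold`` is the mask contrast (0-255 pixel-intensity
    scale) at which p(seen) = 0.5; stronger masks (higher contrast)
    reduce visibility.  ``p_correct_unseen`` above 1/8 is the blindsight
    regime.  ``p_error_detect`` is the probability that a seen but
    mislocalized trial's error is detected (used by the staircase's
    'Seen' classification rule).
    """

    contrast_threshold: float = 131.0
    psychometric_slope: float = 0.08
    p_correct_seen: float = 0.866
    p_correct_unseen: float = 0.507
    guess_uniform: bool = False
    p_error_detect: float = 1.0

    def __post_init__(self) -> None:
        if self.guess_uniform:
            self.p_correct_unseen = CHANCE_8
        for p in (self.p_correct_seen, self.p_correct_unseen, self.p_error_detect):
            if not 0.0 <= p <= 1.0:
                raise DomainError("probabilities must be in [0, 1]")
        if not self.p_correct_seen >= self.p_correct_unseen >= CHANCE_8:
            raise DomainError("expected p_correct_seen >= p_correct_unseen >= 1/8")

    def p_seen(self, contrast: float) -> float:
        """Logistic psychometric function of mask contrast."""
        return float(expit(self.psychometric_slope * (self.contrast_threshold - contrast)))


def simulate_behavior(
    observer: ObserverModel,
    contrast: float,
    n_trials: int,
    seed: int,
    n_absent: int = 0,
) -> pd.DataFrame:
    """Simulate one block of masked-localization trials at a fixed contrast.

    Returns a trial table with columns trial, location, seen, response,
    correct, target_present and error_detected.  Target-absent trials
    (appended last) have location 0, are never 'seen', and draw a uniform
    forced response.
    """
    if not 0.0 <= contrast <= 255.0:
        raise DomainError(f"contrast {contrast} outside 0-255")
    if n_trials <= 0:
        raise DomainError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    p_seen = observer.p_seen(contrast)

    location = rng.integers(1, N_LOCATIONS + 1, size=n_trials)
    seen = rng.random(n_trials) < p_seen
    response = np.empty(n_trials, dtype=np.int64)

    for mask, p_corr, uniform in (
        (seen, observer.p_correct_seen, False),
        (~seen, observer.p_correct_unseen, observer.guess_uniform),
    ):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        if uniform:
            response[idx] = rng.integers(1, N_LOCATIONS + 1, size=idx.size)
        else:
            correct = rng.random(idx.size) < p_corr
            response[idx[correct]] = location[idx[correct]]
            wrong = idx[~correct]
            # uniform over the 7 remaining locations
            offset = rng.integers(1, N_LOCATIONS, size=wrong.size)
            response[wrong] = (location[wrong] - 1 + offset) % N_LOCATIONS + 1

    correct = response == location
    error_detected = np.zeros(n_trials, dtype=bool)
    mis = seen & ~correct
    error_detected[mis] = rng.random(mis.sum()) < observer.p_error_detect

    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "location": location,
            "seen": seen,
            "response": response,
            "correct": correct,
            "target_present": True,
            "error_detected": error_detected,
        }
    )
    if n_absent:
        absent = pd.DataFrame(
            {
                "trial": np.arange(n_trials, n_trials + n_absent),
                "location": 0,
                "seen": False,
                "response": rng.integers(1, N_LOCATIONS + 1, size=n_absent),
                "correct": False,
                "target_present": False,
                "error_detected": False,
            }
        )
        table = pd.concat([table, absent], ignore_index=True)
    return table


def behavior_confusion(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """8x8 row-normalized location -> response confusion matrix per visibility."""
    out = {}
    present = trials[trials["target_present"]]
    for name, sub in (("seen", present[present["seen"]]), ("unseen", present[~present["seen"]])):
        mat = np.zeros((N_LOCATIONS, N_LOCATIONS))
        for loc, resp in zip(sub["location"], sub["response"]):
            mat[loc - 1, resp - 1] += 1
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            mat = np.where(sums > 0, mat / sums, 0.0)
        out[name] = mat
    return out


def hemifield_of(location: np.ndarray) -> np.ndarray:
    """Map circular locations 1-8 to hemifield labels (1-4 left, 5-8 right)."""
    return np.where(np.asarray(location) <= 4, "L", "R")


@dataclass
class SignalRecipe:
    """Parameters of the simulated neural signal.

    The epoch runs from -500 to +2000 ms at 64 Hz by default, with four
    stages: no information (0-115 ms), an early ramp peaking at 147 ms
    (115-162 ms), a transition at reduced amplitude (162-271 ms), and a
    late stage (271-800 ms) in which seen trials carry a chain of
    ``chain_states`` metastable, mutually orthogonal codes amplified by
    ``seen_gain`` while unseen trials carry only the single early code
    decaying exponentially with ``linger_decay_tau_ms``.  By default the
    lingering code is also present (unamplified) on seen trials, so the
    unseen codes are a subset of the seen ones.

    ``pattern_snr`` is the peak amplitude of the unit-norm spatial
    pattern relative to the unit per-channel noise SD.
    """

    n_trials: int = 400
    n_channels: int = 40
    n_eog: int = 2
    sfreq: float = 64.0
    epoch_window: tuple[float, float] = (-500.0, 2000.0)
    stage_windows: tuple[tuple[float, float], ...] = (
        (0.0, 115.0),
        (115.0, 162.0),
        (162.0, 271.0),
        (271.0, 800.0),
    )
    early_peak_ms: float = 147.0
    pattern_snr: float = 1.0
    stage3_gain: float = 0.75
    seen_gain: float = 2.0
    chain_states: int = 4
    state_duration_ms: float | None = None
    linger_decay_tau_ms: float = 550.0
    linger_on_seen: bool = True
    unseen_incorrect_snr_scale: float = 1.0
    ignition_amplitude: float = 0.0
    ignition_window: tuple[float, float] = (280.0, 600.0)
    ignition_seed: int | None = None  # share a topography across replicates
    noise_sd: float = 1.0
    roi_onsets_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROI_ONSETS))
    workspace_rois: tuple[str, ...] = DEFAULT_WORKSPACE_ROIS
    roi_n_channels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sfreq <= 0 or self.n_trials <= 0 or self.n_channels <= 0 or self.chain_states <= 0:
            raise ConfigurationError("counts and sfreq must be positive")
        t0, t1 = self.epoch_window
        prev_end = t0
        for a, b in self.stage_windows:
            if not (t0 <= a < b <= t1):
                raise ConfigurationError("stage windows must lie inside the epoch window")
            if a < prev_end:
                raise ConfigurationError("stage windows must be ordered and disjoint")
            prev_end = b
        span = self.stage_windows[3][1] - self.stage_windows[3][0]
        if self.state_duration_ms is None:
            self.state_duration_ms = span / self.chain_states
        elif self.chain_states * self.state_duration_ms > span + 1e-9:
            raise ConfigurationError(
                f"chain of {self.chain_states} x {self.state_duration_ms} ms "
                f"exceeds the {span} ms stage-4 span"
            )

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.sfreq / 1000.0))
        return t0 + np.arange(n) * 1000.0 / self.sfreq


def _location_patterns(n_signal_channels: int, chain_states: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm spatial patterns, shape (8, 1 + chain_states, n_sig).

    Row 0 is the early/lingering code; rows 1.. are the chained
    metastable codes.  Within a location all rows are mutually
    orthogonal, so chained codes are decodably distinct from each other
    and from the early code.
    """
    n_comp = 1 + chain_states
    if n_comp > n_signal_channels:
        raise ConfigurationError("need at least 1 + chain_states signal channels")
    pats = np.empty((N_LOCATIONS, n_comp, n_signal_channels))
    for loc in range(N_LOCATIONS):
        a = rng.standard_normal((n_signal_channels, n_comp))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))  # fix sign convention for determinism
        pats[loc] = q.T
    return pats


def _stage_envelopes(recipe: SignalRecipe, times: np.ndarray, onset_ms: float = -np.inf):
    """Amplitude envelopes over time (all gated to t >= onset_ms).

    Returns (base, linger, chains) where chains has shape (chain_states, n_times).
    """
    (s2a, s2b), (s3a, s3b) = recipe.stage_windows[1], recipe.stage_windows[2]
    s4a, _ = recipe.stage_windows[3]
    peak = recipe.early_peak_ms
    g3 = recipe.stage3_gain

    base = np.zeros_like(times)
    rise = (times >= s2a) & (times < min(peak, s2b))
    base[rise] = (times[rise] - s2a) / max(peak - s2a, 1e-9)
    fall = (times >= peak) & (times < s2b)
    base[fall] = 1.0 + (g3 - 1.0) * (times[fall] - peak) / max(s2b - peak, 1e-9)
    stage3 = (times >= s3a) & (times < s3b)
    base[stage3] = g3

    linger = np.zeros_like(times)
    s4 = (times >= s4a) & (times < recipe.stage_windows[3][1])
    linger[s4] = g3 * np.exp(-(times[s4] - s4a) / recipe.linger_decay_tau_ms)

    dur = recipe.state_duration_ms
    chains = np.zeros((recipe.chain_states, len(times)))
    for s in range(recipe.chain_states):
        a = s4a + s * dur
        b = min(a + dur, recipe.stage_windows[3][1])
        chains[s, (times >= a) & (times < b)] = 1.0

    gate = times >= onset_ms
    return base * gate, linger * gate, chains * gate


def _ignition(recipe: SignalRecipe, times: np.ndarray, n_sig: int):
    """Location-independent seen-only late component (off unless amplitude > 0).

    Emulates a generic conscious-access (P3-like) evoked response so the
    trial-averaged seen vs unseen contrast has a mean-field difference;
    drawn from its own seed stream so enabling it never perturbs the
    location patterns or the noise.
    """
    a, b = recipe.ignition_window
    env = np.zeros_like(times)
    m = (times >= a) & (times < b)
    env[m] = np.sin(np.pi * (times[m] - a) / (b - a)) ** 2  # raised-cosine lobe
    seed = recipe.seed if recipe.ignition_seed is None else recipe.ignition_seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    vec = rng.standard_normal(n_sig)
    return env, vec / np.linalg.norm(vec)


def _synthesize(
    recipe: SignalRecipe,
    behavior: pd.DataFrame,
    rng: np.random.Generator,
    patterns: np.ndarray,
    channels: pd.DataFrame,
    onset_ms: float = -np.inf,
    seen_gain: float | None = None,
) -> EpochSet:
    times = recipe.times
    n_tr = len(behavior)
    n_ch = len(channels)
    sig_idx = np.flatnonzero((channels["type"] != "eog").to_numpy())
    base, linger, chains = _stage_envelopes(recipe, times, onset_ms)
    ign_env, ign_vec = _ignition(recipe, times, len(sig_idx))
    gain = recipe.seen_gain if seen_gain is None else seen_gain

    data = recipe.noise_sd * rng.standard_normal((n_tr, n_ch, len(times)))
    loc = behavior["location"].to_numpy()
    seen = behavior["seen"].to_numpy(dtype=bool)
    correct = behavior["correct"].to_numpy(dtype=bool)
    present = behavior["target_present"].to_numpy(dtype=bool)
    for i in range(n_tr):
        if not present[i]:
            continue
        p = patterns[loc[i] - 1]
        scale = recipe.pattern_snr
        if not seen[i] and not correct[i]:
            scale *= recipe.unseen_incorrect_snr_scale
        amp0 = base.copy()
        if not seen[i] or recipe.linger_on_seen:
            amp0 = amp0 + linger
        sig = np.outer(p[0], amp0)
        if seen[i]:
            sig = sig + gain * (p[1:].T @ chains)
        data[i][sig_idx] += scale * sig
        if seen[i] and recipe.ignition_amplitude > 0:
            data[i][sig_idx] += recipe.ignition_amplitude * np.outer(ign_vec, ign_env)

    trials = behavior.reset_index(drop=True).copy()
    return EpochSet(data, times, recipe.sfreq, channels, trials)


def generate_epochs(recipe: SignalRecipe, behavior: pd.DataFrame) -> EpochSet:
    """Superpose the recipe's staged location codes onto channel noise.

    Deterministic given ``recipe.seed``: identical seeds give bitwise
    identical EpochSets.
    """
    present = behavior[behavior["target_present"]]
    counts = present["location"].value_counts()
    if len(present) and counts.min() < 1:
        raise ConfigurationError("need at least one trial per used location")
    rng = np.random.default_rng(np.random.SeedSequence(recipe.seed))
    channels = make_channel_table(recipe.n_channels, recipe.n_eog)
    n_sig = int((channels["type"] != "eog").sum())
    patterns = _location_patterns(n_sig, recipe.chain_states, rng)
    return _synthesize(recipe, behavior, rng, patterns, channels)


def generate_roi_epochs(recipe: SignalRecipe, behavior: pd.DataFrame) -> dict[str, EpochSet]:
    """One EpochSet per ROI; information is absent before the ROI's onset.

    The late (stage-4) ``seen_gain`` amplification is applied only in
    workspace ROIs; other regions carry the chain at unit gain.
    """
    out: dict[str, EpochSet] = {}
    t0, t1 = recipe.epoch_window
    for k, (roi, onset) in enumerate(sorted(recipe.roi_onsets_ms.items())):
        if not t0 <= onset <= t1:
            raise ConfigurationError(f"ROI '{roi}' onset {onset} ms outside the epoch window")
        rng = np.random.default_rng(np.random.SeedSequence(recipe.seed, spawn_key=(1000 + k,)))
        channels = make_channel_table(recipe.roi_n_channels, n_eog=0, roi=roi)
        patterns = _location_patterns(recipe.roi_n_channels, recipe.chain_states, rng)
        gain = recipe.seen_gain if roi in recipe.workspace_rois else 1.0
        out[roi] = _synthesize(
            recipe, behavior, rng, patterns, channels, onset_ms=onset, seen_gain=gain
        )
    return out
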