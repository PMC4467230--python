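"""Adaptive mask-contrast calibration (modified Levitt staircase).

Mask contrast (pixel intensity, 0-255) is adjusted block by block so
that the proportion of 'Seen' trials converges to 50%.  The step after
a block is proportional to (p_seen - 0.5): a block that is all seen or
all unseen moves the contrast by the full current maximum step (80 at
the start), and the maximum shrinks geometrically as blocks complete.
Calibration stops once a step falls below 1.5 intensity units or 80
trials have been run.  Block sizes follow the published schedule:
4, 4, 6, 8, then 10 per block.

A trial counts as 'Seen' if the observer reported seeing the target and
localized it correctly, or reported it seen, mislocalized it, but
detected the error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .synth import ObserverModel, simulate_behavior

__all__ = ["StaircaseConfig", "StaircaseState", "initial_state", "staircase_step", "run_calibration"]


@dataclass
class StaircaseConfig:
    initial_intensity: float = 230.0
    max_step: float = 80.0
    stop_step: float = 1.5
    max_trials: int = 80
    first_block_sizes: tuple[int, ...] = (4, 4, 6, 8)
    repeat_block_size: int = 10
    step_decay: float = 0.7  # multiplicative shrink of the max step per completed block

    def __post_init__(self):
        if not 0 <= self.initial_intensity <= 255:
            raise DomainError("initial intensity must be within 0-255")
        if self.stop_step >= self.max_step:
            raise DomainError("stop_step must be below max_step")
        if min(self.first_block_sizes) <= 0 or self.repeat_block_size <= 0:
            raise DomainError("block sizes must be positive")

    def block_size(self, block_index: int) -> int:
        if block_index < len(self.first_block_sizes):
            return self.first_block_sizes[block_index]
        return self.repeat_block_size


@dataclass
class StaircaseState:
    contrast: float
    block_index: int = 0
    trials_done: int = 0
    max_step_current: float = 80.0
    history: list = field(default_factory=list)
    stopped: bool = False
    stop_reason: str = ""


def initial_state(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(contrast=config.initial_intensity, max_step_current=config.max_step)


def staircase_step(state: StaircaseState, p_seen_block: float, config: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one completed block.

    More seen trials than 50% push the contrast up (stronger mask),
    fewer push it down; the contrast is clipped to [0, 255].
    """
    if state.stopped:
        raise RuntimeError("cannot step a stopped staircase")
    if not 0.0 <= p_seen_block <= 1.0:
        raise DomainError("p_seen_block must be in [0, 1]")
    step = state.max_step_current * (p_seen_block - 0.5) / 0.5
    step = float(np.clip(step, -state.max_step_current, state.max_step_current))
    contrast = float(np.clip(state.contrast + step, 0.0, 255.0))
    trials_done = state.trials_done + config.block_size(state.block_index)
    history = state.history + [
        {"block": state.block_index, "contrast": contrast, "p_seen": p_seen_block, "step": step}
    ]
    stopped, reason = False, ""
    if abs(step) < config.stop_step:
        stopped, reason = True, "step_converged"
    elif trials_done >= config.max_trials:
        stopped, reason = True, "max_trials"
    return StaircaseState(
        contrast=contrast,
        block_index=state.block_index + 1,
        trials_done=trials_done,
        max_step_current=state.max_step_current * config.step_decay,
        history=history,
        stopped=stopped,
        stop_reason=reason,
    )


def run_calibration(
    observer: ObserverModel, config: StaircaseConfig | None = None, seed: int = 0
) -> tuple[float, StaircaseState]:
    """Alternate simulated blocks with staircase steps until the stop rule fires."""
    config = config or StaircaseConfig()
    state = initial_state(config)
    ss = np.random.SeedSequence(seed)
    block = 0
    while not state.stopped:
        n = config.block_size(state.block_index)
        child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        trials = simulate_behavior(observer, state.contrast, n, seed=child)
        seen_rule = trials["seen"] & (trials["correct"] | trials["error_detected"])
        state = staircase_step(state, float(seen_rule.mean()), config)
        block += 1
    return state.contrast, state
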