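"""1-up-1-down adaptive staircase for perceptual intensity matching.

Implements the matching procedure used to equate the perceived intensity of
a comparison stimulus (visual contrast or auditory volume, normalized to
[0, 1]) with a reference vibration: after each trial the comparison moves
one fixed step down if it was judged more intense and one step up
otherwise, converging on the 50% point of the psychometric function — the
point of subjective equality (PSE).  A track ends after a fixed number of
reversals, a trial cap, or a plateau at maximum intensity; the PSE is the
mean of the final reversal intensities.

A simulated observer with a logistic psychometric function (plus lapses) is
provided for recovery testing of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import expit

__all__ = [
    "Response",
    "TerminationReason",
    "StaircaseConfig",
    "StaircaseState",
    "SimulatedObserver",
    "MatchResult",
    "StaircaseStateError",
    "EstimationError",
    "step_staircase",
    "staircase_finished",
    "pse_from_reversals",
    "run_simulated_staircase",
]


class Response(str, Enum):
    COMPARISON_MORE_INTENSE = "comparison_more_intense"
    VIBRATION_MORE_INTENSE = "vibration_more_intense"


class TerminationReason(str, Enum):
    REVERSALS = "reversals"
    TRIALS = "trials"
    PLATEAU = "plateau"


class StaircaseStateError(RuntimeError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StaircaseConfig:
    """Staircase parameters; intensities are fractions of the full range."""

    start_value: float = 0.5
    step: float = 0.05
    min_value: float = 0.0
    max_value: float = 1.0
    max_reversals: int = 8
    max_trials: int = 50
    max_plateau_window: int = 10
    n_reversals_for_pse: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.min_value < self.max_value <= 1:
            raise ValueError("require 0 <= min_value < max_value <= 1")
        if not 0 < self.step < (self.max_value - self.min_value):
            raise ValueError("step must be in (0, max-min)")
        if not self.min_value <= self.start_value <= self.max_value:
            raise ValueError("start_value outside bounds")
        if self.n_reversals_for_pse > self.max_reversals:
            raise ValueError("n_reversals_for_pse must be <= max_reversals")


@dataclass
class StaircaseState:
    """Mutable track state; ``history`` holds (presented value, response) pairs."""

    current_value: float
    history: list = field(default_factory=list)
    reversal_values: list = field(default_factory=list)
    direction: int = 0  # +1 up, -1 down, 0 undefined
    finished: bool = False
    termination_reason: TerminationReason | None = None


def new_staircase(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(current_value=config.start_value)


def step_staircase(state: StaircaseState, response: Response, config: StaircaseConfig) -> StaircaseState:
    """Apply one response: record the presented value, move one step, track reversals.

    The step direction is set by the response (comparison more intense ->
    down); a reversal is recorded, at the value presented on the turning
    trial, whenever that direction differs from the previous one.  Moves are
    clamped to the bounds; a clamped (no-movement) trial keeps its intended
    direction, so sitting at a bound does not accumulate reversals unless
    the direction actually flips later.
    """
    if state.finished:
        raise StaircaseStateError("cannot step a finished staircase")
    if not isinstance(response, Response):
        response = Response(response)
    presented = state.current_value
    state.history.append((presented, response))
    direction = -1 if response is Response.COMPARISON_MORE_INTENSE else 1
    if state.direction != 0 and direction != state.direction:
        state.reversal_values.append(presented)
    state.direction = direction
    moved = presented + direction * config.step
    state.current_value = float(min(max(moved, config.min_value), config.max_value))
    return state


def staircase_finished(state: StaircaseState, config: StaircaseConfig) -> tuple[bool, TerminationReason | None]:
    """Check the three termination rules, in priority order.

    Ends after ``max_reversals`` reversals, ``max_trials`` trials, or when
    every one of the last ``max_plateau_window`` presented values sat at the
    maximum bound (the observer cannot be matched within range).
    """
    if len(state.reversal_values) >= config.max_reversals:
        return True, TerminationReason.REVERSALS
    if len(state.history) >= config.max_trials:
        return True, TerminationReason.TRIALS
    w = config.max_plateau_window
    if len(state.history) >= w:
        last = [v for v, _ in state.history[-w:]]
        if all(v == config.max_value for v in last):
            return True, TerminationReason.PLATEAU
    return False, None


def pse_from_reversals(state: StaircaseState, config: StaircaseConfig) -> tuple[float, bool]:
    """PSE = mean of the final ``n_reversals_for_pse`` reversal intensities.

    With fewer reversals available, all of them are averaged and the
    estimate is flagged degraded.
    """
    revs = state.reversal_values
    if not revs:
        raise EstimationError(
            "no reversals recorded; track terminated by "
            f"{state.termination_reason} after {len(state.history)} trials"
        )
    k = config.n_reversals_for_pse
    degraded = len(revs) < k
    used = revs if degraded else revs[-k:]
    return float(np.mean(used)), degraded


@dataclass(frozen=True)
class SimulatedObserver:
    """Logistic observer: P(comparison judged more intense) rises with intensity.

    ``slope`` is the logistic scale in intensity units (0 gives a
    deterministic threshold observer); lapses flip to a coin with
    probability ``lapse_rate`` on both tails.
    """

    pse: float
    slope: float = 0.05
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5]")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")

    def p_comparison_more_intense(self, value: float) -> float:
        if self.slope == 0:
            core = 0.5 if value == self.pse else float(value > self.pse)
        else:
            core = float(expit((value - self.pse) / self.slope))
        return self.lapse_rate + (1 - 2 * self.lapse_rate) * core


@dataclass(frozen=True)
class MatchResult:
    pse_estimate: float
    n_trials: int
    termination_reason: TerminationReason
    n_reversals: int
    degraded: bool


def run_simulated_staircase(
    observer: SimulatedObserver,
    config: StaircaseConfig = StaircaseConfig(),
    rng: np.random.Generator | None = None,
) -> MatchResult:
    """Run one full track against the simulated observer (seed-deterministic)."""
    if rng is None:
        rng = np.random.default_rng()
    state = new_staircase(config)
    while True:
        p = observer.p_comparison_more_intense(state.current_value)
        response = (
            Response.COMPARISON_MORE_INTENSE
            if rng.random() < p
            else Response.VIBRATION_MORE_INTENSE
        )
        step_staircase(state, response, config)
        done, reason = staircase_finished(state, config)
        if done:
            state.finished = True
            state.termination_reason = reason
            break
    try:
        pse, degraded = pse_from_reversals(state, config)
    except EstimationError:
        # plateau with no reversal at all: report the bound, flagged degraded
        pse, degraded = config.max_value, True
    return MatchResult(
        pse_estimate=pse,
        n_trials=len(state.history),
        termination_reason=state.termination_reason,
        n_reversals=len(state.reversal_values),
        degraded=degraded,
    )
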