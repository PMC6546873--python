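"""Gap-detection psychophysics: transformed up-down staircase + listener.

The gap-detection task is a three-interval, three-alternative forced choice:
the listener picks the noise burst carrying a silent gap.  The adaptive rule
is the classical transformed up-down two-down/one-up procedure, which
converges on the stimulus level answered correctly with probability
``sqrt(1/2) = 0.707`` -- the 70.7% correct criterion.

The simulated listener draws responses from a psychometric function

    p(gap) = gamma + (1 - gamma) * F(gap; mu, beta)

with guess rate ``gamma = 1/3`` (3AFC) and ``F`` a logistic in the gap
duration with midpoint ``mu`` (ms) and slope ``beta`` (1/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

GUESS_RATE_3AFC = 1.0 / 3.0
NORMAL_GAP_RANGE_MS = (2.3, 7.5)


@dataclass
class Listener:
    """Simulated gap-detection listener with a logistic psychometric
    function; longer gaps are easier."""

    midpoint_ms: float = 5.0
    slope_per_ms: float = 1.0
    guess_rate: float = GUESS_RATE_3AFC

    def p_correct(self, gap_ms: float) -> float:
        f = 1.0 / (1.0 + math.exp(-self.slope_per_ms
                                  * (gap_ms - self.midpoint_ms)))
        return self.guess_rate + (1.0 - self.guess_rate) * f

    def respond(self, gap_ms: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(gap_ms))


@dataclass
class StaircaseConfig:
    """Two-down/one-up staircase schedule.

    Defaults follow conventional transformed up-down practice: start at an
    easy 8 ms gap, move in 2 ms steps, halve the step to 1 ms after 2
    reversals, and stop after 8 reversals; the threshold is the mean of the
    last 6 reversal gaps (all of which occur at the small step).
    """

    initial_gap_ms: float = 8.0
    step_ms: float = 2.0
    small_step_ms: float = 1.0
    reversals_to_shrink: int = 2
    n_reversals: int = 8
    n_threshold_reversals: int = 6
    floor_ms: float = 0.1
    max_trials: int = 400


@dataclass
class StaircaseState:
    gap_ms: float
    step_ms: float
    correct_streak: int = 0
    last_direction: int = 0            # -1 down, +1 up, 0 no change yet
    reversal_gaps: list = field(default_factory=list)
    n_trials: int = 0


@dataclass
class StaircaseResult:
    trials: list                       # (gap_ms, correct) per trial
    reversal_gaps: list
    threshold_ms: float | None
    converged: bool


def staircase_step(state: StaircaseState, correct: bool,
                   config: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one scored trial (pure function).

    Two consecutive correct responses lower the gap (and reset the streak);
    any incorrect response raises it.  A direction change relative to the
    previous gap change records a reversal at the pre-change gap, and the
    step shrinks once the configured reversal count is reached.
    """
    new = replace(state, reversal_gaps=list(state.reversal_gaps),
                  n_trials=state.n_trials + 1)
    direction = 0
    if correct:
        new.correct_streak += 1
        if new.correct_streak >= 2:
            direction = -1
            new.correct_streak = 0
    else:
        new.correct_streak = 0
        direction = +1
    if direction == 0:
        return new
    if state.last_direction != 0 and direction != state.last_direction:
        new.reversal_gaps.append(state.gap_ms)
        if len(new.reversal_gaps) == config.reversals_to_shrink:
            new.step_ms = config.small_step_ms
    new.gap_ms = max(config.floor_ms, state.gap_ms + direction * new.step_ms)
    new.last_direction = direction
    return new


def run_staircase(listener: Listener, config: StaircaseConfig | None = None,
                  seed: int | np.random.Generator = 0) -> StaircaseResult:
    """Run one adaptive track to its reversal budget.

    The threshold estimate is the mean of the last
    ``config.n_threshold_reversals`` reversal gaps, all of which lie past
    the step-size shrink.  A track that exhausts ``max_trials`` before the
    reversal budget comes back with ``converged=False`` and no threshold.
    """
    if config is None:
        config = StaircaseConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    state = StaircaseState(config.initial_gap_ms, config.step_ms)
    trials = []
    while (len(state.reversal_gaps) < config.n_reversals
           and state.n_trials < config.max_trials):
        correct = listener.respond(state.gap_ms, rng)
        trials.append((state.gap_ms, correct))
        state = staircase_step(state, correct, config)
    converged = len(state.reversal_gaps) >= config.n_reversals
    threshold = None
    if converged:
        tail = state.reversal_gaps[-config.n_threshold_reversals:]
        threshold = float(np.mean(tail))
    return StaircaseResult(trials, list(state.reversal_gaps), threshold,
                           converged)


def long_run_percent_correct(listener: Listener,
                             config: StaircaseConfig | None = None,
                             n_trials: int = 10000,
                             seed: int | np.random.Generator = 0) -> float:
    """Percent correct tracked by the rule once the staircase has converged.

    Runs one track to its reversal budget (discarded as burn-in), then keeps
    the adaptive rule running at the small step for ``n_trials`` further
    trials and returns the percentage answered correctly.  For the
    two-down/one-up rule this estimates the 70.7%-correct criterion
    independently of the listener's psychometric parameters.
    """
    if config is None:
        config = StaircaseConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    state = StaircaseState(config.initial_gap_ms, config.step_ms)
    while (len(state.reversal_gaps) < config.n_reversals
           and state.n_trials < config.max_trials):
        state = staircase_step(state, listener.respond(state.gap_ms, rng),
                               config)
    n_correct = 0
    draws = rng.random(n_trials)
    for u in draws:
        correct = bool(u < listener.p_correct(state.gap_ms))
        n_correct += correct
        state = staircase_step(state, correct, config)
    return 100.0 * n_correct / n_trials


def normal_range_check(threshold_ms: float,
                       normal_range=NORMAL_GAP_RANGE_MS) -> bool:
    """True when a gap-detection threshold lies inside the normal range
    (closed interval, 2.3-7.5 ms by default)."""
    lo, hi = normal_range
    return lo <= threshold_ms <= hi
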