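"""Adaptive 2-up-1-down staircase for auditory-perceptual thresholds.

The duration- and rhythm-discrimination tasks share one engine: the
stimulus deviation (the "level", in abstract deviation units -- larger is
easier) is raised by one step after each incorrect response and lowered by
one step after two successive correct responses.  This transformed
staircase converges on the level where the listener responds correctly
with probability 1/sqrt(2) ~ 70.7%.

A simulated observer with a logistic psychometric function stands in for a
human listener so the procedure can be exercised and validated end to end;
the threshold estimate is the mean level at the last few reversals
(default 6), the standard estimator for short tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_TRIALS = 43
DEFAULT_N_REVERSALS_USED = 6

#: Asymptotic percent-correct convergence point of the 2-up-1-down rule.
CONVERGENCE_P = 1 / np.sqrt(2)


@dataclass
class StaircaseConfig:
    """Staircase parameters.

    The start level defaults to roughly twice a typical child threshold on
    the rhythm-discrimination scale, with a step of 10% of the start.
    """

    n_trials: int = DEFAULT_N_TRIALS
    start_level: float = 40.0
    step: float = 4.0
    floor: float = 0.0
    ceiling: float = 80.0
    n_reversals_used: int = DEFAULT_N_REVERSALS_USED


@dataclass
class StaircaseTrack:
    """Trial-by-trial record of one adaptive track.

    ``levels[i]`` is the stimulus deviation presented on trial i;
    ``responses[i]`` the correctness of the response; ``reversals`` the
    trial indices at which the direction of actual level movement flipped.
    """

    config: StaircaseConfig
    levels: list[float] = field(default_factory=list)
    responses: list[bool] = field(default_factory=list)
    reversals: list[int] = field(default_factory=list)
    _consecutive_correct: int = 0
    _direction: int = 0  # sign of the last actual level change

    def __post_init__(self) -> None:
        if not self.levels:
            self.levels = [self.config.start_level]

    @property
    def n_completed(self) -> int:
        return len(self.responses)

    @property
    def done(self) -> bool:
        return self.n_completed >= self.config.n_trials

    @property
    def current_level(self) -> float:
        return self.levels[-1]

    @property
    def reversal_levels(self) -> list[float]:
        return [self.levels[i] for i in self.reversals]


def staircase_step(track: StaircaseTrack, correct: bool, step_size: float | None = None) -> StaircaseTrack:
    """Advance the staircase by one trial (mutates and returns ``track``).

    One incorrect response raises the level by one step (easier); two
    successive correct responses lower it (harder).  The correct-counter
    resets on every level change and on every error.  Levels are clamped
    to [floor, ceiling]; a clamped non-move records no reversal.
    """
    if track.done:
        raise ValueError("track already has the configured number of trials")
    cfg = track.config
    step = cfg.step if step_size is None else step_size
    track.responses.append(correct)
    level = track.current_level
    delta = 0.0
    if correct:
        track._consecutive_correct += 1
        if track._consecutive_correct >= 2:
            delta = -step
            track._consecutive_correct = 0
    else:
        delta = +step
        track._consecutive_correct = 0
    new_level = float(np.clip(level + delta, cfg.floor, cfg.ceiling))
    moved = new_level != level
    if moved:
        direction = 1 if new_level > level else -1
        if track._direction != 0 and direction != track._direction:
            track.reversals.append(track.n_completed - 1)
        track._direction = direction
    if not track.done:
        track.levels.append(new_level)
    return track


def estimate_threshold(
    track: StaircaseTrack, n_reversals_used: int | None = None
) -> float:
    """Mean level at the last ``n_reversals_used`` reversals (default 6).

    With fewer reversals than requested, all available reversals are used
    and a warning is raised; with none, the final level is returned.
    """
    n = track.config.n_reversals_used if n_reversals_used is None else n_reversals_used
    rev_levels = track.reversal_levels
    if len(rev_levels) == 0:
        warnings.warn("no reversals recorded; using final level", stacklevel=2)
        return track.current_level
    if len(rev_levels) < n:
        warnings.warn(
            f"only {len(rev_levels)} reversals available (requested {n})",
            stacklevel=2,
        )
        return float(np.mean(rev_levels))
    return float(np.mean(rev_levels[-n:]))


@dataclass(frozen=True)
class ObserverModel:
    """Logistic psychometric observer.

    P(correct at level x) = guess + (1 - guess - lapse) / (1 + exp(-slope (x - threshold)))

    ``threshold`` is the logistic midpoint in deviation units; larger
    deviations are easier, so the function is non-decreasing in the level
    (slope >= 0).
    """

    threshold: float
    slope: float = 1.0
    lapse_rate: float = 0.0
    guess_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.lapse_rate <= 1 and 0 <= self.guess_rate <= 1):
            raise ValueError("lapse and guess rates must be probabilities")
        if self.slope < 0:
            raise ValueError("slope must be >= 0 (higher level = easier)")

    def p_correct(self, level: float | np.ndarray) -> np.ndarray:
        from scipy.special import expit

        core = expit(self.slope * (np.asarray(level, float) - self.threshold))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core

    def level_at(self, p: float) -> float:
        """Level at which the observer is correct with probability ``p``."""
        core = (p - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)
        if not 0 < core < 1:
            raise ValueError(f"p={p} unreachable for this observer")
        if self.slope == 0:
            raise ValueError("flat observer has no unique level")
        return self.threshold + np.log(core / (1.0 - core)) / self.slope


def run_simulated_staircase(
    observer: ObserverModel,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int | np.random.Generator = 0,
    config: StaircaseConfig | None = None,
) -> StaircaseTrack:
    """Play the staircase against a simulated observer, reproducibly.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config or StaircaseConfig()
    cfg = StaircaseConfig(**{**cfg.__dict__, "n_trials": n_trials})
    track = StaircaseTrack(config=cfg)
    while not track.done:
        correct = bool(rng.random() < observer.p_correct(track.current_level))
        staircase_step(track, correct)
    return track


def track_to_frame(track: StaircaseTrack):
    """Trial table ``trial, level, response, reversal`` for the track file."""
    import pandas as pd

    n = track.n_completed
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "level": track.levels[:n],
            "response": track.responses,
            "reversal": [i in set(track.reversals) for i in range(n)],
        }
    )
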