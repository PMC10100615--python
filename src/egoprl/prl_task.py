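"""Three-armed probabilistic reversal learning (PRL) environment.

The task presents three options whose reward probabilities start at
90-50-10 and degrade to 80-40-20 halfway through, so that late losses are
harder to attribute to chance versus a contingency change.  The identity of
the best arm additionally permutes at unsignalled reversal trials.  Two
model-free statistics summarise choice behaviour: the win-switch rate
(switching away from an option that just paid out) and the lose-stay rate
(persisting with an option that just failed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ScheduleConfig",
    "RewardSchedule",
    "TaskSession",
    "DataError",
    "build_schedule",
    "win_switch_rate",
    "lose_stay_rate",
]


class DataError(ValueError):
    """Raised when observed session data violate the task's encoding."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration of the reward schedule.

    Trials are 1-indexed.  ``phase_switch_trial`` is the first trial of the
    second (degraded) contingency phase.  ``reversal_trials`` lists trials at
    which the assignment of contingencies to arms permutes; by default the
    assignment rotates, but an explicit permutation per reversal may be given
    via ``reversal_perms`` (``perm[i]`` is the index of the contingency slot
    that arm ``i`` takes after the reversal, relative to the current order).
    """

    n_trials: int = 160
    phase1_probs: Tuple[float, float, float] = (0.9, 0.5, 0.1)
    phase2_probs: Tuple[float, float, float] = (0.8, 0.4, 0.2)
    phase_switch_trial: int = 81
    reversal_trials: Tuple[int, ...] = (41, 121)
    reversal_perms: Optional[Tuple[Tuple[int, int, int], ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        for p in (*self.phase1_probs, *self.phase2_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward probability {p} outside [0, 1]")
        if not 1 <= self.phase_switch_trial <= self.n_trials:
            raise ValueError("phase_switch_trial outside 1..n_trials")
        if list(self.reversal_trials) != sorted(set(self.reversal_trials)):
            raise ValueError("reversal_trials must be strictly increasing")
        for t in self.reversal_trials:
            if not 1 <= t <= self.n_trials:
                raise ValueError(f"reversal trial {t} out of range")
        if self.reversal_perms is not None:
            if len(self.reversal_perms) != len(self.reversal_trials):
                raise ValueError("reversal_perms must align with reversal_trials")
            for perm in self.reversal_perms:
                if sorted(perm) != [0, 1, 2]:
                    raise ValueError(f"{perm} is not a permutation of (0, 1, 2)")


@dataclass(frozen=True)
class RewardSchedule:
    """Per-trial reward probability of each arm (shape ``(n_trials, 3)``)."""

    probs: np.ndarray
    config: ScheduleConfig

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]


@dataclass
class TaskSession:
    """One participant x frame run of the task.

    ``choices`` take values in {1, 2, 3}; ``outcomes`` in {0, 1} (loss/win).
    ``schedule`` is present for simulated sessions and absent for observed
    data, where the generating contingencies are unknown.
    """

    ego_id: str
    frame: str
    choices: np.ndarray
    outcomes: np.ndarray
    schedule: Optional[RewardSchedule] = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.int64)
        if self.choices.shape != self.outcomes.shape:
            raise DataError("choices and outcomes must have equal length")
        if self.choices.size < 1:
            raise DataError("session must contain at least one trial")
        if self.frame not in ("social", "nonsocial"):
            raise DataError(f"unknown frame {self.frame!r}")
        if not np.isin(self.choices, (1, 2, 3)).all():
            raise DataError("choices must lie in {1, 2, 3}")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise DataError("outcomes must lie in {0, 1}")

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)


def build_schedule(config: ScheduleConfig) -> RewardSchedule:
    """Construct the deterministic per-trial reward probability table.

    At every trial exactly one arm carries the highest probability provided
    the phase contingency triples are distinct (they are, by default).
    """
    probs = np.empty((config.n_trials, 3), dtype=float)
    order = [0, 1, 2]  # order[i] = contingency slot currently held by arm i
    reversals = dict(
        zip(
            config.reversal_trials,
            config.reversal_perms
            if config.reversal_perms is not None
            else [(2, 0, 1)] * len(config.reversal_trials),
        )
    )
    for t in range(1, config.n_trials + 1):
        if t in reversals:
            perm = reversals[t]
            order = [order[perm[i]] for i in range(3)]
        base = config.phase1_probs if t < config.phase_switch_trial else config.phase2_probs
        for i in range(3):
            probs[t - 1, i] = base[order[i]]
    return RewardSchedule(probs=probs, config=config)


def win_switch_rate(session: TaskSession) -> float:
    """Fraction of rewarded trials (with a successor) followed by a switch.

    Returns ``nan`` when the participant never won before the final trial,
    in which case the rate is undefined.
    """
    c, o = session.choices, session.outcomes
    eligible = o[:-1] == 1
    n = int(eligible.sum())
    if n == 0:
        return math.nan
    switched = (c[1:] != c[:-1]) & eligible
    return float(switched.sum()) / n


def lose_stay_rate(session: TaskSession) -> float:
    """Fraction of punished trials (with a successor) followed by a repeat.

    Returns ``nan`` when no losses occurred before the final trial.
    """
    c, o = session.choices, session.outcomes
    eligible = o[:-1] == 0
    n = int(eligible.sum())
    if n == 0:
        return math.nan
    stayed = (c[1:] == c[:-1]) & eligible
    return float(stayed.sum()) / n
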