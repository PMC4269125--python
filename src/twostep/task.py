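"""Two-step task environment.

A trial has two stages: a binary first-stage choice leads probabilistically to
one of two second-stage states (a *common* transition with probability
``p_common``, *rare* otherwise), where a second binary choice yields a 20-cent
win with a probability that drifts across trials.  The four win probabilities
(two states x two actions) follow independent Gaussian random walks with
reflecting boundaries, which is what forces continued learning throughout the
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "WalkSet",
    "TransitionOutcome",
    "generate_walks",
    "common_state_for",
    "step_transition",
    "step_reward",
    "compute_payout",
    "walks_to_csv",
    "walks_from_csv",
]

WALK_COLUMNS = ["p_s0a0", "p_s0a1", "p_s1a0", "p_s1a1"]


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the two-step task.

    Defaults encode the published design: 70/30 transition split, reward
    probabilities drifting between 0.25 and 0.75, 20 cents per win, and a
    payout of one third of winnings clamped to [3, 10] euros.
    """

    p_common: float = 0.70
    walk_lo: float = 0.25
    walk_hi: float = 0.75
    walk_sd: float = 0.025
    n_trials: int = 201
    reward_magnitude: float = 0.20
    payout_fraction: float = 1.0 / 3.0
    payout_min: float = 3.0
    payout_max: float = 10.0
    n_practice: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.walk_lo < self.walk_hi < 1.0):
            raise ValueError(
                f"need 0 < walk_lo < walk_hi < 1, got [{self.walk_lo}, {self.walk_hi}]"
            )
        if not (0.5 < self.p_common < 1.0 or self.p_common == 1.0):
            raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if self.n_trials <= 0:
            raise ValueError(f"n_trials must be positive, got {self.n_trials}")
        if self.payout_min > self.payout_max:
            raise ValueError("payout_min must not exceed payout_max")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be nonnegative")


@dataclass(frozen=True)
class WalkSet:
    """Reward-probability trajectories: array of shape (n_trials, 4).

    Column order is (state 0, action 0), (state 0, action 1),
    (state 1, action 0), (state 1, action 1).
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"probs must have shape (n_trials, 4), got {probs.shape}")
        object.__setattr__(self, "probs", probs)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class TransitionOutcome:
    stage2_state: int
    was_common: bool


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi], re-applying until all are inside."""
    x = np.asarray(x, dtype=float).copy()
    # each fold shrinks the excursion; loop terminates for finite input
    while True:
        below, above = x < lo, x > hi
        if not (below.any() or above.any()):
            return x
        x[below] = 2 * lo - x[below]
        x[above] = 2 * hi - x[above]


def generate_walks(
    config: TaskConfig,
    seed: int | np.random.Generator,
    start: np.ndarray | None = None,
) -> WalkSet:
    """Generate four independent reflecting Gaussian random walks.

    Parameters
    ----------
    config
        Task configuration; ``walk_sd`` is the per-trial step s.d. and
        [``walk_lo``, ``walk_hi``] the reflecting interval.
    seed
        Integer seed or an existing Generator.
    start
        Optional length-4 array of initial probabilities.  By default the
        starting values are drawn uniformly in the reflecting interval.
    """
    rng = np.random.default_rng(seed)
    if start is None:
        start = rng.uniform(config.walk_lo, config.walk_hi, size=4)
    else:
        start = np.asarray(start, dtype=float)
        if start.shape != (4,):
            raise ValueError("start must have shape (4,)")
        if ((start < config.walk_lo) | (start > config.walk_hi)).any():
            raise ValueError("start values must lie within [walk_lo, walk_hi]")
    probs = np.empty((config.n_trials, 4))
    probs[0] = start
    steps = rng.normal(0.0, config.walk_sd, size=(config.n_trials - 1, 4))
    for t in range(1, config.n_trials):
        probs[t] = _reflect(probs[t - 1] + steps[t - 1], config.walk_lo, config.walk_hi)
    return WalkSet(probs)


def common_state_for(action: int) -> int:
    """Fixed stage-1 action -> common stage-2 state mapping (identity)."""
    if action not in (0, 1):
        raise ValueError(f"action must be 0 or 1, got {action}")
    return action


def step_transition(
    action: int, config: TaskConfig, rng: np.random.Generator
) -> TransitionOutcome:
    """Draw the stage-2 state reached after a stage-1 action."""
    common = common_state_for(action)
    was_common = bool(rng.random() < config.p_common)
    state = common if was_common else 1 - common
    return TransitionOutcome(stage2_state=state, was_common=was_common)


def step_reward(
    state: int, action: int, trial: int, walks: WalkSet, rng: np.random.Generator
) -> int:
    """Bernoulli reward draw for a stage-2 (state, action) at a given trial."""
    if state not in (0, 1) or action not in (0, 1):
        raise ValueError(f"state/action must be 0 or 1, got {state}/{action}")
    if not 0 <= trial < walks.n_trials:
        raise IndexError(f"trial {trial} out of range for {walks.n_trials}-trial walks")
    p = walks.probs[trial, state * 2 + action]
    return int(rng.random() < p)


def compute_payout(total_reward_eur: float, config: TaskConfig) -> float:
    """Monetary payout: a third of the winnings, clamped to [payout_min, payout_max]."""
    if total_reward_eur < 0:
        raise ValueError(f"total reward must be nonnegative, got {total_reward_eur}")
    return float(
        np.clip(
            total_reward_eur * config.payout_fraction,
            config.payout_min,
            config.payout_max,
        )
    )


def walks_to_csv(walks: WalkSet, path) -> None:
    df = pd.DataFrame(walks.probs, columns=WALK_COLUMNS)
    df.insert(0, "trial", np.arange(walks.n_trials))
    df.to_csv(path, index=False, float_format="%.6f")


def walks_from_csv(path) -> WalkSet:
    df = pd.read_csv(path)
    missing = [c for c in WALK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"walk CSV missing columns: {missing}")
    probs = df[WALK_COLUMNS].to_numpy(dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("walk probabilities must lie in [0, 1]")
    return WalkSet(probs)
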