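"""Velocity-reversal random walks driven by tic indicators.

The walker starts at x = 0 with velocity +v (one position unit per second by
default) and advances in steps of dt seconds. At each step it either keeps
its velocity or reverses it. Three regimes:

* *tic-modulated*: the turn probability is the binary tic indicator — the
  velocity reverses exactly when a tic falls in the current bin. This walk
  is deterministic given the tic train.
* *ballistic* (p = 0): never turns; the straight-line, zero-tic limit.
* *Brownian* (p = 0.5): a fair coin at every step; the maximally chaotic
  limit in which tic and no-tic are equally likely at all times.

The initial direction is fixed at +1; a turn at step j flips the direction
used for the step from t_j to t_{j+1}. A tic in the very first bin coincides
with the walk's start and has no earlier velocity to reverse, so it does not
flip the initial direction (and is invisible to :func:`turn_count`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .session_io import TicIndicator

__all__ = ["WalkTrajectory", "TurnPolicy", "simulate_walk", "turn_count"]


@dataclass
class WalkTrajectory:
    """The (time, position) curve of one walker.

    ``positions`` has N+1 entries with ``positions[0] == 0``; every increment
    has magnitude exactly ``v * dt_s``. Times are implied: ``times[j] = j*dt_s``.
    """

    dt_s: float
    v: float
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_steps(self) -> int:
        return int(self.positions.size - 1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.size) * self.dt_s


@dataclass
class TurnPolicy:
    """What makes the walker reverse: a tic indicator, or a constant probability."""

    kind: str  # "tic_modulated" | "constant_p"
    indicator: Optional[TicIndicator] = None
    p: Optional[float] = None
    seed: Optional[int] = None

    @classmethod
    def tic_modulated(cls, indicator: TicIndicator) -> "TurnPolicy":
        return cls(kind="tic_modulated", indicator=indicator)

    @classmethod
    def constant_p(cls, p: float, seed: int) -> "TurnPolicy":
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"turn probability must be in [0, 1], got {p}")
        return cls(kind="constant_p", p=p, seed=seed)


def simulate_walk(policy: TurnPolicy, n_steps: Optional[int] = None,
                  dt_s: Optional[float] = None, v: float = 1.0) -> WalkTrajectory:
    """Simulate one walker under the given turn policy.

    For a tic-modulated policy ``n_steps`` and ``dt_s`` default to the
    indicator's; if given they must match. For constant-p policies both are
    required (``dt_s`` defaults to 0.1 s).
    """
    if policy.kind == "tic_modulated":
        ind = policy.indicator
        if ind is None:
            raise ValueError("tic_modulated policy requires an indicator")
        if n_steps is None:
            n_steps = ind.n_steps
        elif n_steps != ind.n_steps:
            raise ValueError(
                f"indicator length {ind.n_steps} != n_steps {n_steps}")
        if dt_s is None:
            dt_s = ind.dt_s
        elif abs(dt_s - ind.dt_s) > 1e-12 * ind.dt_s:
            raise ValueError(f"dt_s {dt_s} != indicator dt_s {ind.dt_s}")
        turns = ind.flags.copy()
    elif policy.kind == "constant_p":
        if n_steps is None:
            raise ValueError("constant_p policy requires n_steps")
        if dt_s is None:
            dt_s = 0.1
        rng = np.random.default_rng(policy.seed)
        turns = rng.random(n_steps) < policy.p
    else:
        raise ValueError(f"unknown policy kind {policy.kind!r}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")

    # direction for step j is +1 times (-1)^(number of turns fired in 1..j);
    # step 0 always uses the initial direction.
    turns[0] = False
    directions = np.where(np.cumsum(turns) % 2 == 0, 1.0, -1.0)
    positions = np.concatenate(([0.0], np.cumsum(directions) * v * dt_s))
    return WalkTrajectory(dt_s=dt_s, v=v, positions=positions)


def turn_count(trajectory: WalkTrajectory) -> int:
    """Number of velocity reversals visible in the trajectory.

    Counts steps whose direction differs from the previous step's; for a
    tic-modulated walk this equals the number of flagged bins (bin 0 aside).
    """
    d = np.sign(np.diff(trajectory.positions))
    return int(np.count_nonzero(d[1:] != d[:-1]))
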