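"""Random-exploration agent with specular boundary reflection.

The vehicle moves in discrete periods of length ``dt``. Within a period
its speed is constant; a fresh speed for the next period is drawn
uniformly on (0, v_max]. When a step segment crosses an arena wall the
path reflects specularly: the velocity component normal to the wall is
negated, the tangential component preserved. Corner hits are handled by
folding each axis independently, which applies both reflections.

Headings are measured in degrees clockwise from north (the +y axis),
matching the bearing convention used for landmark perception.

Heading policies (the free-space turning rule is a modelling choice; the
boundary reflection rule is not):

``wander``
    each period the heading is perturbed by a turn drawn uniformly on
    [-30 deg, +30 deg] (default; yields dense space-filling exploration),
``uniform``
    a fresh heading uniform on [0, 360) each period,
``fixed``
    the heading changes only through wall reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import Arena

__all__ = [
    "AgentState",
    "Trajectory",
    "HEADING_POLICIES",
    "step_agent",
    "simulate_trajectory",
    "read_trajectory_csv",
]

HEADING_POLICIES = ("wander", "uniform", "fixed")

#: half-width of the per-period turn under the ``wander`` policy, degrees
WANDER_TURN_DEG = 30.0


@dataclass(frozen=True)
class AgentState:
    """Vehicle pose: position (m), heading (deg CW from north), speed (m/s)."""

    x: float
    y: float
    heading: float
    speed: float


def _fold(p: float, length: float) -> tuple[float, int]:
    """Fold coordinate ``p`` into [0, length] by specular reflection.

    Returns the folded coordinate and the direction sign (+1 if the
    motion direction along this axis is preserved after an even number of
    reflections, -1 after an odd number).
    """
    period = 2.0 * length
    m = p % period
    if m > length:
        return period - m, -1
    return m, 1


def _draw_speed(rng: np.random.Generator, v_max: float) -> float:
    # 1 - U[0,1) lies in (0,1]; speed must be strictly positive
    return v_max * (1.0 - rng.random())


def step_agent(
    state: AgentState,
    arena: Arena,
    v_max: float,
    dt: float,
    rng: np.random.Generator,
    heading_policy: str = "wander",
) -> AgentState:
    """Advance the agent one location-update period.

    The heading is first updated per ``heading_policy``; the agent then
    travels ``state.speed * dt`` along it, reflecting specularly off any
    wall it meets (possibly several times). The returned state holds the
    post-reflection heading and a freshly drawn speed for the next
    period, so consecutive positions never differ by more than
    ``v_max * dt``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if v_max <= 0:
        raise ValueError(f"v_max must be > 0, got {v_max}")
    if heading_policy not in HEADING_POLICIES:
        raise ValueError(f"unknown heading policy {heading_policy!r}")

    heading = state.heading
    if heading_policy == "wander":
        heading = (heading + rng.uniform(-WANDER_TURN_DEG, WANDER_TURN_DEG)) % 360.0
    elif heading_policy == "uniform":
        heading = rng.uniform(0.0, 360.0)

    dist = state.speed * dt
    h = math.radians(heading)
    dx, dy = math.sin(h), math.cos(h)  # clockwise-from-north convention
    x, sx = _fold(state.x + dist * dx, arena.width)
    y, sy = _fold(state.y + dist * dy, arena.height)
    if sx < 0 or sy < 0:
        heading = math.degrees(math.atan2(dx * sx, dy * sy)) % 360.0

    return AgentState(x, y, heading, _draw_speed(rng, v_max))


class Trajectory:
    """Ordered sequence of post-step agent states, as parallel arrays."""

    def __init__(self, t, x, y, heading, speed):
        self.t = np.asarray(t, dtype=np.int64)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.heading = np.asarray(heading, dtype=float)
        self.speed = np.asarray(speed, dtype=float)

    def __len__(self) -> int:
        return len(self.t)

    def positions(self) -> np.ndarray:
        """(n, 2) array of positions."""
        return np.column_stack([self.x, self.y])

    def step_displacements(self) -> np.ndarray:
        """Euclidean displacement between consecutive recorded positions."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "heading": self.heading, "speed": self.speed}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.heading, other.heading)
            and np.array_equal(self.speed, other.speed)
        )


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(df["t"], df["x"], df["y"], df["heading"], df["speed"])


def simulate_trajectory(
    arena: Arena,
    n_steps: int,
    start: tuple[float, float] | None = None,
    v_max: float = 5.0,
    dt: float = 1.0,
    heading_policy: str = "wander",
    seed: int | np.random.SeedSequence | None = None,
) -> Trajectory:
    """Simulate a random exploration of ``n_steps`` location updates.

    ``start`` defaults to the arena centre. The initial heading is drawn
    uniformly and the initial speed uniformly on (0, v_max]. The recorded
    entry ``t`` holds the post-step state after update ``t`` (t = 0..n-1),
    so a length-1 trajectory is the position after one step.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if start is None:
        start = arena.center
    if not arena.contains(*start):
        raise ValueError(f"start {start} outside arena")
    rng = np.random.default_rng(seed)
    state = AgentState(start[0], start[1], rng.uniform(0.0, 360.0), _draw_speed(rng, v_max))
    t = np.arange(n_steps)
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    hs = np.empty(n_steps)
    vs = np.empty(n_steps)
    for i in range(n_steps):
        state = step_agent(state, arena, v_max, dt, rng, heading_policy)
        xs[i], ys[i], hs[i], vs[i] = state.x, state.y, state.heading, state.speed
    return Trajectory(t, xs, ys, hs, vs)
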