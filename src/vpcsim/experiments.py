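"""End-to-end simulation runs and parameter-sweep studies.

``run_single`` wires the pipeline: per location-update step, move the
agent, perceive the landmark annulus, evaluate the place-cell population
and apply the recruitment rule. ``sweep`` repeats runs across values of
one parameter with replicate trajectories, and ``trend_check`` tests the
qualitative orderings the model predicts (more cells for higher FRT,
fewer for wider recognition annuli or larger firing-field adjustment
factors, saturating growth with exploration length).

Randomness: a run's base ``seed`` deterministically derives one seed for
the landmark layout and one for the trajectory, so either source can
also be pinned explicitly (a sweep holds the landmark field fixed across
parameter values within a replicate while each replicate explores along
its own trajectory).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .agent import HEADING_POLICIES, AgentState, Trajectory, _draw_speed, step_agent
from .environment import Arena, LandmarkField, generate_landmark_field
from .fields import RateMap, population_map, rasterize_cell
from .perception import PlaceCode, perceive
from .placecell import (
    WEIGHT_NORMALIZATIONS,
    FiringParams,
    Population,
    maybe_recruit,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "TrendReport",
    "SWEEP_PARAMS",
    "run_single",
    "sweep",
    "trend_check",
]

logger = logging.getLogger("vpcsim")

#: sweep-able parameter names; "annulus" takes (d_min, d_max) pairs and
#: "afff" takes (sigma_d2, sigma_theta2) pairs
SWEEP_PARAMS = ("sigma_d2", "sigma_theta2", "frt", "annulus", "n_steps", "afff")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved configuration of one exploration run.

    Defaults are the baseline study conditions: a 40 m x 40 m arena with
    100 equal-saliency landmarks, a 10-15 m recognition annulus, a 4000
    step random walk at up to 5 m/s with 1 s updates, and firing
    parameters sigma_d2=25 m^2, sigma_theta2=100 deg^2, w_d=w_theta=1,
    FRT=0.2.
    """

    width: float = 40.0
    height: float = 40.0
    n_landmarks: int = 100
    saliency_mode: str = "equal"
    d_min: float = 10.0
    d_max: float = 15.0
    v_max: float = 5.0
    dt: float = 1.0
    heading_policy: str = "wander"
    n_steps: int = 4000
    sigma_d2: float = 25.0
    sigma_theta2: float = 100.0
    w_d: int = 1
    w_theta: int = 1
    frt: float = 0.2
    resolution: float = 0.5
    weight_normalization: str = "current"
    seed: int = 0
    landmark_seed: int | None = None  # derived from seed when None
    trajectory_seed: int | None = None
    start: tuple[float, float] | None = None  # arena centre when None

    @property
    def arena(self) -> Arena:
        return Arena(self.width, self.height)

    @property
    def firing_params(self) -> FiringParams:
        return FiringParams(self.sigma_d2, self.sigma_theta2, self.w_d, self.w_theta, self.frt)

    def resolved_seeds(self) -> tuple[int, int]:
        """(landmark_seed, trajectory_seed), derived from ``seed`` if unset."""
        derived = np.random.SeedSequence(self.seed).generate_state(2) % _SEED_MOD
        lm = self.landmark_seed if self.landmark_seed is not None else int(derived[0])
        tr = self.trajectory_seed if self.trajectory_seed is not None else int(derived[1])
        return lm, tr

    def validate(self) -> list[str]:
        """Collect all invariant violations (empty list = valid)."""
        problems: list[str] = []
        if not (self.width > 0 and self.height > 0):
            problems.append(f"width/height must be > 0, got {self.width} x {self.height}")
        if self.n_landmarks < 0:
            problems.append(f"n_landmarks must be >= 0, got {self.n_landmarks}")
        if self.saliency_mode not in ("equal", "uniform_random"):
            problems.append(f"unknown saliency_mode {self.saliency_mode!r}")
        if not 0 <= self.d_min < self.d_max:
            problems.append(f"need 0 <= d_min < d_max, got [{self.d_min}, {self.d_max}]")
        if self.v_max <= 0:
            problems.append(f"v_max must be > 0, got {self.v_max}")
        if self.dt <= 0:
            problems.append(f"dt must be > 0, got {self.dt}")
        if self.heading_policy not in HEADING_POLICIES:
            problems.append(f"unknown heading_policy {self.heading_policy!r}")
        if self.n_steps < 1:
            problems.append(f"n_steps must be >= 1, got {self.n_steps}")
        if not self.sigma_d2 > 0:
            problems.append(f"sigma_d2 must be > 0, got {self.sigma_d2}")
        if not self.sigma_theta2 > 0:
            problems.append(f"sigma_theta2 must be > 0, got {self.sigma_theta2}")
        if self.w_d not in (0, 1):
            problems.append(f"w_d must be 0 or 1, got {self.w_d}")
        if self.w_theta not in (0, 1):
            problems.append(f"w_theta must be 0 or 1, got {self.w_theta}")
        if not 0.0 <= self.frt <= 1.0:
            problems.append(f"frt must be in [0, 1], got {self.frt}")
        if self.resolution <= 0:
            problems.append(f"resolution must be > 0, got {self.resolution}")
        if self.weight_normalization not in WEIGHT_NORMALIZATIONS:
            problems.append(f"unknown weight_normalization {self.weight_normalization!r}")
        if self.start is not None and not problems[:1] and not self.arena.contains(*self.start):
            problems.append(f"start {self.start} outside arena")
        return problems

    def to_dict(self) -> dict:
        d = asdict(self)
        lm, tr = self.resolved_seeds()
        d["landmark_seed"], d["trajectory_seed"] = lm, tr
        if d["start"] is not None:
            d["start"] = list(d["start"])
        return d


@dataclass
class RunResult:
    """Everything one run produced (rate maps are computed on demand)."""

    config: RunConfig
    field: LandmarkField
    trajectory: Trajectory
    percepts: list[PlaceCode]
    population: Population
    winner_rates: np.ndarray  # pre-recruitment winner rate per step
    recruited: np.ndarray  # bool per step

    @property
    def n_vpcs(self) -> int:
        return len(self.population)

    def post_winner_rates(self) -> np.ndarray:
        """Winner rate per step after any recruitment at that step.

        A just-recruited cell fires at exactly 1 on its own percept, so
        recruited steps report 1.0.
        """
        return np.where(self.recruited, 1.0, self.winner_rates)

    def cell_rate_map(self, cell_id: int, resolution: float | None = None) -> RateMap:
        return rasterize_cell(
            self.population.cells[cell_id],
            self.trajectory,
            self.percepts,
            self.population.params,
            self.config.arena,
            resolution or self.config.resolution,
            self.config.weight_normalization,
        )

    def population_rate_map(self, resolution: float | None = None) -> RateMap:
        return population_map(
            self.cell_rate_map(c.cell_id, resolution) for c in self.population.cells
        )


def run_single(config: RunConfig) -> RunResult:
    """Execute one full exploration run; deterministic given the config."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid run configuration:\n  " + "\n  ".join(problems))
    arena = config.arena
    lm_seed, traj_seed = config.resolved_seeds()
    field_ = generate_landmark_field(arena, config.n_landmarks, config.saliency_mode, lm_seed)
    pop = Population(config.firing_params, config.weight_normalization)
    rng = np.random.default_rng(traj_seed)
    start = config.start if config.start is not None else arena.center
    state = AgentState(start[0], start[1], rng.uniform(0.0, 360.0), _draw_speed(rng, config.v_max))

    n = config.n_steps
    t = np.arange(n)
    xs = np.empty(n)
    ys = np.empty(n)
    hs = np.empty(n)
    vs = np.empty(n)
    percepts: list[PlaceCode] = []
    winner_rates = np.empty(n)
    recruited = np.zeros(n, dtype=bool)
    for i in range(n):
        state = step_agent(state, arena, config.v_max, config.dt, rng, config.heading_policy)
        xs[i], ys[i], hs[i], vs[i] = state.x, state.y, state.heading, state.speed
        code = perceive((state.x, state.y), field_, config.d_min, config.d_max, i)
        percepts.append(code)
        rec, rate = maybe_recruit(pop, code)
        winner_rates[i] = rate
        recruited[i] = rec
        if rec:
            logger.info(
                "step %d: recruited cell %d (winner rate %.4f, %d landmarks perceived)",
                i, len(pop) - 1, rate, code.n,
            )
        if (i + 1) % 1000 == 0:
            logger.info("step %d/%d: %d cells recruited", i + 1, n, len(pop))
    return RunResult(
        config, field_, Trajectory(t, xs, ys, hs, vs), percepts, pop, winner_rates, recruited
    )


def _apply_param(base: RunConfig, param: str, value) -> RunConfig:
    if param == "annulus":
        d_min, d_max = value
        return replace(base, d_min=float(d_min), d_max=float(d_max))
    if param == "afff":
        s_d2, s_th2 = value
        return replace(base, sigma_d2=float(s_d2), sigma_theta2=float(s_th2))
    if param == "n_steps":
        return replace(base, n_steps=int(value))
    if param in ("sigma_d2", "sigma_theta2", "frt"):
        return replace(base, **{param: float(value)})
    raise ValueError(f"unknown sweep parameter {param!r}; choose from {SWEEP_PARAMS}")


def _format_value(param: str, value) -> str:
    if param in ("annulus", "afff"):
        return f"{value[0]:g}-{value[1]:g}"
    return f"{value:g}"


def sweep(
    base: RunConfig,
    param: str,
    values: Sequence,
    replicates: int = 5,
    seeds: Sequence[int] | None = None,
    on_result=None,
) -> pd.DataFrame:
    """Run ``len(values) * replicates`` simulations varying one parameter.

    Within a replicate the landmark field is held fixed across all
    parameter values (isolating the parameter's effect); each replicate
    uses a distinct trajectory seed. ``seeds`` optionally pins the
    per-replicate seeds; otherwise they derive from ``base.seed``.
    ``on_result(value_label, replicate, result)`` is called after each
    run (e.g. to persist per-run outputs). Returns a tidy table with
    columns ``param,value,replicate,seed,n_vpcs``.
    """
    if param not in SWEEP_PARAMS:
        raise ValueError(f"unknown sweep parameter {param!r}; choose from {SWEEP_PARAMS}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if len(values) == 0:
        raise ValueError("values must be nonempty")
    if seeds is not None and len(seeds) != replicates:
        raise ValueError(f"need {replicates} seeds, got {len(seeds)}")
    if seeds is None:
        seeds = [int(s) for s in np.random.SeedSequence(base.seed).generate_state(replicates) % _SEED_MOD]
    rows = []
    for rep, rep_seed in enumerate(seeds):
        lm_seed, traj_seed = RunConfig(seed=rep_seed).resolved_seeds()
        for value in values:
            cfg = _apply_param(base, param, value)
            cfg = replace(cfg, seed=rep_seed, landmark_seed=lm_seed, trajectory_seed=traj_seed)
            result = run_single(cfg)
            label = _format_value(param, value)
            if on_result is not None:
                on_result(label, rep, result)
            rows.append(
                {
                    "param": param,
                    "value": label,
                    "replicate": rep,
                    "seed": rep_seed,
                    "n_vpcs": result.n_vpcs,
                }
            )
            logger.info("sweep %s=%s replicate %d: %d cells", param, rows[-1]["value"], rep, result.n_vpcs)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendReport:
    passed: bool
    direction: str
    values: tuple[str, ...]
    means: tuple[float, ...]
    detail: str

    def __bool__(self) -> bool:
        return self.passed


def trend_check(table: pd.DataFrame, direction: str) -> TrendReport:
    """Check the ordering of replicate-mean cell counts across values.

    ``increasing`` / ``decreasing`` require strictly ordered means in
    first-appearance order of the values; ``saturating`` requires
    strictly increasing means whose successive differences are
    non-increasing (growth that levels off).
    """
    if direction not in ("increasing", "decreasing", "saturating"):
        raise ValueError(f"unknown direction {direction!r}")
    order = table["value"].drop_duplicates().tolist()
    means = [table.loc[table["value"] == v, "n_vpcs"].mean() for v in order]
    diffs = np.diff(means)
    if direction == "increasing":
        ok = bool(np.all(diffs > 0))
        detail = "strictly increasing means" if ok else f"means not strictly increasing: {means}"
    elif direction == "decreasing":
        ok = bool(np.all(diffs < 0))
        detail = "strictly decreasing means" if ok else f"means not strictly decreasing: {means}"
    else:
        inc = bool(np.all(diffs > 0))
        sat = bool(np.all(np.diff(diffs) <= 0)) if len(diffs) > 1 else True
        ok = inc and sat
        detail = (
            "increasing with non-increasing gaps"
            if ok
            else f"not saturating (means {means}, gaps {diffs.tolist()})"
        )
    return TrendReport(ok, direction, tuple(order), tuple(float(m) for m in means), detail)
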