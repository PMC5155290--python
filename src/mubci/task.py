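"""Discrete-time simulation of the hover-dwell reach-and-grasp tasks.

The engine integrates a commanded velocity on a fixed tick, clips the cursor
to the square workspace, and selects a target once the (cursor or lagging
effector) position has remained continuously inside the target's hover disc
for the dwell duration.  Sequences chain a planar reach with a one-axis
descent; the shelf task chains two such pairs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import Outcome


@dataclass(frozen=True)
class TaskConfig:
    workspace: float = 32.0          # side of the square workspace, cm
    hover_radius: float = 3.0        # cm
    hover_duration: float = 2.0      # s (fast variant: 1)
    grasp_tolerance: float = 2.0     # cm, vertical step
    max_feedback: float = 12.0       # s
    prefeedback: float = 3.0         # s (cursor paradigm; 2.5 for robot)
    postfeedback: float = 1.0        # s
    iti: float = 2.0                 # s
    robot_speed: float = 8.0         # cm/s, also the ideal-policy speed
    robot_speed_max: float = 20.0    # cm/s, fast variant tracking limit
    fast_scale: float = 2.0 / 3.0
    tick: float = 0.040              # s, = decoder update interval
    approach_height: float = 17.0    # cm above the block for the grasp step
    grasp_block_cap: int = 13        # max blocks per fixed-target run
    random_block_cap: int = 10       # max blocks per random-target run
    shelf_block_cap: int = 6         # max blocks per shelf run
    exclusion_zones: tuple = ()      # polygons, each a tuple of (x, y) vertices
    robot_tracking: bool = False     # effector lags cursor at robot_speed limit

    def __post_init__(self) -> None:
        if self.hover_radius >= self.workspace / 2:
            raise ValueError("hover_radius must be smaller than half the workspace")
        if self.hover_duration >= self.max_feedback:
            raise ValueError("hover_duration must be shorter than max_feedback")
        for name in ("hover_duration", "max_feedback", "prefeedback",
                     "postfeedback", "iti", "tick"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def half(self) -> float:
        return self.workspace / 2.0

    def fast_variant(self) -> "TaskConfig":
        """Fast-shelf settings: 1 s hover, phases scaled to about two thirds."""
        s = self.fast_scale
        return replace(self, hover_duration=1.0, prefeedback=self.prefeedback * s,
                       postfeedback=self.postfeedback * s, iti=self.iti * s,
                       max_feedback=self.max_feedback * s,
                       robot_speed=self.robot_speed_max)


class TargetKind(enum.Enum):
    FIXED4 = "FIXED4"
    FIXED5 = "FIXED5"
    RANDOM = "RANDOM"
    SHELF_TABLE = "SHELF_TABLE"
    SHELF_SHELF = "SHELF_SHELF"


@dataclass(frozen=True)
class TargetSpec:
    position: tuple[float, float]
    kind: TargetKind = TargetKind.FIXED4
    block_size: tuple[float, float, float] = (4.5, 5.0, 10.0)

    def xy(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


def lr_layout(offset: float = 12.0) -> list[TargetSpec]:
    """Two lateral targets for the 1-D left/right paradigm."""
    return [TargetSpec((-offset, 0.0)), TargetSpec((offset, 0.0))]


def fixed4_layout(offset: float = 12.0) -> list[TargetSpec]:
    """Four targets at the edge midpoints: left, right, up, down."""
    return [TargetSpec((-offset, 0.0)), TargetSpec((offset, 0.0)),
            TargetSpec((0.0, offset)), TargetSpec((0.0, -offset))]


def fixed5_layout(offset: float = 12.0) -> list[TargetSpec]:
    """Four edge targets plus one at the workspace center."""
    return fixed4_layout(offset) + [TargetSpec((0.0, 0.0), TargetKind.FIXED5)]


def shelf_table_layout() -> list[TargetSpec]:
    """Three fixed block positions on the table plane."""
    return [TargetSpec((x, -8.0), TargetKind.SHELF_TABLE) for x in (-10.0, 0.0, 10.0)]


def shelf_shelf_layout() -> list[TargetSpec]:
    """Six target slots on the shelf (vertical) plane: 3 columns x 2 layers."""
    return [TargetSpec((x, y), TargetKind.SHELF_SHELF)
            for y in (6.0, -6.0) for x in (-10.0, 0.0, 10.0)]


def validate_layout(layout: list[TargetSpec], config: TaskConfig) -> None:
    if not layout:
        raise ValueError("target layout must be non-empty")
    for i, a in enumerate(layout):
        for b in layout[i + 1:]:
            if np.linalg.norm(a.xy() - b.xy()) < 2 * config.hover_radius:
                raise ValueError("hover discs overlap; layout rejected")


@dataclass
class TrialResult:
    outcome: Outcome
    time_to_hit: float
    trajectory: list[tuple[float, float, float]] = field(default_factory=list)
    selected_target: int | None = None

    def __post_init__(self) -> None:
        if self.outcome not in (Outcome.HIT, Outcome.MISS, Outcome.ABORT):
            raise ValueError("trial outcome must be HIT, MISS or ABORT")


@dataclass
class SequenceResult:
    steps: list[TrialResult]
    completed: bool
    total_time: float


class RobotTracker:
    """Effector chasing the commanded cursor position under a speed limit."""

    def __init__(self, position: np.ndarray, speed_limit: float):
        self.position = np.asarray(position, dtype=float).copy()
        self.speed_limit = speed_limit
        self.lag_log: list[float] = []

    def track(self, commanded: np.ndarray, dt: float) -> np.ndarray:
        err = np.asarray(commanded, dtype=float) - self.position
        dist = float(np.linalg.norm(err))
        if dist > 0.0:
            step = min(dist, self.speed_limit * dt)
            self.position = self.position + err * (step / dist)
        self.lag_log.append(float(np.linalg.norm(commanded - self.position)))
        return self.position


def _dwell_ticks_needed(config: TaskConfig) -> int:
    # continuous dwell of h seconds spans floor(h/tick)+1 position samples;
    # the selection rule below counts inside samples and fires when
    # (count - 1) * tick >= h, so hover_duration = 0 selects on first entry.
    return int(math.ceil(config.hover_duration / config.tick - 1e-9)) + 1


def run_trial(control_source, target_layout: list[TargetSpec], cued_target: int,
              config: TaskConfig, dims: int = 2,
              record_trajectory: bool = True) -> TrialResult:
    """One planar feedback phase: integrate velocity, hover to select.

    ``control_source`` is called as ``control_source(pos, t) -> (vx, vy)``
    once per tick.  A target is selected when the position stays inside its
    hover disc for ``hover_duration``; leaving the disc resets that
    target's dwell clock.  ``dims=1`` freezes the y axis (LR paradigm).
    """
    validate_layout(target_layout, config)
    if not 0 <= cued_target < len(target_layout):
        raise ValueError("cued_target out of range")
    centers = np.stack([t.xy() for t in target_layout])
    pos = np.zeros(2)
    robot = (RobotTracker(pos, config.robot_speed)
             if config.robot_tracking else None)
    needed = _dwell_ticks_needed(config)
    dwell = np.zeros(len(target_layout), dtype=int)
    traj: list[tuple[float, float, float]] = []
    if hasattr(control_source, "begin_step"):
        control_source.begin_step("planar", centers[cued_target], config)

    def check(p: np.ndarray, t: float) -> TrialResult | None:
        d = np.linalg.norm(centers - p[None, :], axis=1)
        inside = d <= config.hover_radius + 1e-12
        dwell[inside] += 1
        dwell[~inside] = 0
        done = np.flatnonzero(dwell >= needed)
        if done.size:
            sel = int(done[np.argmin(d[done])]) if done.size > 1 else int(done[0])
            out = Outcome.HIT if sel == cued_target else Outcome.MISS
            return TrialResult(out, t, traj, selected_target=sel)
        return None

    if record_trajectory:
        traj.append((0.0, pos[0], pos[1]))
    hit = check(robot.position if robot else pos, 0.0)
    if hit is not None:
        return hit
    n_ticks = int(round(config.max_feedback / config.tick))
    for i in range(n_ticks):
        v = np.asarray(control_source(pos.copy(), i * config.tick), dtype=float)
        if dims == 1:
            v = np.array([v[0], 0.0])
        pos = np.clip(pos + v * config.tick, -config.half, config.half)
        t = (i + 1) * config.tick
        eff = robot.track(pos, config.tick) if robot else pos
        if record_trajectory:
            traj.append((t, eff[0], eff[1]))
        hit = check(eff, t)
        if hit is not None:
            return hit
    return TrialResult(Outcome.ABORT, config.max_feedback, traj)


def run_vertical_trial(control_source, config: TaskConfig,
                       record_trajectory: bool = True) -> TrialResult:
    """One-axis descent: succeed by holding within grasp_tolerance of the
    block center (z = 0) for the dwell duration; no wrong target exists."""
    z = config.approach_height
    needed = _dwell_ticks_needed(config)
    dwell = 0
    traj: list[tuple[float, float, float]] = []
    if hasattr(control_source, "begin_step"):
        control_source.begin_step("vertical", np.array([0.0, 0.0]), config)
    n_ticks = int(round(config.max_feedback / config.tick))
    if record_trajectory:
        traj.append((0.0, 0.0, z))
    for i in range(n_ticks):
        v = np.asarray(control_source(np.array([0.0, z]), i * config.tick),
                       dtype=float)
        z = float(np.clip(z + v[1] * config.tick, 0.0, config.workspace))
        t = (i + 1) * config.tick
        if record_trajectory:
            traj.append((t, 0.0, z))
        if abs(z) <= config.grasp_tolerance + 1e-12:
            dwell += 1
            if dwell >= needed:
                return TrialResult(Outcome.HIT, t, traj, selected_target=0)
        else:
            dwell = 0
    return TrialResult(Outcome.ABORT, config.max_feedback, traj)


def run_grasp_sequence(control_source, layout: list[TargetSpec], cued: int,
                       config: TaskConfig) -> SequenceResult:
    """Reach (2-D hover) then grasp (1-D descent); fails fast on a miss."""
    reach = run_trial(control_source, layout, cued, config)
    steps = [reach]
    if reach.outcome is Outcome.HIT:
        steps.append(run_vertical_trial(control_source, config))
    completed = all(s.outcome is Outcome.HIT for s in steps) and len(steps) == 2
    phase_overhead = config.iti + config.prefeedback + config.postfeedback
    total = sum(s.time_to_hit + phase_overhead for s in steps)
    return SequenceResult(steps, completed, total)


def run_shelf_sequence(control_source, table_layout: list[TargetSpec],
                       shelf_layout: list[TargetSpec],
                       cued_pair: tuple[int, int],
                       config: TaskConfig) -> SequenceResult:
    """Reach-and-grasp on the table plane then reach-and-release on the
    shelf plane; the sequence stops at the first failed step."""
    if len(table_layout) != 3 or len(shelf_layout) != 6:
        raise ValueError("shelf task expects 3 table and 6 shelf positions")
    steps: list[TrialResult] = []
    plan = [
        ("planar", table_layout, cued_pair[0]),
        ("vertical", None, None),
        ("planar", shelf_layout, cued_pair[1]),
        ("vertical", None, None),
    ]
    for kind, layout, cued in plan:
        if kind == "planar":
            res = run_trial(control_source, layout, cued, config)
        else:
            res = run_vertical_trial(control_source, config)
        steps.append(res)
        if res.outcome is not Outcome.HIT:
            break
    completed = len(steps) == 4 and all(s.outcome is Outcome.HIT for s in steps)
    phase_overhead = config.iti + config.prefeedback + config.postfeedback
    total = sum(s.time_to_hit + phase_overhead for s in steps)
    return SequenceResult(steps, completed, total)


# ---------------------------------------------------------------------------
# control policies

class IdealPolicy:
    """Drives straight at the current step's target at the robot speed and
    stops exactly on it (never overshoots within a tick)."""

    def __init__(self, speed: float | None = None):
        self.speed = speed
        self._target = np.zeros(2)
        self._config: TaskConfig | None = None

    def begin_step(self, kind: str, target: np.ndarray, config: TaskConfig) -> None:
        self._target = np.asarray(target, dtype=float)
        self._config = config

    def __call__(self, pos: np.ndarray, t: float) -> np.ndarray:
        cfg = self._config
        speed = self.speed if self.speed is not None else cfg.robot_speed
        err = self._target - pos
        dist = float(np.linalg.norm(err))
        if dist == 0.0:
            return np.zeros(2)
        v = min(speed, dist / cfg.tick)
        return err * (v / dist)


class RandomWalkPolicy:
    """I.i.d. zero-mean Gaussian velocity per tick (chance-level policy)."""

    def __init__(self, sigma: float = 15.0, rng: np.random.Generator | None = None,
                 seed: int | None = None):
        self.sigma = sigma
        self.rng = rng if rng is not None else np.random.default_rng(seed)

    def begin_step(self, kind: str, target: np.ndarray, config: TaskConfig) -> None:
        pass

    def __call__(self, pos: np.ndarray, t: float) -> np.ndarray:
        return self.rng.standard_normal(2) * self.sigma


# ---------------------------------------------------------------------------
# random-target scheduler

def _point_in_polygon(p: np.ndarray, poly: np.ndarray) -> bool:
    x, y = p
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def default_exclusion_zones(workspace: float = 32.0,
                            fraction: float = 0.10) -> tuple:
    """Two corner triangles (top-left, bottom-right) of the given area
    fraction each, standing in for the arm's unreachable regions."""
    h = workspace / 2.0
    a = math.sqrt(2.0 * fraction) * workspace
    top_left = ((-h, h), (-h + a, h), (-h, h - a))
    bottom_right = ((h, -h), (h - a, -h), (h, -h + a))
    return (top_left, bottom_right)


class RandomTargetScheduler:
    """Quadrant-balanced quasi-uniform placement avoiding exclusion zones.

    Quadrants are cycled in a freshly shuffled order every block of four
    placements; within the chosen quadrant the position is uniform over the
    accessible region (rejection sampling against the exclusion polygons and
    a margin keeping the hover disc inside the workspace).
    """

    QUADS = ((1, 1), (-1, 1), (-1, -1), (1, -1))

    def __init__(self, config: TaskConfig, rng: np.random.Generator | None = None,
                 seed: int | None = None):
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self._order: list[int] = []
        self._polys = [np.asarray(p, dtype=float) for p in config.exclusion_zones]
        for q in range(4):
            if self._sample_quadrant(q, max_tries=2000, probe=True) is None:
                raise ValueError(f"exclusion zones cover quadrant {q}")

    def _accessible(self, p: np.ndarray) -> bool:
        return not any(_point_in_polygon(p, poly) for poly in self._polys)

    def _sample_quadrant(self, quad: int, max_tries: int = 1000,
                         probe: bool = False) -> np.ndarray | None:
        sx, sy = self.QUADS[quad]
        # keep the hover disc inside the workspace; quadrants meet at 0
        lo, hi = 0.0, self.config.half - self.config.hover_radius
        rng = np.random.default_rng(12345) if probe else self.rng
        for _ in range(max_tries):
            p = np.array([sx, sy]) * rng.uniform(lo, hi, size=2)
            if self._accessible(p):
                return p
        return None

    def next_target(self) -> TargetSpec:
        if not self._order:
            self._order = list(self.rng.permutation(4))
        quad = self._order.pop(0)
        p = self._sample_quadrant(quad)
        if p is None:
            raise ValueError(f"could not place a target in quadrant {quad}")
        return TargetSpec((float(p[0]), float(p[1])), TargetKind.RANDOM)


def place_random_target(scheduler: RandomTargetScheduler,
                        config: TaskConfig | None = None) -> TargetSpec:
    """Functional wrapper over :meth:`RandomTargetScheduler.next_target`."""
    return scheduler.next_target()
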