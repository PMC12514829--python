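"""Swim-tunnel protocol bookkeeping and performance indices.

An incremental-velocity (critical swimming speed) test holds the fish at
stepwise increasing water speeds, each step one flush/stabilize/measure
cycle long, until the fish is exhausted (completely refuses to swim for
more than 90 s).  The classical indices are

    U_crit = U_max   + v·T/t     (Brett)
    U_gait = U_steady + v·T/t

with v the velocity increment, t the full step duration, U_max the highest
fully completed speed (U_steady: highest fully completed *burst-free*
speed) and T the time endured into the step that ended the run (for
U_gait: time into the step at which the first kick-and-glide burst
occurred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .mo2 import Mo2Record
from .trace import SCHEDULE_SWIM, CycleSchedule, FishMeta

__all__ = [
    "StepProtocol",
    "VelocityStep",
    "SwimTrial",
    "build_protocol",
    "u_crit",
    "u_gait",
    "burst_metrics",
    "exhaustion_detect",
]

logger = logging.getLogger(__name__)

EXHAUSTION_INACTIVE_S = 90.0  # strict: inactive for MORE than 90 s

DEFAULT_START_BLS = 1.4
DEFAULT_INCREMENT_BLS = 0.15
DEFAULT_SETTLING_BLS = 1.2
DEFAULT_SETTLING_S = 25 * 60.0


@dataclass(frozen=True)
class StepProtocol:
    """Velocity-step schedule for one swim trial.

    The settling step (default 1.2 BL/s for 25 min) precedes the first
    measurement velocity and is flagged non-measurement.
    """

    velocities: tuple[float, ...]  # BL/s, step k = start + k·increment
    step_duration_s: float
    increment: float
    cycle: CycleSchedule = SCHEDULE_SWIM
    settling_velocity: float = DEFAULT_SETTLING_BLS
    settling_s: float = DEFAULT_SETTLING_S


def build_protocol(
    start: float = DEFAULT_START_BLS,
    increment: float = DEFAULT_INCREMENT_BLS,
    cycle: CycleSchedule = SCHEDULE_SWIM,
    n_steps: int = 15,
    settling_velocity: float = DEFAULT_SETTLING_BLS,
    settling_s: float = DEFAULT_SETTLING_S,
) -> StepProtocol:
    """Build the incremental-velocity schedule.

    Step k (k = 0, 1, …) runs at ``start + k·increment`` BL/s for the full
    cycle length (flush + stabilization + measure; 660 s with the default
    swim cycle).
    """
    if increment <= 0:
        raise ValidationError("velocity increment must be > 0")
    if start <= 0 or n_steps < 1:
        raise ValidationError("need start > 0 and n_steps >= 1")
    velocities = tuple(start + k * increment for k in range(n_steps))
    return StepProtocol(
        velocities=velocities,
        step_duration_s=cycle.cycle_s,
        increment=increment,
        cycle=cycle,
        settling_velocity=settling_velocity,
        settling_s=settling_s,
    )


@dataclass
class VelocityStep:
    """One velocity step's log."""

    index: int
    velocity: float  # BL/s
    start_time: float  # s from trial start
    duration_completed: float  # s actually endured at this step
    mo2_record: Mo2Record | None = None
    bursts: int = 0
    burst_time: float = 0.0  # total s of kick-and-glide at this step
    first_burst_s: float | None = None  # s into the step of the first burst

    def __post_init__(self) -> None:
        if self.velocity < 0 or self.duration_completed < 0:
            raise ValidationError("velocity and duration_completed must be >= 0")


@dataclass
class SwimTrial:
    """Complete swim-trial event log for one fish at one PO₂ level."""

    fish: FishMeta
    po2_level: float  # % air saturation
    steps: list[VelocityStep]
    step_duration_s: float
    increment: float
    settling_velocity: float = DEFAULT_SETTLING_BLS
    exhausted: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = [s.velocity for s in self.steps]
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValidationError("steps must strictly increase in velocity")

    def completed_steps(self) -> list[VelocityStep]:
        return [
            s
            for s in self.steps
            if s.duration_completed >= self.step_duration_s - 1e-9
        ]

    @property
    def first_burst_step(self) -> int | None:
        for s in self.steps:
            if s.bursts > 0:
                return s.index
        return None


def u_crit(trial: SwimTrial) -> float:
    """Critical swimming speed U_max + v·T/t, BL/s.

    T = 0 collapses to U_max; T = t is equivalent to having completed the
    next step.  A fish exhausted before completing any full step is
    reported at the settling velocity with a warning.
    """
    completed = trial.completed_steps()
    t = trial.step_duration_s
    v = trial.increment
    if not completed:
        logger.warning(
            "fish %s exhausted before the first full step; U_crit reported "
            "as the settling velocity",
            trial.fish.id,
        )
        failed = trial.steps[0] if trial.steps else None
        endured = failed.duration_completed if failed else 0.0
        return trial.settling_velocity + v * min(endured, t) / t
    u_max = completed[-1].velocity
    if not trial.exhausted:
        return u_max  # completed every step it was given
    failed = next(
        (
            s
            for s in trial.steps
            if s.duration_completed < trial.step_duration_s - 1e-9
        ),
        None,
    )
    endured = failed.duration_completed if failed is not None else 0.0
    return u_max + v * min(endured, t) / t


def u_gait(trial: SwimTrial) -> float | None:
    """Gait transition speed U_steady + v·T/t, or None without bursts.

    U_steady is the highest fully completed burst-free speed before the
    first burst; T is the time into the following step at which the first
    burst occurred.  Bursting already at the first step falls back to the
    settling velocity (flagged).
    """
    burst_steps = [s for s in trial.steps if s.bursts > 0]
    if not burst_steps:
        logger.info("fish %s: no gait transition observed", trial.fish.id)
        if "no_gait_transition" not in trial.flags:
            trial.flags.append("no_gait_transition")
        return None
    first = min(burst_steps, key=lambda s: s.index)
    t = trial.step_duration_s
    v = trial.increment
    T = first.first_burst_s if first.first_burst_s is not None else 0.0
    steady_candidates = [
        s
        for s in trial.completed_steps()
        if s.index < first.index and s.bursts == 0
    ]
    if not steady_candidates:
        logger.warning(
            "fish %s burst at its first step; U_gait from the settling velocity",
            trial.fish.id,
        )
        if "burst_at_first_step" not in trial.flags:
            trial.flags.append("burst_at_first_step")
        return trial.settling_velocity + v * min(T, t) / t
    u_steady = max(s.velocity for s in steady_candidates)
    return u_steady + v * min(T, t) / t


@dataclass(frozen=True)
class BurstMetrics:
    total_bursts: int
    bursts_per_min: float
    burst_time_fraction: float
    active_swim_time_s: float


def burst_metrics(trial: SwimTrial) -> BurstMetrics:
    """Burst counts and kick-and-glide time, per active swimming minute.

    Active swimming time is the summed endured duration of the measured
    velocity steps (the settling period is excluded).
    """
    active = float(sum(s.duration_completed for s in trial.steps))
    total = int(sum(s.bursts for s in trial.steps))
    burst_time = float(sum(s.burst_time for s in trial.steps))
    if active <= 0:
        return BurstMetrics(0, 0.0, 0.0, 0.0)
    return BurstMetrics(
        total_bursts=total,
        bursts_per_min=total / (active / 60.0),
        burst_time_fraction=burst_time / active,
        active_swim_time_s=active,
    )


def exhaustion_detect(
    activity,
    t0: float = 0.0,
    step_start: float = 0.0,
    threshold_s: float = EXHAUSTION_INACTIVE_S,
) -> tuple[float, float] | None:
    """Find exhaustion in a binary swimming/inactive log at 1 Hz.

    ``activity``: 1 = swimming, 0 = inactive, one sample per second
    starting at trial time ``t0``.  Exhaustion is the start of the first
    inactive run lasting strictly more than ``threshold_s`` seconds.
    Returns ``(exhausted_time, endured_T)`` with ``endured_T`` measured
    from ``step_start``, or None when the fish never met the rule.
    """
    a = np.asarray(activity).astype(bool)
    if a.ndim != 1:
        raise ValidationError("activity log must be 1-D")
    inactive = ~a
    run_start = None
    run_len = 0
    for i, off in enumerate(inactive):
        if off:
            if run_start is None:
                run_start = i
            run_len += 1
            if run_len > threshold_s:
                exhausted_time = t0 + run_start
                return exhausted_time, exhausted_time - step_start
        else:
            run_start = None
            run_len = 0
    return None
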