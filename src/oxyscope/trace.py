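"""Trial data model: oxygen traces, trial metadata and cycle segmentation.

An intermittent-flow respirometry trial alternates an open *flush* phase
(chamber replenished from the reservoir) with a sealed phase.  The first
part of the sealed phase is a *stabilization* window discarded from rate
fitting; the remainder is the *measure* window whose oxygen decline yields
the oxygen consumption rate.  ``segment_cycles`` cuts a continuous trace
into those windows from the trial's nominal schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .units import _UNITS, WaterConditions

__all__ = [
    "OxygenReading",
    "FishMeta",
    "ChamberSpec",
    "CycleSchedule",
    "OxygenTrace",
    "MeasurementCycle",
    "segment_cycles",
    "read_trace_csv",
    "write_trace_csv",
    "load_trial_config",
]

logger = logging.getLogger(__name__)

PHASE_FLUSH = "flush"
PHASE_STABILIZATION = "stabilization"
PHASE_MEASURE = "measure"


@dataclass(frozen=True)
class OxygenReading:
    """A single timestamped oxygen reading."""

    time: float  # s from trial start
    o2: float
    unit: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("reading time must be >= 0")
        if self.unit not in _UNITS:
            raise ValidationError(f"unknown oxygen unit {self.unit!r}")


@dataclass
class FishMeta:
    """Identity and morphometrics of one individual."""

    id: str
    body_weight: float  # g
    total_length: float  # cm
    standard_length: float | None = None
    treatment: str = "cold_2C"

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be positive")
        if self.total_length <= 0:
            raise ValidationError("total_length must be positive")

    @property
    def is_blank(self) -> bool:
        """Blank (fishless) control runs are tagged with id ``BLANK``."""
        return self.id.upper().startswith("BLANK")


@dataclass
class ChamberSpec:
    """Respirometer geometry.

    ``fish_volume_displacement`` defaults to body weight / 1000 L
    (≈ 1 g/mL tissue density) when left as None and a fish is present;
    pass 0.0 to disable the correction.
    """

    respirometer_volume: float  # L
    fish_volume_displacement: float | None = None
    kind: str = "static_chamber"

    def __post_init__(self) -> None:
        if self.kind not in ("static_chamber", "swim_tunnel"):
            raise ValidationError(f"unknown chamber kind {self.kind!r}")
        if self.respirometer_volume <= 0:
            raise ValidationError("respirometer_volume must be positive")
        if self.fish_volume_displacement is not None:
            if not 0 <= self.fish_volume_displacement < self.respirometer_volume:
                raise ValidationError(
                    "need respirometer_volume > fish_volume_displacement >= 0"
                )

    def effective_volume(self, fish: FishMeta | None = None) -> float:
        """Water volume actually holding dissolved oxygen, L."""
        displacement = self.fish_volume_displacement
        if displacement is None:
            displacement = 0.0
            if fish is not None and not fish.is_blank:
                displacement = fish.body_weight / 1000.0
        v_eff = self.respirometer_volume - displacement
        if v_eff <= 0:
            raise ValidationError("effective chamber volume must be positive")
        return v_eff


@dataclass(frozen=True)
class CycleSchedule:
    """Nominal phase durations of one flush/seal cycle, seconds."""

    flush_s: float
    stabilization_s: float
    measure_s: float

    def __post_init__(self) -> None:
        if min(self.flush_s, self.stabilization_s) < 0 or self.measure_s <= 0:
            raise ValidationError(
                "phase durations must be >= 0 and measure_s > 0"
            )

    @property
    def cycle_s(self) -> float:
        return self.flush_s + self.stabilization_s + self.measure_s


# Schedules used in the study this package targets: long cycles at 2 °C
# (5 min flush + 30.5 min sealed, first 200 s discarded), short at 10 °C,
# and the swim-tunnel step cycle (60 s flush, 120 s stabilisation, 8 min
# measure → 660 s per velocity step).
SCHEDULE_COLD_2C = CycleSchedule(flush_s=300, stabilization_s=200, measure_s=1630)
SCHEDULE_WARM_10C = CycleSchedule(flush_s=150, stabilization_s=200, measure_s=850)
SCHEDULE_SWIM = CycleSchedule(flush_s=60, stabilization_s=120, measure_s=480)


@dataclass
class OxygenTrace:
    """One chamber or tunnel trial's oxygen time series with its metadata."""

    time: np.ndarray  # s from trial start, strictly increasing
    o2: np.ndarray
    unit: str
    conditions: WaterConditions
    chamber: ChamberSpec
    fish: FishMeta
    schedule: CycleSchedule
    po2_level: float | None = None  # nominal % air saturation of the step
    has_gaps: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.shape != self.o2.shape or self.time.ndim != 1:
            raise ValidationError("time and o2 must be equal-length 1-D arrays")
        if self.unit not in _UNITS:
            raise ValidationError(f"unknown oxygen unit {self.unit!r}")
        if self.time.size:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValidationError("reading times must be strictly increasing")
            if dt.size:
                nominal = float(np.median(dt))
                if np.any(dt > 1.5 * nominal):
                    self.has_gaps = True
                    logger.warning(
                        "trace %s: sampling gaps detected (max step %.1f s, "
                        "nominal %.1f s)",
                        self.fish.id,
                        float(dt.max()),
                        nominal,
                    )

    @property
    def dt(self) -> float:
        """Nominal sampling interval, s."""
        if self.time.size < 2:
            return 1.0
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        """Trace span including the final sample's own interval, s."""
        if not self.time.size:
            return 0.0
        return float(self.time[-1] - self.time[0]) + self.dt


@dataclass(frozen=True)
class MeasurementCycle:
    """One flush/seal cycle cut from a trace.

    Windows are half-open ``[start, end)`` in trace time; the measure
    window starts ``stabilization_s`` after the seal.
    """

    index: int
    flush: tuple[float, float]
    stabilization: tuple[float, float]
    measure: tuple[float, float]
    complete: bool

    def measure_samples(
        self, trace: OxygenTrace, interpolate_gaps: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, o2) inside the measure window.

        Interior sampling gaps are filled by linear interpolation onto the
        trace's nominal grid — only inside the window, never across phase
        boundaries.
        """
        t0, t1 = self.measure
        mask = (trace.time >= t0) & (trace.time < t1)
        t = trace.time[mask]
        o2 = trace.o2[mask]
        if interpolate_gaps and t.size >= 2:
            dt = trace.dt
            if np.any(np.diff(t) > 1.5 * dt):
                grid = np.arange(t[0], t[-1] + 0.5 * dt, dt)
                o2 = np.interp(grid, t, o2)
                t = grid
        return t, o2


def segment_cycles(trace: OxygenTrace) -> list[MeasurementCycle]:
    """Cut a trace into flush/stabilization/measure cycles.

    Cycles are laid out back-to-back from the trace start according to the
    trace's nominal schedule.  Gapless traces yield
    ``floor(duration / cycle_length)`` complete cycles; a trailing partial
    cycle is appended flagged ``complete=False``.  A trace shorter than one
    cycle returns an empty list with a warning.
    """
    if trace.schedule is None:
        raise ValidationError("trace has no cycle schedule")
    sched = trace.schedule
    if not trace.time.size:
        logger.warning("empty trace %s: no cycles", trace.fish.id)
        return []
    origin = float(trace.time[0])
    duration = trace.duration
    n_complete = int(np.floor(duration / sched.cycle_s))
    if n_complete == 0:
        logger.warning(
            "trace %s shorter than one cycle (%.0f s < %.0f s)",
            trace.fish.id,
            duration,
            sched.cycle_s,
        )
    cycles: list[MeasurementCycle] = []
    n_total = n_complete + (1 if duration - n_complete * sched.cycle_s > 0 else 0)
    for k in range(n_total):
        start = origin + k * sched.cycle_s
        f_end = start + sched.flush_s
        s_end = f_end + sched.stabilization_s
        m_end = s_end + sched.measure_s
        cycles.append(
            MeasurementCycle(
                index=k,
                flush=(start, f_end),
                stabilization=(f_end, s_end),
                measure=(s_end, m_end),
                complete=k < n_complete,
            )
        )
    return cycles


# ---------------------------------------------------------------------------
# File I/O — fixed CSV dialect (comma-separated, header row, UTF-8) and a
# YAML trial-metadata config.

def write_trace_csv(trace: OxygenTrace, path) -> None:
    """Write a trace as CSV with columns time_s, o2, unit, chamber_id."""
    pd.DataFrame(
        {
            "time_s": trace.time,
            "o2": trace.o2,
            "unit": trace.unit,
            "chamber_id": trace.fish.id,
        }
    ).to_csv(path, index=False)


def read_trace_csv(
    path,
    conditions: WaterConditions,
    chamber: ChamberSpec,
    fish: FishMeta,
    schedule: CycleSchedule,
    po2_level: float | None = None,
) -> OxygenTrace:
    """Read a trace CSV (columns time_s, o2, unit; optional phase, chamber_id)."""
    df = pd.read_csv(path)
    for col in ("time_s", "o2", "unit"):
        if col not in df.columns:
            raise ValidationError(f"trace CSV missing required column {col!r}")
    units = df["unit"].unique()
    if len(units) != 1:
        raise ValidationError("trace CSV mixes oxygen units")
    return OxygenTrace(
        time=df["time_s"].to_numpy(float),
        o2=df["o2"].to_numpy(float),
        unit=str(units[0]),
        conditions=conditions,
        chamber=chamber,
        fish=fish,
        schedule=schedule,
        po2_level=po2_level,
    )


def load_trial_config(path):
    """Load trial metadata from YAML.

    Expected top-level keys: ``fish``, ``chamber``, ``conditions``,
    ``schedule`` and optionally ``po2_level``.  Returns the corresponding
    dataclasses in that order (po2_level last, None if absent).
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    fish = FishMeta(**cfg["fish"])
    chamber = ChamberSpec(**cfg["chamber"])
    conditions = WaterConditions(**cfg["conditions"])
    schedule = CycleSchedule(**cfg["schedule"])
    return fish, chamber, conditions, schedule, cfg.get("po2_level")
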