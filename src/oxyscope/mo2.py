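"""Oxygen consumption (ṀO₂) extraction from sealed-phase declines.

The sealed-phase decline in chamber oxygen concentration is fitted by
ordinary least squares; the (positive) depletion slope is scaled to a
whole-animal rate by the effective water volume, corrected for background
(bacterial) respiration measured in blank runs, and allometrically
normalized to a 100 g reference mass:

    ṀO₂        = slope · 3600 · V_eff / BW            [µmol O₂ / g·h]
    ṀO₂(100)   = ṀO₂ · (BW / 100)^(1 − b),  b = 0.8 by default
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .trace import ChamberSpec, FishMeta, MeasurementCycle, OxygenTrace, segment_cycles
from .units import KPA, PERCENT_AIRSAT, UMOL_PER_L, WaterConditions, convert_o2

__all__ = [
    "Mo2Record",
    "BackgroundModel",
    "fit_o2_decline",
    "mo2_from_slope",
    "correct_background",
    "mass_normalize",
    "extract_mo2_records",
    "estimate_blank_rate",
]

logger = logging.getLogger(__name__)

MIN_READINGS = 30

#: Default allometric scaling exponent for mass normalization.
DEFAULT_SCALING_EXPONENT = 0.8

#: Background corrections eating more than this fraction of the raw rate
#: are flagged suspect.
SUSPECT_CORRECTION_FRACTION = 0.20


@dataclass
class Mo2Record:
    """One measurement cycle's extracted metabolic rate."""

    fish_id: str
    cycle_index: int
    mo2_raw: float  # µmol O₂/g·h, background-corrected
    mo2_normalized: float  # ṀO₂(100), µmol O₂/g·h at 100 g reference mass
    mean_po2_kpa: float
    mean_po2_percent: float
    fit_r2: float
    phase_context: str = "rest_chamber"  # or "swim_step"
    velocity: float | None = None  # BL/s, swim steps only
    flags: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return "invalid" not in self.flags


@dataclass
class BackgroundModel:
    """Blank (fishless) respiration model: a whole-chamber rate.

    ``method`` records whether blanks ran interleaved/before the trial
    (``empty_chamber``) or after it (``post_test``); both reduce to the
    same scalar subtraction, they differ only in which blank runs feed
    ``blank_rate``.
    """

    method: str = "empty_chamber"
    blank_rate: float = 0.0  # µmol O₂/h per chamber, NOT mass-specific
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in ("empty_chamber", "post_test"):
            raise ValidationError(f"unknown background method {self.method!r}")
        if self.blank_rate < 0:
            raise ValidationError("blank_rate must be >= 0")


def fit_o2_decline(
    time: np.ndarray, conc_umol_l: np.ndarray
) -> tuple[float, float] | None:
    """OLS fit of concentration (µmol/L) vs time (s) over a measure window.

    Returns ``(slope, r²)`` with the slope reported as a positive
    depletion rate (µmol/L per s), or None when the window has fewer than
    30 readings (skipped with a warning).  Non-finite readings are
    rejected outright.
    """
    time = np.asarray(time, float)
    conc = np.asarray(conc_umol_l, float)
    if not (np.isfinite(time).all() and np.isfinite(conc).all()):
        raise ValidationError("non-finite readings in measure window")
    if time.size < MIN_READINGS:
        logger.warning(
            "measure window with %d < %d readings skipped", time.size, MIN_READINGS
        )
        return None
    t = time - time.mean()
    slope = float(t @ (conc - conc.mean()) / (t @ t))
    resid = conc - conc.mean() - slope * t
    ss_tot = float(((conc - conc.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return -slope, r2


def mo2_from_slope(
    slope: float, chamber: ChamberSpec, fish: FishMeta
) -> float:
    """Whole-animal mass-specific rate from a depletion slope.

    slope in µmol/L per s → µmol O₂/g·h using the chamber's effective
    volume and the fish's body weight.
    """
    if slope < 0:
        raise ValidationError("depletion slope must be >= 0")
    v_eff = chamber.effective_volume(fish)
    return slope * 3600.0 * v_eff / fish.body_weight


def correct_background(
    mo2_raw: float,
    background: BackgroundModel,
    chamber: ChamberSpec,
    fish: FishMeta,
) -> tuple[float, list[str]]:
    """Subtract blank-chamber respiration from a raw rate.

    The blank rate is a whole-chamber µmol O₂/h, divided by body weight to
    stay unit-consistent with the mass-specific rate.  Returns the
    corrected rate and any flags (``suspect_background`` above a 20%
    correction fraction, ``invalid`` if the correction exceeds the raw
    rate).
    """
    correction = background.blank_rate / fish.body_weight
    corrected = mo2_raw - correction
    flags: list[str] = []
    if mo2_raw > 0:
        fraction = correction / mo2_raw
        if fraction > SUSPECT_CORRECTION_FRACTION:
            flags.append("suspect_background")
        logger.debug("background correction fraction %.3f", fraction)
    if corrected < 0:
        flags.append("invalid")
    return corrected, flags


def mass_normalize(
    mo2: float, body_weight: float, b: float = DEFAULT_SCALING_EXPONENT
) -> float:
    """Allometric normalization to a 100 g reference mass.

    ṀO₂(100) = ṀO₂ · (BW/100)^(1−b); with b = 1 this is the identity.
    """
    if body_weight <= 0:
        raise ValidationError("body_weight must be positive")
    if not 0 < b <= 1:
        raise ValidationError("scaling exponent b must be in (0, 1]")
    return mo2 * (body_weight / 100.0) ** (1.0 - b)


def estimate_blank_rate(
    blank_traces,
    method: str = "empty_chamber",
) -> BackgroundModel:
    """Fit blank (fishless) traces and pool them into a BackgroundModel.

    Each blank trace goes through the same decline-fit path as fish
    trials; its slope scales to a whole-chamber µmol O₂/h.  Multiple
    blanks are pooled by their mean.
    """
    rates = []
    ids = []
    for trace in blank_traces:
        v = trace.chamber.effective_volume(trace.fish)
        for cycle in segment_cycles(trace):
            if not cycle.complete:
                continue
            t, o2 = cycle.measure_samples(trace)
            conc = convert_o2(o2, trace.unit, UMOL_PER_L, trace.conditions)
            fit = fit_o2_decline(t, conc)
            if fit is None:
                continue
            slope, _ = fit
            rates.append(max(slope, 0.0) * 3600.0 * v)
            ids.append(trace.fish.id)
    blank_rate = float(np.mean(rates)) if rates else 0.0
    return BackgroundModel(method=method, blank_rate=blank_rate, provenance=tuple(ids))


def extract_mo2_records(
    trace: OxygenTrace,
    background: BackgroundModel | None = None,
    b: float = DEFAULT_SCALING_EXPONENT,
    phase_context: str = "rest_chamber",
    velocity: float | None = None,
    r2_threshold: float | None = None,
) -> list[Mo2Record]:
    """Full per-trace pipeline: segment → fit → correct → normalize.

    ``r2_threshold`` optionally flags low-r² cycles (off by default; no
    cutoff is applied unless requested).
    """
    background = background or BackgroundModel(blank_rate=0.0)
    conditions: WaterConditions = trace.conditions
    records: list[Mo2Record] = []
    for cycle in segment_cycles(trace):
        if not cycle.complete:
            continue
        t, o2 = cycle.measure_samples(trace)
        conc = convert_o2(o2, trace.unit, UMOL_PER_L, conditions)
        fit = fit_o2_decline(t, conc)
        if fit is None:
            continue
        slope, r2 = fit
        mo2_raw = mo2_from_slope(max(slope, 0.0), trace.chamber, trace.fish)
        corrected, flags = correct_background(
            mo2_raw, background, trace.chamber, trace.fish
        )
        if slope < 0:
            flags.append("negative_slope")
        if r2_threshold is not None and r2 < r2_threshold:
            flags.append("low_r2")
        mean_conc = float(np.mean(conc))
        records.append(
            Mo2Record(
                fish_id=trace.fish.id,
                cycle_index=cycle.index,
                mo2_raw=corrected,
                mo2_normalized=mass_normalize(
                    max(corrected, 0.0), trace.fish.body_weight, b
                ),
                mean_po2_kpa=float(
                    convert_o2(mean_conc, UMOL_PER_L, KPA, conditions)
                ),
                mean_po2_percent=float(
                    convert_o2(mean_conc, UMOL_PER_L, PERCENT_AIRSAT, conditions)
                ),
                fit_r2=r2,
                phase_context=phase_context,
                velocity=velocity,
                flags=flags,
            )
        )
    return records


def records_to_frame(records) -> "pd.DataFrame":
    """Tabulate Mo2Records (one row per cycle) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "fish_id": r.fish_id,
                "cycle": r.cycle_index,
                "po2_percent": r.mean_po2_percent,
                "po2_kpa": r.mean_po2_kpa,
                "mo2_raw": r.mo2_raw,
                "mo2_100": r.mo2_normalized,
                "r2": r.fit_r2,
                "phase_context": r.phase_context,
                "velocity": r.velocity,
                "flags": ";".join(r.flags),
            }
            for r in records
        ]
    )
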