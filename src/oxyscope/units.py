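"""Water conditions and dissolved-oxygen unit conversions.

Respirometry data move between three equivalent expressions of ambient
oxygen: percent air saturation, dissolved concentration (µmol O₂/L) and
partial pressure (kPa).  All conversions are linear once two anchors are
fixed for the water in question: the concentration at 100% air saturation
(``sat_concentration``) and the O₂ partial pressure at 100% air saturation
(``sat_po2``).  Both anchors can be supplied directly — e.g. to reproduce a
published equivalence exactly — or derived from temperature, salinity and
barometric pressure via a seawater solubility model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "PERCENT_AIRSAT",
    "KPA",
    "UMOL_PER_L",
    "WaterConditions",
    "saturation_concentration",
    "saturation_po2",
    "water_vapor_pressure_kpa",
    "convert_o2",
]

#: Unit tags accepted throughout the package.
PERCENT_AIRSAT = "percent_airsat"
KPA = "kPa"
UMOL_PER_L = "umol_per_L"

_UNITS = (PERCENT_AIRSAT, KPA, UMOL_PER_L)

#: Mole fraction of O₂ in dry air.
O2_MOLE_FRACTION = 0.2095

#: Molar volume of an ideal gas at STP, L/mol (converts mL/L to µmol/L).
_MOLAR_VOLUME_STP = 22.3916

# García & Gordon (1992) O₂ solubility fit, Benson–Krause data,
# C* in mL(STP)/L; valid roughly T ∈ [-2, 40] °C, S ∈ [0, 42].
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_GG_B = (-0.00624523, -0.00737614, -0.0103410, -0.00817083)
_GG_C0 = -4.88682e-7

_STANDARD_PRESSURE_KPA = 101.325


def water_vapor_pressure_kpa(temperature: float, salinity: float = 0.0) -> float:
    """Saturated water vapor pressure in kPa (Buck equation, seawater-corrected).

    The salinity correction (−0.0537% per PSU) follows the usual vapour
    pressure depression of seawater.
    """
    t = temperature
    p_pure = 0.61121 * math.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return p_pure * (1.0 - 0.000537 * salinity)


def _gg_solubility_ml_per_l(temperature: float, salinity: float) -> float:
    ts = math.log((298.15 - temperature) / (273.15 + temperature))
    ln_c = sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    ln_c += _GG_C0 * salinity * salinity
    return math.exp(ln_c)


@dataclass
class WaterConditions:
    """Physical state of the experimental water.

    Parameters
    ----------
    temperature
        Water temperature, °C. Must lie in [−2, 40] (solubility-model range).
    salinity
        Practical salinity, PSU (≥ 0).
    barometric_pressure
        Total air pressure, kPa. Default 101.325.
    sat_concentration
        Dissolved O₂ at 100% air saturation, µmol/L. If given, it overrides
        the solubility model (use this to pin a published anchor value).
    sat_po2
        O₂ partial pressure at 100% air saturation, kPa. If given it
        overrides the default ``(P_baro − P_H2O) × 0.2095``.
    """

    temperature: float
    salinity: float
    barometric_pressure: float = _STANDARD_PRESSURE_KPA
    sat_concentration: float | None = field(default=None)
    sat_po2: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not -2.0 <= self.temperature <= 40.0:
            raise ValidationError(
                f"temperature {self.temperature} °C outside the supported "
                "range [-2, 40]"
            )
        if self.salinity < 0:
            raise ValidationError(f"salinity must be >= 0, got {self.salinity}")
        if self.barometric_pressure <= 0:
            raise ValidationError("barometric_pressure must be positive")
        if self.sat_concentration is None:
            self.sat_concentration = saturation_concentration(self)
        elif self.sat_concentration <= 0:
            raise ValidationError("sat_concentration must be positive")
        if self.sat_po2 is None:
            self.sat_po2 = saturation_po2(self)
        if not 0 < self.sat_po2 < self.barometric_pressure:
            raise ValidationError(
                "sat_po2 must lie in (0, barometric_pressure), got "
                f"{self.sat_po2}"
            )


def saturation_concentration(conditions: WaterConditions) -> float:
    """Dissolved O₂ concentration at 100% air saturation, µmol/L.

    Uses the García–Gordon seawater solubility fit (Benson–Krause
    coefficients) with a moist-air pressure correction for non-standard
    barometric pressure.  A user-supplied ``sat_concentration`` on the
    conditions is returned unchanged.
    """
    if conditions.sat_concentration is not None:
        return conditions.sat_concentration
    ml_per_l = _gg_solubility_ml_per_l(conditions.temperature, conditions.salinity)
    umol_per_l = ml_per_l * 1000.0 / _MOLAR_VOLUME_STP
    pw = water_vapor_pressure_kpa(conditions.temperature, conditions.salinity)
    scale = (conditions.barometric_pressure - pw) / (_STANDARD_PRESSURE_KPA - pw)
    return umol_per_l * scale


def saturation_po2(conditions: WaterConditions) -> float:
    """O₂ partial pressure at 100% air saturation, kPa.

    Standard respirometry convention: the O₂ mole fraction of dry air
    applied to barometric pressure minus saturated water vapour pressure.
    """
    if conditions.sat_po2 is not None:
        return conditions.sat_po2
    pw = water_vapor_pressure_kpa(conditions.temperature, conditions.salinity)
    return (conditions.barometric_pressure - pw) * O2_MOLE_FRACTION


def convert_o2(
    value,
    from_unit: str,
    to_unit: str,
    conditions: WaterConditions,
):
    """Convert dissolved-oxygen values between units.

    Scalar or numpy-array ``value``; conversions are linear through the
    100%-air-saturation anchors of ``conditions``.  Round-trips are exact
    to floating-point precision.
    """
    for unit in (from_unit, to_unit):
        if unit not in _UNITS:
            raise ValidationError(
                f"unknown oxygen unit {unit!r}; expected one of {_UNITS}"
            )
    if from_unit == to_unit:
        return value
    sat_conc = conditions.sat_concentration
    sat_po2 = conditions.sat_po2
    if sat_conc is None or sat_po2 is None:
        raise ValidationError("conditions lack conversion anchors")
    # Normalize to percent air saturation, then to the target unit.
    if from_unit == PERCENT_AIRSAT:
        percent = value
    elif from_unit == KPA:
        percent = value / sat_po2 * 100.0
    else:
        percent = value / sat_conc * 100.0
    if to_unit == PERCENT_AIRSAT:
        return percent
    if to_unit == KPA:
        return percent / 100.0 * sat_po2
    return percent / 100.0 * sat_conc
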