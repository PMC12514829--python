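"""Metabolic trait estimation: SMR, MMR, aerobic scope and the ṀO₂–PO₂ curve.

Standard metabolic rate is estimated from resting-chamber cycles by a
trim-then-quantile rule: the lowest 5% of the rates (residual handling
artefacts) are dropped and the 15% quantile of the remainder taken.
Maximum metabolic rate mirrors it from swim-step rates: the top 5% are
dropped as artefacts and the mean of the remaining top-30% tail taken.
Spontaneous-activity spikes are removed beforehand with the boxplot
(1.5×IQR outlier / 3×IQR extreme) rule.  All quantiles use one pinned
interpolation rule so estimates are reproducible to the last digit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .errors import ValidationError

__all__ = [
    "FilterConfig",
    "TraitEstimates",
    "Mo2Curve",
    "iqr_filter",
    "estimate_smr",
    "temperature_smr",
    "estimate_mmr",
    "aerobic_scope",
    "fit_mo2_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Outlier-rule constants and the quantile interpolation rule.

    ``quantile_rule`` is any numpy quantile ``method`` tag; the default
    ``linear`` (interpolation between order statistics) is used everywhere
    in this package.
    """

    k_outlier: float = 1.5
    k_extreme: float = 3.0
    quantile_rule: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.k_outlier <= self.k_extreme:
            raise ValidationError("need 0 < k_outlier <= k_extreme")

    def quantile(self, values, q):
        return np.quantile(np.asarray(values, float), q, method=self.quantile_rule)


DEFAULT_FILTER = FilterConfig()


@dataclass
class TraitEstimates:
    """Trait summary for one individual or pooled group at one PO₂ level."""

    fish_id: str  # individual id or a pooled tag such as "pooled"
    po2_level: float | str  # % air saturation, or "60-100 pooled"
    smr: float | None = None
    mmr: float | None = None
    as_abs: float | None = None
    fas: float | None = None
    n_cycles_used: int = 0
    temperature: float | None = None
    flags: list[str] = field(default_factory=list)


def iqr_filter(values, cfg: FilterConfig = DEFAULT_FILTER):
    """Partition values by the boxplot rule into (kept, outliers, extremes).

    Outliers lie beyond Q1/Q3 ± 1.5·IQR, extremes beyond ± 3·IQR
    (extremes are reported separately, not double-counted as outliers).
    Downstream estimation removes both categories.  Fewer than 4 values:
    nothing is filtered and a warning is logged.
    """
    x = np.asarray(values, float)
    if x.size < 4:
        logger.warning("iqr_filter: only %d values, no filtering applied", x.size)
        return x, x[:0], x[:0]
    q1 = cfg.quantile(x, 0.25)
    q3 = cfg.quantile(x, 0.75)
    iqr = q3 - q1
    lo_out, hi_out = q1 - cfg.k_outlier * iqr, q3 + cfg.k_outlier * iqr
    lo_ext, hi_ext = q1 - cfg.k_extreme * iqr, q3 + cfg.k_extreme * iqr
    extreme = (x < lo_ext) | (x > hi_ext)
    outlier = ((x < lo_out) | (x > hi_out)) & ~extreme
    kept = x[~(outlier | extreme)]
    return kept, x[outlier], x[extreme]


def _trim_count(n: int, fraction: float) -> int:
    return int(np.floor(fraction * n))


def estimate_smr(
    values,
    cfg: FilterConfig = DEFAULT_FILTER,
    trim: float = 0.05,
    quantile: float = 0.15,
    mode: str = "trim_quantile",
) -> float:
    """SMR from one individual's resting ṀO₂(100) cycles.

    Default (``trim_quantile``): drop the lowest ``floor(0.05·n)`` values,
    then take the 15% quantile of the remainder.  The alternate
    ``plain_quantile`` mode returns the plain 20% quantile of the whole
    input, for sensitivity checks.

    Fewer than 10 values still yields an estimate, with a low-confidence
    warning.
    """
    x = np.sort(np.asarray(values, float))
    if x.size == 0:
        raise ValidationError("estimate_smr: empty input")
    if x.size < 10:
        logger.warning("estimate_smr: only %d values, low-confidence estimate", x.size)
    if mode == "plain_quantile":
        return float(cfg.quantile(x, trim + quantile))
    if mode != "trim_quantile":
        raise ValidationError(f"unknown SMR mode {mode!r}")
    kept = x[_trim_count(x.size, trim):]
    return float(cfg.quantile(kept, quantile))


def temperature_smr(per_individual_smrs) -> tuple[float, float]:
    """Treatment-level SMR: mean ± SD of per-individual SMRs.

    Individual SMRs entering here should come from cycles whose mean PO₂
    lies in the normoxic band (60–100% air saturation by convention).
    A single individual yields SD = nan with a warning.
    """
    x = np.asarray(per_individual_smrs, float)
    if x.size == 0:
        raise ValidationError("temperature_smr: empty input")
    if x.size == 1:
        logger.warning("temperature_smr: single individual, SD undefined")
        return float(x[0]), float("nan")
    return float(x.mean()), float(x.std(ddof=1))


def estimate_mmr(
    values,
    cfg: FilterConfig = DEFAULT_FILTER,
    trim: float = 0.05,
    upper_quantile: float = 0.30,
) -> float:
    """MMR from active ṀO₂(100) swim-step rates pooled at one PO₂ level.

    Drops the highest ``floor(0.05·n)`` values as artefacts, then returns
    the mean of all remaining values at or above the (1 − 0.30) quantile
    of the remainder.
    """
    x = np.sort(np.asarray(values, float))
    if x.size == 0:
        raise ValidationError("estimate_mmr: empty input")
    n_drop = _trim_count(x.size, trim)
    kept = x[: x.size - n_drop] if n_drop else x
    threshold = cfg.quantile(kept, 1.0 - upper_quantile)
    tail = kept[kept >= threshold]
    return float(tail.mean())


def aerobic_scope(smr: float, mmr: float) -> tuple[float, float]:
    """Absolute and factorial aerobic scope: (MMR − SMR, MMR / SMR).

    A negative absolute scope (MMR < SMR) is returned but logged; FAS
    requires SMR > 0.
    """
    if smr <= 0:
        raise ValidationError("aerobic_scope: FAS undefined for SMR <= 0")
    as_abs = mmr - smr
    if as_abs < 0:
        logger.warning("aerobic_scope: MMR < SMR (AS = %.3g), record suspect", as_abs)
    return as_abs, mmr / smr


@dataclass
class Mo2Curve:
    """Evaluable smooth ṀO₂(PO₂) regression with a pointwise ±SD band.

    Defined only on the observed PO₂ range; evaluation outside raises.
    """

    _spline: object
    po2_min: float
    po2_max: float
    residual_sd: float
    effective_df: float

    def __call__(self, po2):
        p = np.asarray(po2, float)
        if np.any(p < self.po2_min - 1e-9) or np.any(p > self.po2_max + 1e-9):
            raise ValidationError(
                f"Mo2Curve defined on [{self.po2_min:.3g}, {self.po2_max:.3g}] only"
            )
        out = self._spline(p)
        return float(out) if np.isscalar(po2) else out

    def band(self, po2):
        """(fit − SD, fit + SD) at the requested PO₂."""
        fit = self(po2)
        return fit - self.residual_sd, fit + self.residual_sd


def fit_mo2_curve(po2, mo2, lam: float | None = None) -> Mo2Curve:
    """Penalized smoothing-spline regression of ṀO₂ over PO₂.

    Cubic smoothing spline with the penalty weight chosen by generalized
    cross-validation (``lam=None``), the same penalized-likelihood idea
    used to pick the number of effective terms in a penalized polynomial
    regression.  Duplicate PO₂ values are averaged before fitting.
    Requires at least 8 distinct PO₂ values.
    """
    p = np.asarray(po2, float)
    m = np.asarray(mo2, float)
    if p.shape != m.shape or p.ndim != 1:
        raise ValidationError("po2 and mo2 must be equal-length 1-D arrays")
    order = np.argsort(p, kind="stable")
    p, m = p[order], m[order]
    xu, inverse, counts = np.unique(p, return_inverse=True, return_counts=True)
    if xu.size < 8:
        raise ValidationError(
            f"fit_mo2_curve needs >= 8 distinct PO2 values, got {xu.size}"
        )
    yu = np.bincount(inverse, weights=m) / counts
    spline = make_smoothing_spline(xu, yu, w=counts.astype(float), lam=lam)
    resid = m - spline(p)
    dof = max(p.size - xu.size, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof)) if p.size > xu.size else float(
        np.std(resid)
    )
    return Mo2Curve(
        _spline=spline,
        po2_min=float(xu[0]),
        po2_max=float(xu[-1]),
        residual_sd=residual_sd,
        effective_df=float(xu.size),
    )
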