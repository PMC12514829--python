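"""Critical oxygen thresholds via the oxygen supply capacity (α) method.

The per-cycle supply ratio α₀ = ṀO₂(100)/PO₂ (µmol O₂/g·h·kPa) measures
how much oxygen the animal moved per unit of ambient oxygen pressure.  As
ambient PO₂ falls, α₀ rises until the supply system saturates at its
capacity α — estimated per individual as the mean of the three highest α₀
observations.  The thresholds then follow from the α-line (the line of
slope α through the origin):

    P_crit  = SMR / α        (lowest PO₂ sustaining standard metabolism)
    P_cmax  = MMR / α        (PO₂ below which maximum metabolism declines;
                              in curve mode, the α-line ∩ MMR(PO₂) root)

A scalar calibration offset in the oxygen readings inflates α₀ near
anoxia; ``calibration_offset_correct`` recovers it by requiring that,
offset removed, a trial contains multiple equivalent estimates of α.
The classical two-segment regression-intersection P_crit is provided for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import NoConformityError, ValidationError
from .traits import Mo2Curve

__all__ = [
    "AlphaFit",
    "OffsetResult",
    "alpha0",
    "top_alpha",
    "estimate_alpha",
    "pcrit_from_alpha",
    "pcmax_from_alpha",
    "calibration_offset_correct",
    "pcrit_regression",
]

logger = logging.getLogger(__name__)

ALPHA_K = 3  # observations averaged into each individual's alpha


@dataclass
class AlphaFit:
    """Result container for one treatment's α-method analysis."""

    alpha0_po2: np.ndarray  # kPa
    alpha0_values: np.ndarray  # µmol O₂/g·h·kPa
    alpha: float
    alpha_sd: float
    per_individual_alpha: dict = field(default_factory=dict)
    calibration_offset: float = 0.0
    pcrit_kpa: float | None = None
    pcrit_percent: float | None = None
    pcrit_umol_l: float | None = None
    pcmax_kpa: float | None = None
    method_tags: tuple[str, ...] = ()


def alpha0(mo2_100: float, po2_kpa: float) -> float:
    """Per-cycle oxygen supply ratio ṀO₂(100)/PO₂."""
    if po2_kpa <= 0:
        raise ValidationError("alpha0 requires PO2 > 0")
    return mo2_100 / po2_kpa


def top_alpha(alpha0_values, k: int = ALPHA_K) -> float:
    """One individual's α: mean of its k highest α₀ observations.

    Exactly k values enter the mean; ties at the kth rank are broken by
    earlier cycle order (stable sort), which leaves the mean unchanged
    but keeps provenance deterministic.
    """
    x = np.asarray(alpha0_values, float)
    if x.size < k:
        raise ValidationError(f"top_alpha needs >= {k} values, got {x.size}")
    order = np.argsort(-x, kind="stable")[:k]
    return float(x[order].mean())


def estimate_alpha(alpha0_per_individual, k: int = ALPHA_K):
    """Treatment-level α: per-individual top-k means, averaged ± SD.

    ``alpha0_per_individual``: mapping id → α₀ sequence, or a plain
    iterable of sequences.  Individuals with fewer than k observations
    are excluded with a warning.  Returns ``(alpha, alpha_sd,
    per_individual)``; SD is nan for a single individual.
    """
    if hasattr(alpha0_per_individual, "items"):
        items = list(alpha0_per_individual.items())
    else:
        items = list(enumerate(alpha0_per_individual))
    per_individual = {}
    for key, series in items:
        series = np.asarray(series, float)
        if series.size < k:
            logger.warning(
                "individual %s excluded from alpha: %d < %d alpha0 values",
                key,
                series.size,
                k,
            )
            continue
        per_individual[key] = top_alpha(series, k)
    if not per_individual:
        raise ValidationError("no individual had enough alpha0 observations")
    vals = np.array(list(per_individual.values()))
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return float(vals.mean()), sd, per_individual


def pcrit_from_alpha(smr: float, alpha: float) -> float:
    """P_crit = SMR / α, kPa."""
    if alpha <= 0:
        raise ValidationError("pcrit_from_alpha requires alpha > 0")
    if smr < 0:
        raise ValidationError("pcrit_from_alpha requires SMR >= 0")
    return smr / alpha


def pcmax_from_alpha(mmr, alpha: float, search_grid: int = 512) -> float:
    """P_cmax from the α-line.

    Scalar mode (``mmr`` a number): MMR / α.  Curve mode (``mmr`` an
    Mo2Curve): the smallest PO₂ at which the α-line α·P crosses the
    fitted MMR(P) curve, found by a bracketed root search; if the line
    never crosses inside the curve's range, falls back to
    max(MMR)/α with a warning.
    """
    if alpha <= 0:
        raise ValidationError("pcmax_from_alpha requires alpha > 0")
    if not isinstance(mmr, Mo2Curve):
        return float(mmr) / alpha
    curve: Mo2Curve = mmr
    grid = np.linspace(curve.po2_min, curve.po2_max, search_grid)
    mmr_vals = curve(grid)
    # surplus of the MMR curve over the alpha-line; on the oxygen-conforming
    # limb the two coincide (f ≈ 0), so bracket the crossing from above: the
    # highest PO2 at which the curve still clearly exceeds the line.
    f = mmr_vals - alpha * grid
    tol = 1e-9 * max(float(np.max(np.abs(mmr_vals))), 1.0)
    above = np.nonzero(f > tol)[0]
    if above.size == 0 or above[-1] == grid.size - 1:
        logger.warning("alpha-line never crosses the MMR curve; using max(MMR)/alpha")
        return float(np.max(mmr_vals)) / alpha
    i = above[-1]
    return float(brentq(lambda p: curve(p) - alpha * p, grid[i], grid[i + 1]))


@dataclass
class OffsetResult:
    """Outcome of the calibration-offset search."""

    offset: float  # kPa added to every PO₂ reading
    alpha0_corrected: list  # per-group corrected α₀ arrays
    flags: tuple[str, ...] = ()
    grid: np.ndarray | None = None
    objective: np.ndarray | None = None


def _offset_objective(mo2_groups, po2_groups, delta: float, k: int) -> float:
    """Sum over individuals of the CV among the top-k recomputed α₀."""
    total = 0.0
    n_groups = 0
    for mo2, po2 in zip(mo2_groups, po2_groups):
        shifted = po2 + delta
        ok = shifted > 0
        if ok.sum() < k:
            continue
        a0 = mo2[ok] / shifted[ok]
        top = np.sort(a0)[-k:]
        mean = top.mean()
        if mean <= 0:
            continue
        total += top.std(ddof=0) / mean
        n_groups += 1
    return total / n_groups if n_groups else float("inf")


def calibration_offset_correct(
    mo2,
    po2,
    individuals=None,
    k: int = ALPHA_K,
    grid_range: tuple[float, float] = (-5.0, 5.0),
    grid_step: float = 0.01,
    cv_tol: float = 0.01,
) -> OffsetResult:
    """Recover a scalar PO₂ calibration offset from an α₀ series.

    Searches δ ∈ [−5, +5] kPa on a 0.01 kPa grid for the shift that
    minimizes the coefficient of variation among each individual's top-k
    recomputed α₀ = ṀO₂/(PO₂+δ), summed over individuals — i.e. the shift
    under which the trial holds multiple equivalent estimates of α.

    ``individuals`` optionally labels each observation; omitted, the whole
    series is one group.  δ = 0 is returned untouched when the unshifted
    series already satisfies the equivalence criterion (CV ≤ ``cv_tol``).
    A wide flat objective (> 1 kPa of near-minimal δ) is flagged
    ``low_identifiability``.
    """
    mo2 = np.asarray(mo2, float)
    po2 = np.asarray(po2, float)
    if mo2.shape != po2.shape or mo2.ndim != 1:
        raise ValidationError("mo2 and po2 must be equal-length 1-D arrays")
    if individuals is None:
        groups = [(mo2, po2)]
    else:
        individuals = np.asarray(individuals)
        groups = [
            (mo2[individuals == g], po2[individuals == g])
            for g in np.unique(individuals)
        ]
    if any(m.size < k for m, _ in groups):
        raise ValidationError(f"each individual needs >= {k} observations")
    mo2_groups = [m for m, _ in groups]
    po2_groups = [p for _, p in groups]

    flags: list[str] = []
    base_cv = _offset_objective(mo2_groups, po2_groups, 0.0, k)
    if base_cv <= cv_tol:
        corrected = [m / p for m, p in groups]
        return OffsetResult(0.0, corrected, tuple(flags))

    lo, hi = grid_range
    deltas = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    obj = np.array(
        [_offset_objective(mo2_groups, po2_groups, d, k) for d in deltas]
    )
    finite = np.isfinite(obj)
    if not finite.any():
        raise ValidationError("offset objective undefined over the whole grid")
    best = int(np.nanargmin(np.where(finite, obj, np.inf)))
    offset = float(deltas[best])

    # flat objective check: how wide is the region within one CV percent
    # of the minimum?  A sharp minimum localizes delta well below 1 kPa.
    span_mask = obj[finite] <= obj[best] + 0.01
    near_min_span = float(
        deltas[finite][span_mask].max() - deltas[finite][span_mask].min()
    )
    if near_min_span > 1.0:
        flags.append("low_identifiability")
        logger.warning(
            "offset search poorly identified: near-minimal range spans %.2f kPa",
            near_min_span,
        )
    corrected = [m / (p + offset) for m, p in groups]
    return OffsetResult(offset, corrected, tuple(flags), deltas, obj)


def pcrit_regression(po2, mo2, smr: float) -> float:
    """Classical regression-intersection P_crit (comparison mode).

    Fits a two-segment model over PO₂-sorted rates — an oxygen-conforming
    declining limb (OLS line) below the breakpoint and a regulating flat
    segment (mean) above it — with the breakpoint chosen by exhaustive
    least-total-squared-error search.  P_crit is where the declining limb
    crosses ``smr``.  Raises :class:`NoConformityError` when no declining
    limb is detectable (all points regulating).
    """
    po2 = np.asarray(po2, float)
    mo2 = np.asarray(mo2, float)
    if po2.shape != mo2.shape or po2.size < 5:
        raise ValidationError("pcrit_regression needs >= 5 paired observations")
    order = np.argsort(po2, kind="stable")
    p, m = po2[order], mo2[order]

    sse_flat_all = float(((m - m.mean()) ** 2).sum())
    best = None
    for j in range(2, p.size - 1):  # >= 2 points per segment
        pl, ml = p[:j], m[:j]
        slope, intercept = np.polyfit(pl, ml, 1)
        sse_low = float(((ml - (slope * pl + intercept)) ** 2).sum())
        mu = m[j:].mean()
        sse_high = float(((m[j:] - mu) ** 2).sum())
        sse = sse_low + sse_high
        if best is None or sse < best[0]:
            best = (sse, slope, intercept)
    sse, slope, intercept = best
    rate_scale = max(float(np.max(np.abs(m))), 1e-30)
    rise = slope * (p[-1] - p[0])
    if rise <= 1e-9 * rate_scale or sse > 0.95 * sse_flat_all:
        raise NoConformityError(
            "no conformity observed: no declining limb detectable"
        )
    return float((smr - intercept) / slope)
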