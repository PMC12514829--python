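"""End-to-end cohort analysis: traces → records → traits → oxygen limits.

This is the glue the acceptance checks and examples run: it reproduces, on
simulated (or measured) cohorts, the full estimation chain — background
correction, per-cycle ṀO₂ extraction, boxplot outlier removal per fish and
PO₂ level, quantile SMR/MMR estimation, and the α-method thresholds with
per-individual-first aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .limits import estimate_alpha, pcrit_from_alpha
from .mo2 import BackgroundModel, Mo2Record, estimate_blank_rate, extract_mo2_records
from .swim import u_crit, u_gait
from .traits import (
    DEFAULT_FILTER,
    FilterConfig,
    aerobic_scope,
    estimate_mmr,
    estimate_smr,
    iqr_filter,
    temperature_smr,
)

__all__ = ["CohortEstimates", "analyze_cohort", "assign_levels", "filter_records"]

SMR_BAND = (60.0, 100.0)  # % air saturation band defining "normoxic" SMR


def assign_levels(records: list[Mo2Record], levels) -> dict[int, float]:
    """Map each record (by id) to the nearest nominal PO₂ level, % air sat."""
    levels = np.asarray(sorted(levels))
    out = {}
    for r in records:
        out[id(r)] = float(levels[np.argmin(np.abs(levels - r.mean_po2_percent))])
    return out


def filter_records(
    records: list[Mo2Record],
    levels,
    cfg: FilterConfig = DEFAULT_FILTER,
) -> list[Mo2Record]:
    """Boxplot-filter records within each fish × PO₂-level group.

    Both outliers and extremes are removed, mirroring how spontaneous
    activity artefacts are stripped before SMR estimation.
    """
    level_of = assign_levels(records, levels)
    groups: dict[tuple[str, float], list[Mo2Record]] = {}
    for r in records:
        if not r.valid:
            continue
        groups.setdefault((r.fish_id, level_of[id(r)]), []).append(r)
    kept: list[Mo2Record] = []
    for group in groups.values():
        if len(group) < 4:  # too few for the boxplot rule; keep all
            kept.extend(group)
            continue
        vals = np.array([r.mo2_normalized for r in group])
        kept_vals, _, _ = iqr_filter(vals, cfg)
        kept_set = set()
        remaining = list(kept_vals)
        for r in group:
            if r.mo2_normalized in remaining:
                remaining.remove(r.mo2_normalized)
                kept_set.add(id(r))
        kept.extend(r for r in group if id(r) in kept_set)
    kept.sort(key=lambda r: (r.fish_id, r.cycle_index))
    return kept


@dataclass
class CohortEstimates:
    """Recovered treatment-level estimates for one cohort."""

    smr: float
    smr_sd: float
    per_fish_smr: dict
    alpha: float
    alpha_sd: float
    per_fish_alpha: dict
    pcrit_kpa: float  # mean of per-individual SMR_i / alpha_i
    pcrit_kpa_sd: float
    pcrit_kpa_pooled: float  # treatment SMR / treatment alpha
    mmr: float | None = None
    as_abs: float | None = None
    fas: float | None = None
    u_crit_mean: float | None = None
    u_gait_mean: float | None = None
    n_records: int = 0
    records: list = field(default_factory=list, repr=False)
    swim_records: list = field(default_factory=list, repr=False)


def analyze_cohort(
    cohort,
    levels=None,
    cfg: FilterConfig = DEFAULT_FILTER,
    smr_band=SMR_BAND,
    background: BackgroundModel | None = None,
) -> CohortEstimates:
    """Run the full estimation pipeline on a simulated cohort.

    Steps: blank-trace background fit → per-cycle ṀO₂ extraction →
    boxplot filtering per fish × level → per-fish SMR (normoxic band) →
    treatment SMR → per-fish α (top-3 α₀) → per-fish P_crit = SMR_i/α_i →
    treatment means; swim traces → per-step rates → pooled MMR → AS/FAS →
    Brett U_crit / U_gait.
    """
    if background is None:
        background = estimate_blank_rate([cohort.blank_trial.trace])

    records: list[Mo2Record] = []
    for sim in cohort.chamber_trials:
        records.extend(extract_mo2_records(sim.trace, background))
    if levels is None:
        levels = sorted({round(r.mean_po2_percent / 5) * 5 for r in records})
    kept = filter_records(records, levels, cfg)

    by_fish: dict[str, list[Mo2Record]] = {}
    for r in kept:
        by_fish.setdefault(r.fish_id, []).append(r)

    per_fish_smr = {
        fid: estimate_smr(
            [
                r.mo2_normalized
                for r in recs
                if smr_band[0] <= r.mean_po2_percent <= smr_band[1] + 5
            ],
            cfg,
        )
        for fid, recs in by_fish.items()
        if any(
            smr_band[0] <= r.mean_po2_percent <= smr_band[1] + 5 for r in recs
        )
    }
    smr, smr_sd = temperature_smr(list(per_fish_smr.values()))

    alpha0_by_fish = {
        fid: [r.mo2_normalized / r.mean_po2_kpa for r in recs]
        for fid, recs in by_fish.items()
    }
    alpha, alpha_sd, per_fish_alpha = estimate_alpha(alpha0_by_fish)

    pcrits = [
        pcrit_from_alpha(per_fish_smr[fid], per_fish_alpha[fid])
        for fid in per_fish_smr
        if fid in per_fish_alpha
    ]
    pcrit = float(np.mean(pcrits))
    pcrit_sd = float(np.std(pcrits, ddof=1)) if len(pcrits) > 1 else float("nan")

    mmr = as_abs = fas = ucrit_mean = ugait_mean = None
    swim_records: list[Mo2Record] = []
    if cohort.swim_trials:
        for sim in cohort.swim_trials:
            recs = extract_mo2_records(
                sim.trace, background, phase_context="swim_step"
            )
            for r in recs:
                if r.cycle_index < len(sim.swim.steps):
                    step = sim.swim.steps[r.cycle_index]
                    r.velocity = step.velocity
                    step.mo2_record = r
            swim_records.extend(recs)
        if swim_records:
            mmr = estimate_mmr(
                [r.mo2_normalized for r in swim_records if r.valid], cfg
            )
            as_abs, fas = aerobic_scope(smr, mmr)
        ucrits = [u_crit(sim.swim) for sim in cohort.swim_trials]
        ugaits = [g for sim in cohort.swim_trials if (g := u_gait(sim.swim))]
        ucrit_mean = float(np.mean(ucrits)) if ucrits else None
        ugait_mean = float(np.mean(ugaits)) if ugaits else None

    return CohortEstimates(
        smr=smr,
        smr_sd=smr_sd,
        per_fish_smr=per_fish_smr,
        alpha=alpha,
        alpha_sd=alpha_sd,
        per_fish_alpha=per_fish_alpha,
        pcrit_kpa=pcrit,
        pcrit_kpa_sd=pcrit_sd,
        pcrit_kpa_pooled=pcrit_from_alpha(smr, alpha),
        mmr=mmr,
        as_abs=as_abs,
        fas=fas,
        u_crit_mean=ucrit_mean,
        u_gait_mean=ugait_mean,
        n_records=len(kept),
        records=kept,
        swim_records=swim_records,
    )
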