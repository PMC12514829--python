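"""Forward simulator of respirometry and swim-tunnel trials with known truth.

The simulated animal is an oxyregulator with a hard supply ceiling: at any
instant its realized oxygen consumption is

    ṀO₂_realized = min(demand, α_true · PO₂, MMR_true)

where demand is the standard rate inflated by spontaneous-activity bouts
(chamber) or by the swimming cost function demand(U) = SMR·(1 + a·U^c)
(tunnel).  Sealed-phase chamber oxygen declines by the realized
consumption plus a small constant background (bacterial) rate; flush
phases relax the chamber back to the ambient level of the current step of
the PO₂ schedule.  Optode readings add Gaussian noise and an optional
constant calibration offset.  Loss of equilibrium (chamber) and
exhaustion-by-refusal (tunnel) events truncate trials.

Every trial is driven by a private random stream keyed on
``(seed, trial_id)``, so identical inputs replay byte-for-byte.

Treatment-level truth parameters are defined at the 100 g reference mass;
``generate_cohort`` scales them to each fish's body weight through the
same allometric exponent the analysis uses to normalize, so recovered
ṀO₂(100)-based estimates are directly comparable with the treatment
truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .trace import (
    SCHEDULE_COLD_2C,
    SCHEDULE_WARM_10C,
    ChamberSpec,
    CycleSchedule,
    FishMeta,
    OxygenTrace,
)
from .swim import StepProtocol, SwimTrial, VelocityStep, build_protocol
from .units import UMOL_PER_L, WaterConditions

__all__ = [
    "TruthParams",
    "SimulatedTrial",
    "CohortResult",
    "COLD_2C",
    "WARM_10C",
    "PO2_LEVELS_COLD",
    "PO2_LEVELS_WARM",
    "simulate_chamber_trial",
    "simulate_blank_trial",
    "simulate_swim_trial",
    "generate_cohort",
]

#: PO₂ step schedules (% air saturation) used by the two treatments.
PO2_LEVELS_COLD = (100, 85, 75, 65, 55, 40, 35, 30, 25, 20, 15, 10)
PO2_LEVELS_WARM = (100, 75, 65, 55, 50, 40, 30, 25)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of one simulated animal (or treatment).

    Rates are µmol O₂/g·h at the 100 g reference mass for treatment-level
    parameter sets; ``generate_cohort`` rescales them per fish.
    """

    smr_true: float = 0.49
    mmr_true: float = 3.47
    alpha_true: float = 0.29  # µmol O₂/g·h·kPa
    activity_rate: float = 2.0  # spontaneous bouts per hour
    activity_duration_s: float = 1200.0  # mean bout length (exponential)
    activity_sigma: float = 0.6  # lognormal σ of bout magnitude (median 1)
    background_fraction: float = 0.02  # of SMR, whole-chamber
    noise_sd: float = 0.3  # optode noise, µmol/L
    calibration_offset_true: float = 0.0  # kPa added to every reading
    loe_threshold: float = 1.8  # kPa; loss of equilibrium below this
    burst_rate_normoxia: float = 2.9  # bursts/min at full anaerobic shortfall
    cot_a: float = 0.9  # swimming cost coefficient
    cot_c: float = 2.0  # swimming cost exponent
    anaerobic_budget: float = 0.10  # µmol O₂/g of tolerated shortfall
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.smr_true, self.mmr_true, self.alpha_true) < 0:
            raise ValidationError("truth rates must be >= 0")
        if self.mmr_true < self.smr_true:
            raise ValidationError("mmr_true must be >= smr_true")
        if not 0 <= self.background_fraction < 1:
            raise ValidationError("background_fraction must be in [0, 1)")


#: Treatment presets: cold-acclimated at 2 °C and warm-acclimated at 10 °C.
COLD_2C = TruthParams(smr_true=0.49, mmr_true=3.47, alpha_true=0.29)
WARM_10C = TruthParams(smr_true=2.78, mmr_true=6.48, alpha_true=0.57)


@dataclass
class SimulatedTrial:
    """A simulated trial: the observable trace plus the hidden truth."""

    trace: OxygenTrace
    truth: TruthParams
    events: list = field(default_factory=list)
    time: np.ndarray | None = None  # s, simulation grid
    true_conc: np.ndarray | None = None  # µmol/L, noise/offset-free
    realized_mo2: np.ndarray | None = None  # µmol O₂/g·h at each instant
    swim: SwimTrial | None = None


def _trial_rng(seed: int, trial_id: str) -> np.random.Generator:
    """One private, platform-stable random stream per (seed, trial)."""
    key = zlib.crc32(trial_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


def _activity_multiplier(
    rng: np.random.Generator, n: int, dt: float, truth: TruthParams
) -> np.ndarray:
    """Summed magnitudes of active spontaneous-activity bouts per sample.

    Bouts arrive as a Poisson process, last exponentially long and carry a
    lognormal (median 1) demand multiplier; overlapping bouts add.
    """
    a = np.zeros(n)
    if truth.activity_rate <= 0:
        return a
    total_s = n * dt
    n_events = rng.poisson(truth.activity_rate * total_s / 3600.0)
    starts = rng.uniform(0.0, total_s, size=n_events)
    durations = rng.exponential(truth.activity_duration_s, size=n_events)
    magnitudes = rng.lognormal(mean=0.0, sigma=truth.activity_sigma, size=n_events)
    for s, d, m in zip(starts, durations, magnitudes):
        i0 = int(s // dt)
        i1 = min(int((s + d) // dt) + 1, n)
        a[i0:i1] += m
    return a


def simulate_chamber_trial(
    truth: TruthParams,
    fish: FishMeta,
    chamber: ChamberSpec,
    conditions: WaterConditions,
    po2_schedule=PO2_LEVELS_COLD,
    cycles_per_level: int = 3,
    schedule: CycleSchedule = SCHEDULE_COLD_2C,
    dt: float = 1.0,
    trial_id: str | None = None,
) -> SimulatedTrial:
    """Simulate one intermittent-flow chamber trial over a stepped PO₂ schedule.

    ``po2_schedule`` must be non-increasing (% air saturation).  The trial
    is truncated with an LOE event when the true PO₂ stays below the
    loss-of-equilibrium threshold for 60 s.
    """
    levels = list(po2_schedule)
    if any(b > a for a, b in zip(levels, levels[1:])):
        raise ValidationError("po2_schedule must be non-increasing")
    v_eff = chamber.effective_volume(fish)
    rng = _trial_rng(truth.seed, trial_id or f"chamber:{fish.id}")

    sat_conc = conditions.sat_concentration
    kpa_per_conc = conditions.sat_po2 / sat_conc
    bw = fish.body_weight
    background_umol_h = truth.background_fraction * truth.smr_true * bw
    offset_conc = truth.calibration_offset_true / kpa_per_conc

    cycle_n = int(round(schedule.cycle_s / dt))
    flush_n = int(round(schedule.flush_s / dt))
    n = cycle_n * cycles_per_level * len(levels)
    ambient = np.repeat(
        [lvl / 100.0 * sat_conc for lvl in levels], cycles_per_level * cycle_n
    )
    in_flush = (np.arange(n) % cycle_n) < flush_n
    activity = _activity_multiplier(rng, n, dt, truth)
    demand = truth.smr_true * (1.0 + activity)
    # flush relaxation constant: ~5 turnovers per flush phase
    flush_k = 1.0 - np.exp(-5.0 * dt / max(schedule.flush_s, dt))

    time = np.arange(n) * dt
    conc = np.empty(n)
    realized = np.empty(n)
    events: list[dict] = []
    c = float(ambient[0])
    loe_run = 0.0
    end = n
    loe_cap = truth.mmr_true
    step_h = dt / 3600.0
    for i in range(n):
        supply = truth.alpha_true * c * kpa_per_conc
        r = min(demand[i], supply, loe_cap)
        if in_flush[i]:
            c += (ambient[i] - c) * flush_k
        else:
            c -= (r * bw + background_umol_h) * step_h / v_eff
            c = max(c, 0.0)
        conc[i] = c
        realized[i] = r
        if c * kpa_per_conc < truth.loe_threshold:
            loe_run += dt
            if loe_run >= 60.0:
                events.append(
                    {"event": "loss_of_equilibrium", "time_s": time[i],
                     "po2_kpa": c * kpa_per_conc}
                )
                end = i + 1
                break
        else:
            loe_run = 0.0

    time, conc, realized = time[:end], conc[:end], realized[:end]
    readings = conc + offset_conc
    if truth.noise_sd > 0:
        readings = readings + rng.normal(0.0, truth.noise_sd, size=end)
    trace = OxygenTrace(
        time=time,
        o2=readings,
        unit=UMOL_PER_L,
        conditions=conditions,
        chamber=chamber,
        fish=fish,
        schedule=schedule,
        po2_level=None,
    )
    return SimulatedTrial(
        trace=trace,
        truth=truth,
        events=events,
        time=time,
        true_conc=conc,
        realized_mo2=realized,
    )


def simulate_blank_trial(
    truth: TruthParams,
    chamber: ChamberSpec,
    conditions: WaterConditions,
    po2_level: float = 100.0,
    cycles: int = 2,
    schedule: CycleSchedule = SCHEDULE_COLD_2C,
    dt: float = 1.0,
    reference_weight: float = 100.0,
    trial_id: str = "blank:0",
) -> SimulatedTrial:
    """Simulate a fishless (blank) control run: background respiration only.

    The background rate is ``background_fraction × SMR × reference
    weight`` µmol O₂/h per chamber, matching what the paired fish trial
    experiences.
    """
    blank_fish = FishMeta(id="BLANK", body_weight=reference_weight, total_length=1.0)
    blank_truth = replace(
        truth,
        smr_true=truth.smr_true * truth.background_fraction,
        mmr_true=max(truth.mmr_true, truth.smr_true) * truth.background_fraction,
        alpha_true=1e6,  # background is not supply-limited
        activity_rate=0.0,
        background_fraction=0.0,
        loe_threshold=-1.0,
    )
    sim = simulate_chamber_trial(
        blank_truth,
        blank_fish,
        chamber,
        conditions,
        po2_schedule=(po2_level,),
        cycles_per_level=cycles,
        schedule=schedule,
        dt=dt,
        trial_id=trial_id,
    )
    sim.truth = truth
    return sim


def simulate_swim_trial(
    truth: TruthParams,
    fish: FishMeta,
    tunnel: ChamberSpec,
    conditions: WaterConditions,
    po2_level: float = 100.0,
    protocol: StepProtocol | None = None,
    dt: float = 1.0,
    trial_id: str | None = None,
) -> SimulatedTrial:
    """Simulate a critical-swimming-speed step test at one PO₂ level.

    Demand follows demand(U) = SMR·(1 + a·U^c) and is capped by
    min(MMR, α·PO₂).  While demand exceeds the cap, kick-and-glide bursts
    fire at a rate proportional to the relative shortfall (multiplied by
    PO₂/PO₂_normoxia, reproducing burst suppression in hypoxia) and an
    anaerobic tolerance budget drains at the shortfall rate; once it
    empties the fish refuses to swim (inactive > 90 s → exhaustion) and
    the trial ends.
    """
    protocol = protocol or build_protocol()
    v_eff = tunnel.effective_volume(fish)
    rng = _trial_rng(truth.seed, trial_id or f"swim:{fish.id}:{po2_level}")

    sat_conc = conditions.sat_concentration
    kpa_per_conc = conditions.sat_po2 / sat_conc
    bw = fish.body_weight
    background_umol_h = truth.background_fraction * truth.smr_true * bw
    offset_conc = truth.calibration_offset_true / kpa_per_conc
    ambient_conc = po2_level / 100.0 * sat_conc
    po2_normoxia = conditions.sat_po2

    step_s = protocol.step_duration_s
    step_n = int(round(step_s / dt))
    flush_n = max(int(round(protocol.cycle.flush_s / dt)), 1)
    flush_k = 1.0 - np.exp(-5.0 / flush_n)

    time_list: list[float] = []
    conc_list: list[float] = []
    realized_list: list[float] = []
    steps: list[VelocityStep] = []
    events: list[dict] = []
    budget = truth.anaerobic_budget
    c = ambient_conc
    exhausted = False
    step_h = dt / 3600.0
    refusal_time: float | None = None

    for k, u in enumerate(protocol.velocities):
        start = k * step_s
        demand = truth.smr_true * (1.0 + truth.cot_a * u**truth.cot_c)
        bursts = 0
        burst_time = 0.0
        first_burst: float | None = None
        endured = step_s
        for i in range(step_n):
            t = start + i * dt
            po2_kpa = c * kpa_per_conc
            cap = min(truth.mmr_true, truth.alpha_true * po2_kpa)
            r = min(demand, cap)
            shortfall = demand - r
            if i < flush_n:
                c += (ambient_conc - c) * flush_k
            else:
                c -= (r * bw + background_umol_h) * step_h / v_eff
                c = max(c, 0.0)
            time_list.append(t)
            conc_list.append(c)
            realized_list.append(r)
            if shortfall > 0:
                # burst propensity collapses as PO2 falls from Pcmax toward
                # Pcrit, reproducing the observed loss of burst swimming in
                # deep hypoxia (qualitative only)
                pcrit_t = truth.smr_true / truth.alpha_true
                pcmax_t = truth.mmr_true / truth.alpha_true
                hypoxia_factor = (
                    min(max((po2_kpa - pcrit_t) / (pcmax_t - pcrit_t), 0.0), 1.0)
                    ** 2
                )
                rate_per_s = (
                    truth.burst_rate_normoxia
                    / 60.0
                    * (shortfall / truth.smr_true)
                    * hypoxia_factor
                )
                n_bursts = rng.poisson(rate_per_s * dt)
                if n_bursts:
                    bursts += int(n_bursts)
                    burst_time += 2.0 * n_bursts  # ~2 s of kick-and-glide each
                    if first_burst is None:
                        first_burst = i * dt
                budget -= shortfall * step_h
                if budget <= 0:
                    endured = i * dt
                    exhausted = True
                    refusal_time = t
                    break
        steps.append(
            VelocityStep(
                index=k,
                velocity=u,
                start_time=start,
                duration_completed=endured,
                bursts=bursts,
                burst_time=burst_time,
                first_burst_s=first_burst,
            )
        )
        if exhausted:
            events.append(
                {"event": "exhaustion", "time_s": refusal_time,
                 "velocity_bls": u, "endured_s": endured}
            )
            break

    time = np.asarray(time_list)
    conc = np.asarray(conc_list)
    realized = np.asarray(realized_list)
    readings = conc + offset_conc
    if truth.noise_sd > 0:
        readings = readings + rng.normal(0.0, truth.noise_sd, size=time.size)
    trace = OxygenTrace(
        time=time,
        o2=readings,
        unit=UMOL_PER_L,
        conditions=conditions,
        chamber=tunnel,
        fish=fish,
        schedule=protocol.cycle,
        po2_level=po2_level,
    )
    swim = SwimTrial(
        fish=fish,
        po2_level=po2_level,
        steps=steps,
        step_duration_s=step_s,
        increment=protocol.increment,
        settling_velocity=protocol.settling_velocity,
        exhausted=exhausted,
    )
    return SimulatedTrial(
        trace=trace,
        truth=truth,
        events=events,
        time=time,
        true_conc=conc,
        realized_mo2=realized,
        swim=swim,
    )


@dataclass
class CohortResult:
    """A simulated cohort: trials plus the truth registry for scoring."""

    chamber_trials: list
    swim_trials: list
    blank_trial: SimulatedTrial
    truth_registry: dict  # fish id → per-fish TruthParams
    treatment_truth: TruthParams
    fish: list
    conditions: WaterConditions


def generate_cohort(
    n: int = 7,
    truth: TruthParams = COLD_2C,
    conditions: WaterConditions | None = None,
    seed: int = 0,
    po2_schedule=PO2_LEVELS_COLD,
    cycles_per_level: int = 8,
    schedule: CycleSchedule = SCHEDULE_COLD_2C,
    swim_po2_levels=(100.0,),
    dt: float = 1.0,
    scaling_exponent: float = 0.8,
    individual_cv: float = 0.08,
    weight_mean_g: float = 39.6,
    weight_sd_g: float = 9.5,
    length_mean_cm: float = 19.7,
    length_sd_cm: float = 1.3,
) -> CohortResult:
    """Draw a cohort of fish and simulate their chamber and swim trials.

    Body weights and lengths come from truncated normals matching the
    study cohort's moments (39.6 ± 9.5 g, 19.7 ± 1.3 cm).  Treatment-level
    truth rates, defined at 100 g, are scaled to each fish's weight with
    the allometric exponent the analysis later uses to normalize, then
    jittered per fish by a lognormal factor (CV ``individual_cv``).
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    if conditions is None:
        conditions = WaterConditions(temperature=2.0, salinity=34.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x0C0]))

    weights = np.clip(
        rng.normal(weight_mean_g, weight_sd_g, size=n), 0.3 * weight_mean_g, None
    )
    lengths = np.clip(
        rng.normal(length_mean_cm, length_sd_cm, size=n), 0.5 * length_mean_cm, None
    )
    chamber = ChamberSpec(respirometer_volume=2.5, kind="static_chamber")
    tunnel = ChamberSpec(respirometer_volume=5.0, kind="swim_tunnel")

    sigma = np.sqrt(np.log1p(individual_cv**2))
    chamber_trials, swim_trials, fish_list = [], [], []
    registry: dict[str, TruthParams] = {}
    for i in range(n):
        fid = f"F{i+1:02d}"
        fish = FishMeta(
            id=fid,
            body_weight=float(weights[i]),
            total_length=float(lengths[i]),
        )
        allometric = (fish.body_weight / 100.0) ** (scaling_exponent - 1.0)
        # mean-one lognormal jitters; metabolic rates and supply capacity
        # vary semi-independently across fish
        jitter_rate = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        jitter_alpha = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        fish_truth = replace(
            truth,
            smr_true=truth.smr_true * allometric * jitter_rate,
            mmr_true=truth.mmr_true * allometric * jitter_rate,
            alpha_true=truth.alpha_true * allometric * jitter_alpha,
            seed=int(seed) % 2**31,
        )
        registry[fid] = fish_truth
        fish_list.append(fish)
        chamber_trials.append(
            simulate_chamber_trial(
                fish_truth,
                fish,
                chamber,
                conditions,
                po2_schedule=po2_schedule,
                cycles_per_level=cycles_per_level,
                schedule=schedule,
                dt=dt,
                trial_id=f"cohort{seed}:chamber:{fid}",
            )
        )
        for level in swim_po2_levels:
            swim_trials.append(
                simulate_swim_trial(
                    fish_truth,
                    fish,
                    tunnel,
                    conditions,
                    po2_level=float(level),
                    dt=dt,
                    trial_id=f"cohort{seed}:swim:{fid}:{level}",
                )
            )
    blank = simulate_blank_trial(
        replace(truth, seed=int(seed) % 2**31),
        chamber,
        conditions,
        cycles=2,
        schedule=schedule,
        dt=dt,
        reference_weight=float(np.mean(weights)),
        trial_id=f"cohort{seed}:blank",
    )
    return CohortResult(
        chamber_trials=chamber_trials,
        swim_trials=swim_trials,
        blank_trial=blank,
        truth_registry=registry,
        treatment_truth=truth,
        fish=fish_list,
        conditions=conditions,
    )
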