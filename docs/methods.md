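# Methods

## Scope and data model

The package estimates whole-animal metabolic traits from intermittent-flow
respirometry: alternating open (flush) and sealed phases in a chamber or
swim tunnel, with dissolved oxygen logged at nominally 1 Hz. A trial is an
`OxygenTrace` (time, oxygen, unit) plus metadata: `WaterConditions`
(temperature, salinity, barometric pressure and the two 100%-air-saturation
anchors), `ChamberSpec` (volume, fish displacement), `FishMeta` and a
`CycleSchedule` (flush / stabilization / measure durations). Segmentation
lays cycles back-to-back from the trace start; only complete cycles feed
rate estimation, and the stabilization window after sealing is excluded
from fits. Missing samples are linearly interpolated inside a measure
window, never across phase boundaries.

## Units and solubility

All oxygen conversions are linear through two anchors: the dissolved
concentration at 100% air saturation (µmol/L) and the corresponding O₂
partial pressure (kPa). By default the concentration anchor comes from the
García–Gordon seawater solubility fit (Benson–Krause coefficients, valid
−2…40 °C, 0…42 PSU) with a moist-air barometric correction, and the
pressure anchor from (P_baro − P_H₂O(T,S)) × 0.2095. Both anchors accept
user-supplied values, because published conversion tables are themselves
internally inconsistent at the last digit and the only way to reproduce a
given table exactly is to pin its anchors. Round-trip conversions are
exact to floating point.

## Rate extraction

The sealed-phase decline is fitted by ordinary least squares
(concentration vs time); robust alternatives are deliberately not used, as
OLS on a pre-trimmed window is the standard in the field and keeps the
estimator linear. The slope scales to a mass-specific rate via the
effective water volume (chamber minus fish displacement; displacement
defaults to BW/1000 L ≈ 1 g/mL when unspecified, configurable off).
Fishless blank runs pass through the same fit path and pool into a
whole-chamber background rate subtracted from each record; corrections
above 20% of the raw rate flag the record suspect, corrections exceeding
it flag it invalid. Fit r² is recorded but no r² cutoff is applied by
default — a configurable threshold exists but published practice here
states none. Rates normalize to a 100 g reference mass with scaling
exponent b = 0.8, ṀO₂(100) = ṀO₂·(BW/100)^(1−b).

## Trait estimators

Quantiles everywhere use linear interpolation of order statistics (numpy
`method="linear"`), pinned in `FilterConfig` so every estimate is
reproducible to the last digit. The boxplot rule removes both outliers
(beyond 1.5·IQR) and extremes (beyond 3·IQR) per fish × PO₂ level before
estimation; groups of fewer than four values are left unfiltered.

- SMR uses the stepwise rule — drop the lowest `floor(0.05·n)` values,
  then the 15% quantile of the remainder — rather than a plain 20%
  quantile (available as `mode="plain_quantile"` for sensitivity checks);
  the stepwise form is the operative published definition. Per-fish SMRs
  from the 60–100% air-saturation band average into the treatment SMR
  (mean ± SD across individuals).
- MMR mirrors it on pooled swim-step rates: drop the top `floor(0.05·n)`,
  then the mean of all values at or above the 70% quantile of the rest.
- AS = MMR − SMR (negative values flagged, not hidden); FAS = MMR/SMR.
- The smooth ṀO₂(PO₂) regression is a cubic smoothing spline with the
  penalty selected by generalized cross-validation — the same
  penalized-likelihood idea as choosing polynomial terms by penalized
  log-likelihood, with the penalty weight continuous instead of a term
  count. Duplicate PO₂ values are averaged (weighted) before fitting; the
  curve refuses evaluation outside the observed range and carries a
  constant residual-SD band.

## The α-method

α₀ = ṀO₂(100)/PO₂ (µmol O₂/g·h·kPa) per cycle. Each individual's α is the
mean of its three highest α₀ — exactly three values, ties at the third
rank broken by earlier cycle (stable sort), which never changes the mean
but keeps provenance deterministic. Aggregation is individual-first
throughout: α and P_crit = SMR/α are computed per fish with that fish's
SMR, then averaged (mean ± SD); this is the only aggregation under which
treatment-level means and SDs of ratio quantities are well-defined, and a
pooled mode (treatment SMR / treatment α) is also reported. Resting-α uses
chamber records only; exercise-α would use swim-step records only.
P_cmax is MMR/α in scalar mode; in curve mode it is the intersection of
the α-line with the fitted MMR(PO₂) curve, bracketed from the high-PO₂
side because the line and the curve coincide on the oxygen-conforming
limb (the low side is degenerate by construction).

The calibration-offset correction assumes a trial contains multiple
equivalent α estimates once a scalar PO₂ reading error δ is removed. The
search minimizes the coefficient of variation among each individual's
top-3 recomputed α₀ = ṀO₂/(PO₂+δ), summed over individuals, by exhaustive
grid over δ ∈ [−5, +5] kPa at 0.01 kPa — a grid because the objective is
piecewise-smooth (the top-3 membership changes with δ) and gradient
methods are unreliable on it. δ = 0 is returned untouched when the
unshifted series already satisfies equivalence (CV ≤ 0.01). The method is
only identified when the series includes genuinely supply-limited
observations at distinct low PO₂ values; a near-minimum region wider than
1 kPa flags `low_identifiability`. Note that with replicated identical
cycles at one level (possible in noiseless simulation) the criterion is
blind by construction — equivalence among replicas holds under any δ.

The classical comparison estimator fits a two-segment model (OLS line
below a breakpoint, constant above) with exhaustive breakpoint search and
intersects the declining limb with SMR; it raises "no conformity
observed" when no declining limb improves on the flat fit.

## Swim protocol and indices

The default protocol starts at 1.4 BL/s and increments 0.15 BL/s per
660 s step (60 s flush + 120 s stabilization + 480 s measure), after a
25 min settling period at 1.2 BL/s. The t in U_crit = U_max + vT/t is the
full 660 s step because velocity is held through all three phases.
Exhaustion is the start of the first inactive run strictly longer than
90 s in the 1 Hz activity log. U_gait anchors at the highest fully
completed burst-free speed, with T the time into the following step of
its first burst; trials without bursts return an undefined U_gait with a
flag, and bursts already at the first step fall back to the settling
velocity. Burst events are observer/simulator annotations, not detected
from video.

## The simulator

The simulated animal is an oxyregulator with a hard ceiling: realized
ṀO₂ = min(demand, α_true·PO₂, MMR_true) at every instant. Chamber demand
is SMR_true·(1 + ΣA) with spontaneous-activity bouts; tunnel demand is
SMR_true·(1 + a·U^c) with a = 0.9, c = 2 chosen so demand reaches the
cold-preset MMR (3.47 µmol O₂/g·h) at the observed top sustained speed of
2.6 BL/s. Sealed-phase oxygen declines by (realized·BW + background)/V_eff
via explicit Euler steps; flush phases relax exponentially to the ambient
level of the current schedule step (≈5 turnovers per flush). Optode
readings add Gaussian noise (default 0.3 µmol/L) and an optional constant
calibration offset. Background respiration defaults to 2% of SMR.
Loss of equilibrium fires after 60 s below 1.8 kPa (~8.6% air saturation,
inside the observed LOE band) and truncates the trial; in the tunnel, an
anaerobic tolerance budget (0.10 µmol O₂/g) drains at the supply shortfall
rate and triggers refusal when empty, with kick-and-glide bursts firing
at a rate proportional to the relative shortfall and suppressed
quadratically between P_cmax and P_crit (qualitative only — reproducing
the observed disappearance of bursting in deep hypoxia, with no
quantitative claim attached).

Activity bouts are Poisson in time (2 /h), exponentially long (mean
1200 s) with lognormal median-1 magnitudes (σ_log 0.6). Long sparse bouts
matter: they leave ~20% of measurement windows quiescent, which is what
the 15%-quantile SMR estimator needs, while making some low-PO₂ windows
near-fully supply-limited, which is what the top-3 α₀ estimator needs.
Brief frequent bouts of equal duty cycle break the α estimator because no
window ever rides the supply ceiling for its full duration.

Treatment truth parameters (cold preset SMR 0.49, MMR 3.47, α 0.29;
warm preset SMR 2.78, MMR 6.48, α 0.57) are defined at the 100 g
reference mass. `generate_cohort` draws body weights and lengths from
truncated normals matching the study cohort (39.6 ± 9.5 g, 19.7 ± 1.3 cm),
scales truth rates to each fish with the same allometric exponent the
analysis uses to normalize (so ṀO₂(100)-based estimates are directly
comparable to treatment truth), and jitters rates and supply capacity
semi-independently (lognormal, CV 8%). Every trial draws from a private
random stream keyed on (seed, trial id), so identical inputs replay
byte-for-byte.

### Problem sizes

The real protocol holds each PO₂ level for about two days (~80–100
measurement cycles) at 1 Hz. The cohort generator defaults to 8 cycles
per level with traces thinned to 0.1 Hz — roughly a tenth of the study's
data volume — which preserves the operating regime of the quantile and
top-3 estimators while keeping a 20-cohort recovery study to a few
seconds. Much thinner designs (≤3 cycles per level) visibly bias P_crit
upward: too few windows for the SMR quantile to find quiescence or for
α₀ to find full supply limitation.

### What the simulator does not emulate

Hypoxia-induced up-regulation of resting demand (the real animal's
routine rate rises below ~50% air saturation from elevated ventilatory
cost; here elevated demand at low PO₂ arises only through activity
bouts), diel rhythms and the second-night selection window, chamber
leaks, optode drift (the calibration error is a constant offset),
temperature dynamics (presets differ only in parameter values), and any
mechanistic cardio-respiratory physiology. Passing recovery tests
therefore show the estimators are consistent for an ideal oxyregulator
under realistic noise, activity contamination and supply limitation —
not that they are unbiased for every real animal.

## Numerical choices and degenerate inputs

- Quantile trims use `floor(fraction·n)` values, making the estimators
  exactly reproducible by order-statistic oracles at any n.
- Decline fits require ≥30 readings; shorter windows are skipped with a
  warning rather than producing high-variance rates.
- Fewer than 10 SMR values or a single individual yield estimates with
  logged low-confidence warnings (SD = nan for n = 1).
- `estimate_alpha` excludes individuals with <3 α₀ values; an empty
  remainder raises.
- The offset grid excludes shifted PO₂ ≤ 0 pointwise and raises only if
  the objective is undefined over the whole grid.
- Empty traces and traces shorter than one cycle return empty cycle lists
  with warnings; validation errors are raised as `ValidationError`, the
  no-conformity condition of the regression comparison as
  `NoConformityError`.

## Known limitations

- P_crit from the α-method inherits the small upward bias of SMR (activity
  leakage into the quantile) and downward bias of α (partial supply
  limitation); on default recovery studies the compound median error is
  ~4–8%.
- MMR reads a few percent low because the top-30% tail averages step
  rates slightly below the ceiling.
- The offset correction carries a ~0.03 kPa systematic from within-window
  curvature of supply-limited declines (slope-over-mean vs instantaneous
  ratio); it is well inside the 0.01 kPa grid's practical resolution.
- The regression-intersection P_crit is a comparison mode only; its
  breakpoint model (flat + line) is a coarse description of real
  profiles with intermediate up-regulation.
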