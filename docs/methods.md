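# Methods

## The accumulated-cooling-temperature index

Spike induction in *Phalaenopsis* is driven by the contrast between the warm
vegetative environment a plant is adapted to and the cooler induction room it
is moved into. The dose index is the accumulated cooling temperature

    ACT = Σ_d (T_vd − T_cd)·H_d + Σ_d (T_vn − T_cn)·H_n     [°C·h]

summed over days in the cooling room, with `T_vd/T_vn` the vegetative day and
night set-points, `T_cd/T_cn` the cooling-room set-points, and `H_d + H_n =
24 h` the photoperiod split (default 14/10 h). `Day-ACT` keeps only the day
term and exists to test the hypothesis that daytime cooling alone controls
induction.

**Clamping.** Temperatures above the vegetative reference do not induce, so
each differential is clamped at zero *per term, per day* — the minimal rule
that realises "warm conditions accumulate nothing" without inventing
structure the data cannot support. The unclamped algebraic sum remains
available (`clamp=False`) for sensitivity analysis. An optional inhibition
threshold (off by default; 28–29 °C are the values reported in the
literature for *Phalaenopsis*) zeroes a whole day's accumulation when the
day temperature reaches it; it is opt-in because the published dose index
does not include it.

**Hourly logs.** When a climate computer's log is supplied instead of
set-points, each sample contributes `max(0, T_ref − T_sample) ×
interval_hours`, with the day/night reference chosen by a configured clock
window (lights-on hour + photoperiod), not solar position — cooling rooms
run on artificial light. Per-sample clamping means a transient warm
excursion pauses accumulation for its own samples only; it does not void the
day. On a square-wave log matching a set-point regime the log route
reproduces the regime route to 1e-9 °C·h (tested). Logs must be strictly
increasing in time with no gap wider than twice the declared sampling
interval; a gap is an error naming the first missing interval rather than a
silently shortened dose.

## The induction sigmoid

The cohort spiking percentage is modelled as

    Y(ACT) = Ymax / (1 + B·exp(−ACT/K))

- `Ymax` (%) — plateau; the fraction of the cohort that is inducible at all.
- `K` (°C·h) — dose scale; the curve reaches `Ymax/2` at `ACT = K·ln B`.
- `B` (—) — offset fixing the day-zero value `Y(0) = Ymax/(1+B)`.

The model is monotone increasing in dose and bounded in `(0, Ymax)`; the
closed-form inverse `ACT = −K·ln[(Ymax/Y − 1)/B]` underlies scheduling.

Published parameter triples for three data pools are shipped as presets
(`FOUR_VARIETY_PARAMS`, `LITERATURE_PARAMS`, `POOLED_PARAMS`). The source
typography for these fitted equations is ambiguous — read additively they
would give `Y(0) ≈ 138 %`, which is impossible for a percentage — so they
are interpreted in the fraction form above, whose `Y(0) ≈ 2.5 %` matches the
reported curves at the origin. This reading is fixed throughout the package.

## Estimation

Parameters are estimated by unweighted least squares on the percentage
scale (the estimator used to produce the published triples; a binomial GLM
would weight cohorts differently and is deliberately out of scope):
trust-region reflective minimisation (`scipy.optimize.least_squares`) with
the analytic Jacobian, tolerances 1e-14, and box constraints
`Ymax ∈ (0, 200]`, `B > 0`, `K > 0`. The `Ymax` bound is set at 200 rather
than 100 so that a plateau the data push past 100 % converges there visibly
and triggers a warning, instead of pinning to the biological bound and
masquerading as convergence. Duplicate doses are treated as independent
observations. Fitting requires at least 4 rows (3 parameters + 1 df) and a
non-constant dose column.

**Initialisation** (when no start is given) is moment-style in the model's
own geometry: `Ymax₀ = min(100, 1.05·max Y)`, `K₀ = dose span / 4`,
`B₀ = clip(Ymax₀ / max(Y at the smallest dose, 0.5) − 1, 1, 500)`. Noise-free
recovery is exact to better than 1e-4 relative from any start in the basin
`Ymax₀ ∈ [80, 120]`, `B₀ ∈ [1, 500]`, `K₀ ∈ [100, 2000]` (tested).

**Fit statistics.** `R² = 1 − SS_res/SS_tot` with `SS_tot` about the mean of
the observations — the convention nonlinear-regression packages print, kept
so values are comparable with published fits — and the residual standard
error `s = sqrt(SS_res/(n − 3))` with `p = 3` parameters. A constant
response has `SS_tot = 0`; `R²` is then reported as undefined (NaN/null)
while `s` is still computed. Both definitions are embedded in the fit-result
JSON so downstream comparisons are unambiguous. Parameter standard errors
come from `s²(JᵀJ)⁻¹` at the optimum.

**Index comparison.** `compare_indices` fits one pooled sigmoid per dose
index (full ACT and Day-ACT) over cohorts carrying both abscissas and flags
the index with the smaller pooled `s`, alongside per-group residual spreads.
When vegetative regimes differ across cohorts, Day-ACT rescales each group's
abscissa by a different factor, so cohorts induced by a common full-ACT
curve cannot be pooled on it — the mechanism behind the full index winning.
If all groups share one day/night differential pair the two indices are
proportional, the sigmoid family absorbs the rescaling into `K`, and the
comparison is an exact tie (tested to 1e-6).

## Scheduling

`required_act` inverts the fitted curve at the target percentage and clamps
at zero (a target already met at move-in needs no cooling); targets at or
above `Ymax` are an explicit unreachable-target error naming the plateau.
`days_to_target` divides by the regime's daily increment and takes the
ceiling — plants are moved on whole days, and the returned day is the first
whose prediction meets the target (verified against a brute-force day loop).
A regime that accumulates nothing is an error, not an infinite loop.

## The cohort simulator

The trial the model comes from scored cohorts of 1000 plants per variety;
the per-plant raw data are not published, so the simulator generates
cohorts with the structure the analysis assumes:

- `plant_threshold` (default): each plant draws a latent induction
  threshold `u ~ U(0,1)` once and is spiked on every scoring day where
  `Y(ACT)/100 ≥ u`. Induction is irreversible, so counts are cumulative and
  monotone, day-to-day errors are positively correlated within a cohort,
  and the ever-spiking fraction converges to `Ymax/100` (tested at n = 10⁵
  within 0.5 points).
- `binomial`: independent `Binomial(n, p_day)` per scoring day —
  non-cumulative, kept for variance calibration.
- `none`: exact curve values.

Defaults mirror the study conditions: 1000 plants per cohort, the four
variety regimes (32/24, 27/23, 26/23, 26/23 °C vegetative) against the
22/19 °C cooling room at a 14 h photoperiod — daily increments 190, 110, 96,
96 °C·h — and one shared true parameter set (the pooled preset), since the
four varieties were found to share a common curve in full ACT. The scoring
cadence is every 2 days to day 40; the actual trial cadence is not recorded,
so this is a stand-in choice, not a claim about the study. The
literature-like fixture uses the literature preset at a 110 °C·h/day
increment for the same reason. What the simulator does **not** emulate:
variety-specific plateaus or scales, measurement/recording error on the
percentages, temperature excursions around set-points, and any time-domain
process (lag between induction and visible buds). Passing recovery tests
therefore demonstrates estimator correctness under the assumed dose-response
structure, not model adequacy for any particular greenhouse.

Fixture generation is a pure function of `(spec, seed)`; the study-fixture
seed fans out to per-cohort seeds via `numpy.random.SeedSequence`.

## Numerical choices and edge cases

- Percentages are 0–100 everywhere; the only 0–1 conversion lives inside
  the simulator.
- `predict` accepts negative doses (the curve is defined there); observation
  tables reject them, as accumulated doses are nonnegative by construction.
- Regime construction rejects non-finite temperatures, values outside
  0–45 °C, and photoperiod splits that do not sum to 24 h.
- Forward/inverse round-trips hold to 1e-9 across the parameter grid;
  goodness-of-fit agrees with brute-force sum-of-squares arithmetic to
  1e-12 (both tested).
- The stochastic recovery suite uses 200 cohorts of 1000 plants; the
  convergence check of the ever-spiking fraction uses a single 10⁵-plant
  cohort. These sizes make the whole suite run in a couple of seconds while
  leaving the binomial standard errors small enough for the stated bounds.

## Known limitations

- The estimator is least squares on percentages, not a binomial likelihood;
  cohort-size weights are accepted but off by default to match the published
  fits. A GLM route would be a natural extension.
- The dose index has no high-temperature inhibition term unless explicitly
  enabled, and no humidity, light-intensity or photoperiod covariates.
- Scheduling is whole-day and calendar-free: no holidays, no partial final
  days, no room-capacity optimisation.
- Whether the historical data pools used the same clamped day+night dose
  definition cannot be verified from the published record; the package
  applies one definition uniformly.
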