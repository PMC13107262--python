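# Methods

## The measurement process

Accelerometer/depth acoustic tags (V13AP/V13TP class) transmit an ID
plus one sensor value at random intervals drawn uniformly between a
minimum and maximum delay (200–300 s for the standard protocol; 40–60 s
for the 2024 high-rate protocol), alternating depth and acceleration
1:1. The transmitted acceleration is a single smoothed value: the mean
of tri-axial magnitudes sampled at 12.5 Hz over a 25-s window, clipped
to the tag's dynamic range — 0 to 3.43 m/s² (standard) or 0 to 4.9 m/s²
(2024). The ceiling makes the data right-censored: a tag at or above
the ceiling reports exactly the ceiling. Transmitted values are
quantised (we model 8-bit resolution for acceleration, 0.2 m for
depth).

Moored receivers log transmissions with an imperfect clock; the error
accumulates approximately linearly between the satellite-synchronised
initiation and download time stamps, which is what the linear
correction assumes. A transmission may be heard by several receivers
(duplicates), missed entirely, or a spurious record may be decoded from
noise (typically an isolated detection).

## Cleaning chain

Stages run in a fixed order on time-corrected records, each
non-increasing in record count and reconciled in a removal ledger
(input = output + removed):

1. **Clock correction**: `t ← t − drift·(t − start)/(end − start)`,
   anchored at receiver initiation/download. Applied before all
   filters. Records outside the deployment interval pass through with a
   warning.
2. **Dead fish**: a fish whose depth range never exceeds
   `depth_epsilon` (default 0.5 m — the scale of the depth sensor's
   resolution; configurable) is removed entirely; otherwise the record
   is truncated from the earliest depth-record time whose suffix stays
   within `depth_epsilon` for longer than `stillness_window` (default
   1 day) through the end of the record. A terminal flat stretch
   shorter than the window is kept (the fish may simply have left the
   array).
3. **Deduplication**: among records sharing (fish, sensor, value),
   groups are built greedily in time order — the earliest ungrouped
   record anchors a group absorbing every later match within the
   minimum tag delay of the *anchor* — and only the anchor is kept.
   Anchor-based closure is a deliberate choice (a gap rule chained
   across receivers could merge distinct transmissions); the
   implementation uses a vectorised fast path for sessions that span
   less than one delay and an exact scan otherwise, and is tested
   against a naive reimplementation.
4. **Lone daily detections** are dubious decodes and removed; calendar
   days are evaluated in a configurable timezone (default Europe/Oslo,
   the study region's local time).
5. **Depth pairing**: each accelerometer record is assigned the
   same-fish depth record minimising |Δt|, ties broken toward the
   earlier record; accel records with no depth within 1800 s are
   dropped and counted. The pairing fraction is reported before scope
   restriction. With the standard protocol the assigned depth typically
   sits one tag delay (200–300 s) away.
6. **Scope**: fish depths ≤ 60 m (inclusive), tagging calendar year
   only (UTC), and removal of records inside exclusion windows
   (noise-exposure periods).
7. **High-rate trimming**: fish on the 2024 protocol keep every fifth
   time-ordered pair (indices 0, 5, 10, …), aligning their effective
   transmission rate with the standard protocol.
8. **Labels**: season — February–March = spawning, May–December =
   feeding, January and April omitted as transitional; depth category —
   half-open split `[0, 20)` shallow, `[20, 60]` deep. Exactly 20.0 m
   is deep by this convention (the verbal "< 20 m, > 20 m" definition
   leaves the boundary point undefined; the measure-zero choice cannot
   affect results, only determinism).

## Censoring imputation

Within each dataset (ground × year), transmitted accelerations are
modelled as a censored Gaussian with one mean per fish and a common
residual s.d.; values exactly at the ceiling are the censored ones.
The likelihood uses density terms below the ceiling and upper-tail
survival terms at it. Two equivalent fitters exist: a general-design
BFGS fit with analytic gradient (delta-method covariance for Wald
intervals), and an EM specialisation to the group-mean design (E-step:
truncated-normal conditional moments; M-step: closed-form updates) that
is O(n) per iteration and used inside the pipeline. They agree to
~1e-4 on shared problems, and the general fitter matches
`survival::survreg(dist = "gaussian")`.

Each ceiling value is then replaced by one random draw from the fitted
truncated-normal upper tail at its fish's mean. Single stochastic
imputation (not the conditional mean) is used so the extra variance
propagates into the per-fish means that downstream models weight;
multiple imputation with between-draw pooling is out of scope. With no
censored values the step is the identity. Fish identity is the only
imputation covariate: fish-level means are exactly what the
aggregation consumes; the covariate set is configurable.

## Per-fish statistics

Each fish contributes one value per analysis — the mean of its imputed
accelerations in scope — or two values when split by depth category,
weighted by the natural log of its detection count. Log base is a
convention choice; since only relative weights matter to the fits, the
base is irrelevant except for the n = 1 fish, whose strict ln 1 = 0
weight would silently delete it. The default floors the weight at ln 2
(flag `weight_floor=False` restores strict ln n).

`P_HV` is the per-fish(-stratum) fraction of values strictly above
2 m/s², the burst/sprint acceleration range for cod; ceiling-imputed
values can only move further above the threshold, so imputation never
lowers `P_HV`. Before beta regression, proportions are squeezed into
(0,1) by `(p·(n−1) + 0.5)/n` with `n` the number of rows in the model
table (the sample-size convention of the standard squeeze); the
transform is monotone, fixes 0.5, and tends to the identity as n grows.

## Models

All fits are weighted maximum likelihood (mixed models by ML, not REML,
so likelihoods are comparable across fixed-effect subsets). Weights
enter as precision (GLM prior) weights: Gaussian variance σ²/w, gamma
shape k·w, beta precision φ·w. A constant rescaling of all weights is
therefore absorbed by the dispersion parameter, which keeps Wald
inference calibrated when the weights are only relative.

* **Weighted LM** (`gaussian_lm`): statsmodels WLS; t-based p-values.
* **Weighted LMM** (`gaussian_lmm`): one random intercept (year);
  marginal likelihood maximised directly with β profiled out by GLS;
  Woodbury identities keep each group linear in its size. Matches
  `lme4::lmer(REML = FALSE)` to ~1e-4.
* **Gamma GLMM** (log link) and **beta GLMM** (logit link): fish-level
  random intercept, optionally nested in a year intercept. The marginal
  likelihood is evaluated by *adaptive* Gauss–Hermite quadrature:
  per-fish conditional modes found by damped Newton (both conditional
  log-densities are concave in the intercept), nodes centred at the
  mode and scaled by the conditional s.d., 15 nodes by default.
  Non-adaptive quadrature is not sufficient here: with thousands of
  detections per fish the conditional posterior is far narrower than
  the prior and prior-scaled nodes miss it. The nested year level uses
  the same adaptive scheme with the outer mode found by
  finite-difference Newton on the inner integrated likelihood.
  Estimates match `glmmTMB` to ~1e-4 when the Laplace approximation is
  accurate (many observations per group) and are *more* accurate
  otherwise (verified by node-count invariance and exact-likelihood
  comparison at both optima).
* Wald z inference on fixed effects from the numerically evaluated
  observed information; random-effect variances below 1e-5 are pinned
  to 0 and flagged singular. Gamma responses equal to 0 (possible in
  quiet feeding-season aggregates) are shifted by half the smallest
  positive value, with a logged note. ICC = τ00/(τ00 + σ²) with a
  family-specific observation-level variance on the latent scale:
  σ² for Gaussian, trigamma(shape) for gamma/log, and the delta-method
  variance 1/((1+φ)·μ(1−μ)) averaged over observations for beta/logit.
  Marginal/conditional R² follow the usual latent-scale variance
  partition.

Treatment contrasts are fixed with female and shallow (< 20 m) as the
reference levels, so the intercept is the female/shallow value.

**AICc selection**: every hierarchically valid subset of the starting
fixed effects (interactions require their main effects; random effects
always kept) is fitted by ML and ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), k counting fixed effects plus
variance/dispersion parameters. The retained set is the union of terms
appearing in any model within 2 AICc units of the best; the final model
refits that union. Candidates with n ≤ k + 1 are skipped (AICc
undefined).

## The simulator

What it emulates: the tag protocol (uniform delays, 1:1 alternation,
window smoothing, quantisation, censoring); behaviour as baseline
locomotor noise plus a homogeneous Poisson burst process whose rate
depends on sex, season and current depth stratum, with lognormal burst
magnitudes expressed directly as window-mean increments; per-fish
lognormal heterogeneity in baseline level and in each stratum's burst
rate; depth as an exact-discretisation mean-reverting (OU) walk around
a sex-specific mean (males deeper), reflected at 1 m and the seabed,
with optional female descents toward the male mean depth and frozen
depth after death; receivers with per-transmission detection
probability, linear clock drift, and spurious lone detections. All
randomness descends from one master seed through named substreams
(schedule / behaviour / detection, then per fish), so a fixed seed
reproduces every layer bit-for-bit.

Two equivalent activity paths exist: a per-sample trace (samples at
12.5 Hz, explicit burst episodes of finite duration) used for
single-window work, and a window-level path (baseline window mean drawn
as N(μ, σ/√312); each burst adds its magnitude) used for whole-study
simulation. They share the same window-mean distribution up to
burst-edge truncation, which the window-level path ignores.

What it does not emulate — and hence what passing tests cannot show
about real data: acoustic propagation and collision physics (detection
is i.i.d. Bernoulli, not range- or noise-dependent), tidal/diel
structure, movement in and out of the array, temporal autocorrelation
in behaviour beyond the burst process, tag failure, or fish that shed
tags. Parameter-recovery results demonstrate correctness of the
estimators under the stated generative model, not robustness to these
field realities.

### Default scenario conditions

The stock spawning-ground scenario uses 60 fish (30 per sex), a 30-day
February–March deployment, the standard tag, one receiver with
detection probability 0.5 (a typical mid-range value for coastal
arrays), 30 s of accumulated clock drift, and behaviour defaults chosen
to look like a lekking ground at realistic effect sizes: equal
baselines (0.25 m/s² sample mean, s.d. 0.3), burst rates per hour of
6 (shallow, both sexes), 3 (deep females) and 9 (deep males) — a 3×
male deep excess producing an interaction of ~0.2–0.3 on the log scale;
burst magnitudes lognormal(meanlog ln 2.5, sdlog 0.6) so a minority of
burst windows saturate the 3.43 m/s² ceiling (~2% of transmissions
censored); fish heterogeneity s.d. 0.25 (log burst rate, per stratum)
and 0.15 (log baseline); depth means 15 m (F) and 30 m (M), stationary
s.d. 7 m, relaxation time 1 h, two 30-min female descents per day. The
null variant sets the male deep rate equal to the female deep rate and
changes nothing else. The net-pen scenario confines depth to < 6 m,
detects every transmission, and raises male burst rates tenfold, making
censoring common, as confinement does.

### Study sizes used in the verification suite

Simulation sizes in the tests are the package's chosen verification
conditions: tag-protocol statistics at 10⁵ intervals; filter oracles on
100 random 1000-record instances; censored-model recovery at n = 2000
with ~20% censoring and coverage over 200 replicates; end-to-end
effect recovery and type-I error at the default scenario (60 fish,
30 days, ~3×10⁵ detections) over 100 replicates per arm; `P_HV`
construction at 10⁴ windows with burst-in-window probability 0.2.

The AICc-retention simulations are deliberately small-sample, where the
criterion's parsimony pressure is decisive and which mirror the
net-pen-scale datasets this selection step is used on. Designed from
the finite-sample likelihood-ratio distribution (n·log(1 + F/(n−p)),
F-distributed, not its χ² limit): at n = 8 a strong single covariate is
retained exactly in ≈96% of fits (a spurious addition lands within 2
AICc units with probability ≈0.04), and at n = 6 pure-noise candidates
are all rejected in ≈90%.

## Numerical choices and degenerate inputs

* Timestamps are float epoch seconds internally; CSV interchange is
  ISO-8601 UTC.
* Tied pairing distances prefer the earlier depth record
  (deterministic).
* Censoring indicator is `value ≥ ceiling`; quantisation maps any
  saturated window to exactly the ceiling, so equality is exact.
* The Tobit BFGS fit accepts a stationary point whose gradient is
  negligible even when the line search ends on precision loss; EM stops
  on a 1e-9 relative log-likelihood change.
* All-censored (or any fully censored group) raises — the likelihood
  is unbounded; imputation refuses a non-converged fit.
* Empty aggregation groups emit no row; an empty model table skips that
  model (warning), and a run in which nothing is fittable aborts with
  the stage name and the ledger so far.
* GLMM variance parameters are optimised on the log scale within
  [e⁻¹², e⁶]; the lower bound doubles as the singularity detector.

## Known limitations

* Single imputation understates the uncertainty contributed by the
  censoring model; at the ~2% censoring rates of field-like scenarios
  this is negligible, in net-pen-like regimes it is not.
* The weighted-likelihood treatment of log-n weights is a convention,
  not a probability model; Wald coverage under strong weight
  heterogeneity is approximate (verified ≈ nominal at the study's
  weight spread).
* p-values for mixed models are Wald z (no Satterthwaite/Kenward-Roger
  small-sample correction); with ≲ 20 groups they are anti-conservative.
* The nested (fish-in-year) quadrature assumes each fish is observed in
  one year, which the tagging-year restriction guarantees upstream.
* Clock-drift inversion applies the linear correction to the recorded
  time rather than solving for true time; the residual error is
  second-order in drift/deployment-length and far below the tag-delay
  time scale.
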