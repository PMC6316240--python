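# Methods

## Scope and data model

`mbrkit` models a 48-reactor fed-batch screening campaign end to end.  The
interchange format is a long-format measurement table
(`run_id, time_h, variable, value, replicate, censored`) with eight observed
variables: biomass (g L⁻¹ dry weight), glucose, ethanol (g L⁻¹), volumetric
EPG activity EA_v (U mL⁻¹), pH, DOT (% air saturation), broth volume (L) and
cumulative base addition (L).  All campaign analytics operate on this table;
the simulator is one producer of it, real at-line data would be another.

## Feed design

Every run follows batch → (optional 2-h hunger) → two-phase fed-batch.

* Initial feed rate: F₀ = µ_set/(S_in·Y_X/S) · X₀·V₀, with the design yield
  Y_X/S = 0.5 g g⁻¹ and X₀ the biomass concentration present at feed start in
  that reactor (the campaign generator fills it from the batch simulation; a
  configurable fallback of 1.70 g L⁻¹ serves stand-alone scheduling).
* Phase 1 (12 h): exponential F₀·e^(µ_set·t); linear anchored at F₀ with the
  slope 2F₀[(e^(µ_set·T)−1)/µ_set − T]/T²; constant at the exponential's
  time-average F₀(e^(µ_set·T)−1)/(µ_set·T).  The linear and constant forms
  are *derived* from the equal-glucose requirement: all three shapes deliver
  F₀(e^(µ_set·T)−1)/µ_set liters over phase 1 (exact, tested to 1e-9
  relative).
* Phase 2: one constant rate per feed-rate group, set to the exponential end
  value F₀·e^(µ_set·T) so the exponential profile is continuous at the
  switch.  The source protocol states only that the phase-2 rate is equal
  across profiles of a group; continuity pins the remaining freedom.
* Discretization: pulses every 5 min; each pulse delivers the exact integral
  of the continuous profile over its interval, clipped at 30 µL.  Clipped
  volume is discarded (under-delivery), not carried over — consistent with
  clipping "shortening" the effective high-feed phase.  Feed stock is
  100 g L⁻¹ for µ_set = 0.0875 h⁻¹ and 500 g L⁻¹ for the two higher rates;
  with the dilute stock at 0.175 h⁻¹ the phase-2 feed alone would overflow a
  10-mL reactor.

## Kinetic model of the generator

The generator is declared an *emulation*: no growth equations are available
for the reference process, so a Sonnleitner–Käppeli-style bottleneck model
supplies trajectories whose printed summary statistics and qualitative regime
structure match the reference campaign.  Specific rates (per g dry biomass):

* glucose uptake q_S = q_S,max · S/(K_S+S) · f_E(E) · σ(t), with
  q_S,max = 1.61 g g⁻¹ h⁻¹, K_S = 0.1 g L⁻¹;
* oxidative/overflow split at the respiratory capacity
  q_S,crit = 0.90 g g⁻¹ h⁻¹: the oxidized part yields Y_XS,ox = 0.118 g g⁻¹
  biomass, the overflow part yields Y_XS,ferm = 0.045 g g⁻¹ plus ethanol at
  Y_ES = 0.48 g g⁻¹;
* ethanol uptake q_E = q_E,max · E/(K_E+E) · K_I,S/(K_I,S+S) · σ(t)
  (q_E,max = 0.45 g g⁻¹ h⁻¹, K_E = 0.5, K_I,S = 0.05 g L⁻¹ — strong glucose
  repression), biomass yield Y_XE = 0.30 g g⁻¹;
* ethanol stress: f_E halves glucose uptake around E ≈ 15 g L⁻¹
  (threshold 10, quadratic width 5 g L⁻¹), which self-limits ethanol in
  high-feed runs near the observed ~15 g L⁻¹; a second stress term divides
  the biomass yields by 1+(E−5)/3 above 5 g L⁻¹, keeping the biomass at feed
  start only mildly higher for S₀ = 30 than for S₀ = 20;
* product formation q_P = q_P,max · (µ/µ_opt)e^(1−µ/µ_opt) · K_IE,P/(K_IE,P+E)
  · e^(−k_dec·max(0, t−t_BE−8 h)) · σ(t), with q_P,max = 250 U g⁻¹ h⁻¹,
  µ_opt = 0.045 h⁻¹, K_IE,P = 1.5 g L⁻¹, k_dec = 0.2 h⁻¹ and t_BE the run's
  batch end.  Anchoring the late productivity decline to the culture's own
  batch end (its physiological age) rather than campaign time is what makes
  the lowest feed rate with S₀ = 30 g L⁻¹ the top late producer, as observed;
* growth stagnation σ(t): logistic decline to 5% centered at 36 h (width
  2 h), after which glucose accumulates in every run;
* DOT is a quasi-steady display variable, 100·(1 − OUR/OTR_max) with
  OUR = (0.40·q_S,ox + 1.95·q_E)·X and OTR_max = kLa·c*_O₂ = 3.0 g L⁻¹ h⁻¹;
  oxygen never feeds back on growth.  pH is one-side controlled at 6.0 with
  an upward drift (0.012 h⁻¹) whose onset lags feed start by
  3 h + 0.5/µ_set — later at lower feed rates, as observed.

Integration is explicit Euler (default dt = 1/240 h = 0.25 min) on mass
totals, with feed pulses and 250-µL sample withdrawals applied as impulses
on the step grid.  Because consumption is accumulated with the same
quadrature, the glucose balance S₀V₀ + fed = consumed + residual holds to
float precision, and the volume balance V = V₀ + feed + base − evaporation −
samples is exact by construction.  Withdrawals remove volume and mass
proportionally (concentrations untouched); evaporation (4 µL h⁻¹)
concentrates.  Base addition tracks growth at 1.6 mL per g biomass formed
(3.5 M ammonia titrated against growth-linked acidification).

Batch end is defined by glucose depletion (S < 0.05 g L⁻¹); feed start is
batch end plus the hunger phase.  The batch phase depends only on
(S₀, hunger), so the generator runs one batch pre-simulation per group to
set each run's feed-start biomass and batch end before scheduling.

### Calibration and its tension

Defaults are calibrated so that the *noiseless* S₀ = 20 g L⁻¹ batch, read
back through the package's own finite-difference estimators at the 2-h
sampling cadence, reproduces the reference batch-phase physiology:
µ ≈ 0.138 h⁻¹ (reference 0.18 ± 0.05), q_S ≈ 1.58 g g⁻¹ h⁻¹
(1.34 ± 0.34) and biomass at feed start ≈ 1.93 g L⁻¹ (1.70 ± 0.28).  The
three reference centers are mutually inconsistent with a closed glucose
balance — µ/q_S·S₀ ≈ 2.7 g L⁻¹ of biomass would have to form from 20 g L⁻¹
glucose, yet only ≈1.7 g L⁻¹ is present at feed start — so no constant-yield
model can hit all three centers; the defaults sit inside all three ranges
simultaneously instead.  A consequence of the feasible compromise (lower µ,
low yields reflecting the strain's heavy metabolic burden) is that simulated
batches run ≈17.8 h (S₀ = 20) and ≈20.5 h (S₀ = 30) rather than the observed
15/16.55 h.  The package's default analysis landmarks are therefore placed
at the *same process phases* rather than the same clock times: early target
26 h, late target 40 h, campaign end 48 h.

### Observation model

At-line sampling follows the robot's column-wise scheme on the 8×6 block:
batch-phase rounds every 2 h with 5-min offsets between columns (single
determination); from the campaign-wide fed-batch start, one column every
20 min, giving every reactor a 2-h period, with biomass/glucose in duplicate
and EA_v in triplicate.  Noise is multiplicative Gaussian (biomass 5%,
glucose 7%, ethanol 8%, EA_v 10%, DOT 3%, volume 1%, base 2%; pH additive
sd 0.02).  Ethanol below 1.0 g L⁻¹ (the post-dilution detection limit) is
reported left-censored *at* the limit with a flag, keeping the unfolded
matrix rectangular; a half-limit substitution is available as an option.
Run 46 carries the default injected failure: from 0.5 h its pH reading
drifts high and its DOT flatlines, and the mis-handled culture grows at 55%
of the healthy rate, so the run is multivariately abnormal from early on.
All randomness derives from a single campaign seed via per-run substreams.

## Preprocessing

Biomass is normalized to the start volume, X_N = X·V_dil/V₀, where V_dil
accounts for feed, base and evaporation but *not* sample withdrawals —
withdrawals remove culture without diluting it, and including them would
bias the growth-rate estimator by about −4%.  Other variables are left
unnormalized.  Specific rates use consecutive sample pairs:
µ = (ln X_N,2 − ln X_N,1)/Δt, q_S = (S₁−S₂)/(Δt·X̄) (consumption positive),
q_P = (EA_v,2 − EA_v,1)·1000/(Δt·X̄) with X̄ the arithmetic-mean biomass and
the factor 1000 converting U mL⁻¹ per g L⁻¹ into U g⁻¹.  On noiseless
simulated batches the estimators recover the model's µ to better than 1e-3
h⁻¹ at fine sampling; q_S carries an additional ≈1% bias from evaporation
and base flows entering dS/dt.

Staggered samples are rectangularized by averaging duplicate determinations
and linearly interpolating onto a common grid (default 2 h, the per-reactor
sampling period); boundary values are held, never extrapolated.  Batch-wise
unfolding stacks one row per run with columns ordered variable-major,
time-minor; autoscaling centers and scales each column (n−1 denominator),
zeroing and flagging constant columns.

Because the batch length differs between S₀ groups by ≈2.7 h, the
diagnostics stage grids each run on time *relative to its feed start*
(landmark alignment, the standard remedy for unequal batch lengths in
batch-wise MSPC) over the first feed phase, τ ∈ [0, 12] h.  On the absolute
clock the unfolded matrix is dominated by the batch-length difference and
the leading score direction separates S₀ groups; aligned on the feeding
response, the dominant structure is the feed-rate regime, as in the
reference campaign.  The PLSR history models keep absolute-time horizons
(a soft sensor consumes "everything measured until now").

## Multivariate stages

**PCA** is computed by SVD of the autoscaled matrix; component signs are
fixed by making each component's largest-magnitude loading positive.  The
retained dimension defaults to the smallest number of components explaining
≥80% variance, capped at 5.  Outliers are flagged by Hotelling's
T² = Σ t²_j/λ_j over retained components against the F-limit
k(n−1)/(n−k)·F_{k,n−k}(1−α), α = 0.01.

**k-means** runs on the retained (unwhitened) scores with greedy
furthest-point seeding from a seeded random first center, best of 50
restarts by inertia; restarts ending with an empty cluster are consumed from
the pool.  k defaults to 2 after outlier removal (the campaign's two
process regimes); the spec-level default of 3 on the full set corresponds to
outlier + two regimes.

**CART** (shared by cluster characterization and optimization) splits
numeric factors by threshold and the categorical feed profile by exhaustive
binary subset partition (exact at cardinality 3); classification uses Gini,
regression variance reduction.  A split must remove at least a fraction
`min_gain` of its *parent node's* impurity (default 0.2 classification /
0.35 regression): on permuted targets chance splits rarely clear ~30% of a
node's SSE, while genuine design-factor effects remove most of it, so the
guard suppresses spurious structure without pruning real effects.
Regression trees use min_leaf = 6 — two conditions' worth of triplicates —
so leaves aggregate whole conditions.

**PLSR** is NIPALS with autoscaled X and centered y; for a univariate
response the weight vector per component is X'y/‖X'y‖ followed by deflation,
and models for all nested component counts are available from one fit.  The
component count is chosen per training fold by an inner 5-fold CV (capped at
10).  Cross-validation uses seeded folds with sizes differing by at most
one; the error is the target-normalized RMSECV (a fraction; ×100 = %),
reported as mean ± sd across folds and pooled.  Forward selection adds the
candidate minimizing the mean RMSECV, using one shared fold assignment per
seed so steps and horizons are comparable; ties break to the earlier
measurement time, then variable name (design factors sort first with
time −1).  Selection stops at the first step with no improvement, so the
reported trace is non-increasing.  The history sweep truncates the unfolded
matrix per horizon and reruns the whole selection with identical folds.

**Optimization** fits four regression trees (ethanol and EA_v at the early
and late landmark) on the design factors using the *measured* (noisy)
values of the non-outlier runs.  Optimal paths are all leaves within
slack·(range of leaf means) of the best leaf (slack = 0.15, a repo
convention reproducing multi-row optimal-condition tables); factors not
constrained along a path are reported as "any" ('-').  Superposition maps
each path to its matched condition-id set, unions per target, intersects
across the four targets and reports factor levels shared by every
intersection member; an empty intersection is returned with pairwise-overlap
diagnostics.

## What passing tests do and do not show

The generator reproduces the reference campaign's *structure*: regime
ordering of ethanol in the feed rate, detection-limit censoring at the low
rate, glucose accumulation at the high rate and late in all runs, a single
early-detectable abnormal run, feed-rate-determined clusters (sizes 17/30),
and the (exponential, 0.0875 h⁻¹, 30 g L⁻¹, no hunger) condition recurring
as optimal.  It does not reproduce real MBR data's unmodelled physics —
DOT clogging artifacts, evaporation gradients across the block, pipetting
failures other than the scripted one, organic-acid side metabolism — so
passing tests validate the analytics chain and the stated calibration
targets, not predictive fidelity for any particular wet-lab run.  Known
further limitations: high-feed runs accumulate implausibly high glucose
(>100 g L⁻¹) late in the campaign because the calibrated low-yield cells
cannot consume the clipped-but-large phase-2 feed; volumes in those runs
slightly exceed the nominal 12-mL working volume (no overflow guard); and
DOT/pH are display models without feedback on growth.

## Problem sizes and runtime

Defaults are sized for a laptop core: 48 runs × 48 h at dt = 0.25 min
simulate in ~5 s; the full pipeline including forward selection at the 26-h
horizon and a three-point history sweep takes ~1 min; the test suite ~1.5
min.  The acceptance script simulates only the noiseless batch phase and
runs in seconds.
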