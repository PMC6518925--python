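# Methods

## Time and temperature conventions

A `TemperatureSeries` holds one daily mean water temperature per calendar
day.  Time within a trajectory is measured in fractional days post
fertilization (DPF); the fertilization day is day 0 and spans `[0, 1)`, so a
closed-form prediction of `D` days at constant temperature corresponds to
DPF `D` exactly.  Accumulated thermal units (ATU, °C·day) are the running
sum of daily means, pro-rating the final partial day.  Two configurable
clamps (`ClampPolicy`) apply:

* rate evaluation floors daily means at **0.1 °C** — the lower bound of the
  temperature range the somite-age relationship was fitted on — so
  development never goes negative or explodes near the model boundaries
  (the somite model is additionally clamped to its 0.1–11.0 °C validity
  range);
* ATU sums floor daily means at **0 °C**: thermal units are non-negative,
  and winter logger readings slightly below zero contribute no thermal
  energy.

## Development models and accumulation

Crisp, WinSIRP and Kane predict days-to-event directly; their daily
development fraction is `1/D(T)` and the event fires when fractions sum
to 1.  The somite (Gorodilov) model accrues `1440/τₛ(T)` somite-units per
day with `log₁₀ τₛ = 3.0984 − 0.0967 T + 0.00207 T²`; 50% ("peak") hatch at
315 units and emergence at 450.  Crossings are located by linear
interpolation inside the crossing day; the ATU at the event is the daily-mean
sum through that fractional point.  A series that ends (or is interrupted by
an unfilled logger gap) before a threshold is reached yields an explicit
unresolved status — never an extrapolation.

Two conventions were genuinely open and are fixed as follows:

* **Crisp intercept.**  The commonly reprinted form of the Crisp equation
  carries a corrupt constant term (`log(−11.0)`, undefined).  We use the
  base-10 parameterization `log₁₀ D = 5.1908 − 2.6562 log₁₀(T + 11.0)`
  (equivalently `D = 155200·(T + 11)^−2.6562`), the original Atlantic
  salmon desk-study constant; it is an overridable model parameter.
* **Weekly averaging (WinSIRP).**  `T_wk` is the mean of daily temperatures
  in consecutive non-overlapping 7-day blocks counted from the start date,
  each day in a block contributing `1/D(T_wk)`; a trailing partial block
  uses its own mean.  This is the simplest block scheme consistent with
  "weekly average temperatures"; a rolling mean is a plausible alternative
  and differs negligibly on slowly varying series.

Only the temperature-dependent core of WinSIRP is implemented; its
dissolved-oxygen, pH, flow and waste corrections are out of scope.

## Hatch-timing estimation

Daily cumulative proportions hatched are treated as independent binomial
observations of a logistic curve in cumulative ATU (days post fertilization
is available as an alternative covariate).  The denominator is the number of
eggs that *eventually* hatched: timing is modelled conditionally on
hatching, because hatch success varies widely among maternal families while
timing does not, and dead eggs are removed during incubation.  Estimates are
therefore invariant to death counts by construction.  ATU at 50% hatch is
`−intercept/slope`, at 90% hatch `(logit 0.9 − intercept)/slope`; DPF at 50%
hatch inverts the cumulative-ATU clock.  Treating the cumulative counts as
independent is an approximation (successive days share eggs); the
simulation-based bias checks in the test suite quantify its practical
effect at the design's egg counts.

Degenerate paths: a tube whose eggs all hatch on one observation day has no
identifiable slope — the 50% point falls back to the midpoint between the
last all-unhatched day and the hatch day and the estimate is flagged; a tube
with zero hatch has no estimate and is excluded with a logged reason.
Families whose every tube hatched below 15% (configurable) are removed
before analysis, mirroring the near-total-failure exclusion used in
practice.

## Repeatability and evaluation statistics

The intraclass correlation uses the one-way random-effects ANOVA estimator
`(MSB − MSW)/(MSB + (k₀ − 1)·MSW)` with the unbalanced-design average group
size `k₀`, and an F-distribution (Searle) 95% interval; the interval method
is a choice — the estimator itself is checked against a brute-force ANOVA
oracle on all balanced designs up to 6×6.

Mixed models are random-intercept (maternal family) fits by REML via
statsmodels MixedLM.  The family effect is tested by a likelihood-ratio test
of maximum-likelihood fits against the fixed-effects-only model on 1 df; the
plain χ²₁ p-value is primary, with the boundary-corrected (halved) p-value
reported alongside, since the null variance sits on the parameter-space
boundary.  Fixed effects are tested with Wald F statistics whose denominator
degrees of freedom use a Satterthwaite-type approximation computed directly:
the REML log-likelihood of the random-intercept model is written in closed
form, its finite-difference Hessian gives the covariance of the variance
components, each eigencontrast of the effect's covariance gets
`ν = 2f²/(∇f' A ∇f)`, and the multi-df denominator pools them as
`2E/(E − q)`.  When the family variance collapses to the boundary the F
test falls back to residual degrees of freedom and the fit is flagged
singular rather than raising.  The implementation is cross-checked against
an independent mixed-model stack (R lme4/lmerTest) in the test suite.

Observed-vs-predicted evaluation pairs the treatment × fertilization-date
cells (12 pairs in the bundled design) and applies a two-sided paired t-test
(df = n − 1) to predicted-minus-observed ATU per model.  Zero variance across
pairs leaves t undefined and it is reported as NaN.  The Kane model predicts
90% hatch and is only evaluated when an observed 90% column exists.  Two
prediction modes are provided:

* **closed form at the cell mean** (default): each model's days-to-event is
  evaluated at the cell's mean incubation temperature, predicted ATU =
  `D(T̄)·T̄`.  This is the procedure the bundled per-cell summary supports
  and is the default for reproducing the laboratory evaluation.
* **profile**: rate-summation accumulation over a daily series per cell
  (reconstructed or measured).  An unresolved event refuses the test rather
  than dropping the pair.

The two modes differ systematically on strongly varying regimes (Jensen's
inequality: development is non-linear in temperature, so performance at the
mean is not mean performance); on the warm-spike treatment the profile mode
predicts substantially fewer ATU than the closed form at the mean.  The
somite model's units-per-ATU is minimized near 6 °C, which bounds its
predictable ATU at 50% hatch at ~514 for *any* temperature profile — a
useful sanity bound when comparing against observed values above it.

## Regime reconstruction

The bundled incubation summary prints, per treatment × fertilization date,
the mean incubation temperature, ATU and DPF at 50% hatch.  Daily tank
profiles are rebuilt as: constant treatment at the printed mean; spike
treatments as piecewise profiles (pre-spike level, 2-day linear ramps, 10 °C
or 2 °C plateau of ~3 weeks placed from 20 December, then constant 3.4 °C)
with the pre-spike level solved by root-finding so the cumulative ATU at the
printed DPF₅₀ matches the printed ATU₅₀ exactly.  The printed mean is then
checked over a fertilization-to-last-hatch horizon (DPF₅₀ + 6 days) within
0.5 °C and the residual reported.  The printed mean, ATU and DPF are not
mutually consistent to better than ~0.3 °C in every cell (they were
measured, then rounded), so the ATU constraint is the binding one.  Daily
profiles are not uniquely identified by three printed summary statistics per
cell; the residual ambiguity is inherent to the reconstruction.

## Synthetic experiment generator

`simulate_experiment` draws, per family, a hatch-success probability uniform
on (0.34, 0.78) and a Normal family-level ATU shift; per tube a Normal tube
shift; per surviving egg a hatch ATU from a logistic distribution centred on
the true-model ATU at 50% hatch for that tube's regime.  The logistic choice
makes the estimation module's link correctly specified in the base case; a
Normal mode is provided for misspecification checks.  Daily counts follow by
thresholding cumulative ATU; dead eggs get uniform death days early in
incubation.  Defaults mirror the split-brood design: 17 families over four
November fertilization dates, 50 eggs per tube, 5 replicate tubes in the
constant treatment and one in each varying treatment, family SD 8 ATU and
tube SD 6.4 ATU (an intraclass correlation of ≈0.61 — a family spread small
relative to the ~500 ATU incubation total), egg scale 3 ATU.

The river generator is a seasonal sinusoid (mean 7 °C, amplitude 10 °C,
coldest day in early February — the sub-zero trough clamps to ≈0 °C from
December to April, peaking near 17 °C in summer) plus AR(1) noise
(ρ = 0.85, innovation SD 0.6 °C), clamped at 0.  It emulates the gross
seasonal shape and short-term autocorrelation of boreal river loggers, not
their asymmetric autumn cooling, ice-up dynamics, diel structure or gaps
(gaps are exercised separately).  Passing tests on these series demonstrate
internal consistency of the accumulation and window logic, not field
accuracy for any particular river.

## Problem sizes and runtime choices

The simulation-based checks use 200 tubes for estimator bias, 100 seeded
replicates of a 17-family × 5-tube experiment for interval coverage, and
100 replicates for variance-component recovery; these sizes keep Monte
Carlo error comfortably below the tested tolerances while the full suite
runs in about a minute.

## Known limitations

* In-stream logger temperatures stand in for intra-gravel incubation
  temperatures; gravel buffering is not modelled.
* Emergence is behaviourally mediated and less sharply defined than hatch;
  the 450-somite-unit threshold inherits any bias of tray-reared
  calibration data.
* The logistic fit treats daily cumulative proportions as independent;
  an interval-censored survival formulation would be more rigorous and is
  deliberately out of scope.
* Reconstructed tank profiles are constraint-based, not measured; analyses
  that depend on within-regime temperature ordering beyond the printed
  summaries inherit that ambiguity.
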