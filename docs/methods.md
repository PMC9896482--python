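# Methods

## Induction-time model

The package models isothermal induction times under the single nucleus
mechanism: nucleation events in a stirred volume *V* form a stationary
Poisson process with intensity *J·V*, and detection lags the nucleation
event by a growth time *t_g*. The observable induction time is therefore
shifted-exponential, `P(t) = 1 - exp(-J V (t - t_g))` for `t >= t_g`.
Assumptions worth keeping in mind:

* constant supersaturation and temperature over the measurement (the
  packaged study conditions are paracetamol/isopropanol at 15 °C,
  c = 155.81, c* = 97.38 g/kg, S = c/c* = 1.6);
* one dominant nucleus per run — secondary nucleation and growth are
  lumped into *t_g*;
* no censoring: runs that never nucleated within the observation window
  cannot be represented, and the loader rejects missing or non-positive
  times. Because of this, the median induction time is often the safer
  summary than the mean, and `summarize` returns both.

The empirical cumulative probability of an ordered series assigns the
*i*-th observation `P_i = i/M` by default. The mean plotting position
`i/(M+1)` is selectable wherever an empirical CDF enters a computation:
it keeps `P < 1` at the largest observation and makes noise-free
quantile constructions exactly self-consistent. Tied observations each
keep their own rank, so the step function's value at a tied time is the
largest rank there. For even *M* the median is the mean of the two
central order statistics.

Units are SI everywhere inside the library (s, m³, #/(m³ s)); the
fixture tables print mL, mm and rpm and are converted at the I/O
boundary (mL → m³, rpm/60 → rev/s).

## Estimators

**Direct fit.** Bounded nonlinear least squares (trust-region reflective,
`scipy.optimize.least_squares`, xtol = ftol = gtol = 1e-12) of the model
CDF against the empirical one at the observed times. Default box
constraints are J ∈ [0.01, 20] #/(m³ s) and t_g ∈ [3000, 30000] s —
values that bracket the packaged study's fits; both are parameters. The
objective is flat in t_g above min(t_i) (the model then predicts P = 0 at
every observation), so the solver is multi-started at t_g ∈ {min t_i,
0.5 min t_i, lower bound} with a moment-style start for J, and the best
converged candidate wins. The reported `fit_rmse` is
√(Σ residuals² / M).

**MLE.** The likelihood is nonzero only for t_g ≤ min(t_i) and increases
with t_g on that interval, so t̂_g = min(t_i) exactly; maximizing
`M ln(JV) − JV Σ(t_i − t̂_g)` gives Ĵ = [M / Σ(t_i − t̂_g)] / V. Both
estimates are biased upward (the sample minimum can never undershoot the
true growth time); the benchmark below quantifies the net effect. All-tied
series are rejected as degenerate.

**Bootstrap.** M observations are resampled with replacement n_boot times
(default 1000), the base estimator (direct or MLE) is applied per
resample, and the mean and standard deviation across resamples are
reported. Degenerate resamples (all draws equal) and non-convergent fits
are skipped and counted in `n_failed`. Each call takes one explicit seed
feeding a `numpy.random.default_rng`; resample indices are drawn as a
single `(n_boot, M)` integer block, which fixes the generator contract
and makes runs bit-reproducible.

Note on a subtle point: the bootstrap *mean* does not converge to the
single-fit estimate as n_boot grows. For min-based estimators the
bootstrap expectation of min(t_i*) exceeds min(t_i) by an amount set by
the gap between the two smallest observations, independent of n_boot.
The test suite therefore checks replication stability (two independent
bootstrap runs agree within Monte-Carlo error) rather than convergence
to the plug-in value.

## Synthetic data and the estimator benchmark

Synthetic induction times are drawn by inverse transform: u ~ U[0, 1)
(u = 1 excluded to keep times finite) pushed through the quantile
function t = t_g − ln(1−u)/(JV). The benchmark's default generating
truth is J = 0.1 #/(m³ s), V = 0.01 m³, t_g = 10,000 s — comparable to
the largest-scale (10 L) experimental series — with M ∈ {5, 10, 20, 40,
80} and 1000 datasets per M. Every estimator sees the same datasets at a
given M. Reported errors are mean absolute errors for J, t_g, and
log10(J); the last is the natural band half-width for models that
predict J on a log scale. The closed-form routes (MLE, MLE+bootstrap)
are fully vectorised; the direct fit runs per dataset, and the
direct-fit bootstrap costs n_boot × n_datasets least-squares fits, so
the shipped benchmark configurations default to the closed-form routes
plus the plain direct fit.

At these conditions the benchmark shows MAE falling monotonically with M
for every method and the MLE at least as accurate as the direct fit for
both parameters at M ≤ 20 — the basis for using the MLE (and its MAE
curves as error bands) throughout the downstream analysis. The
MLE+bootstrap J error explodes at M = 5: resampled five-point series
frequently have tiny Σ(t_i − min), inflating 1/Σ.

## Fabricated studies

Real CFD feature values and raw induction times for the 17 packaged
configurations are not publicly deposited, so the correlation and
ensemble stages are exercised on a fabricated study with known ground
truth. The fabrication recipe is a fixture, not flow physics:

* family bases from classical scalars — shear-rate family ∝ impeller
  speed × impeller-type constant × √(d/D); dissipation family = specific
  power per unit mass; turbulent-kinetic-energy family ∝ u_tip²;
  velocity family ∝ u_tip; signed axial/radial means with
  impeller-type-dependent sign and magnitude; power draw ∝ specific
  power;
* each family mean gets lognormal jitter (σ = 0.1) seeded from the
  *geometry only*, so the fields are exactly monotone in impeller speed
  within a vessel/impeller family;
* quantiles are fixed multiples {0.55, 0.8, 1.15} of the family mean,
  making quantile columns perfectly collinear with their family mean so
  the Pearson reduction has realistic work to do (on the default
  17-configuration fixture it drops 16 of 24 numeric columns).

Ground-truth kinetics follow a recorded linear mapping in (log-volume,
standardized-feature) space: log10 J = −3.26 − 0.85·log10 V +
0.25·z(sr_mean) + 0.20·z(ep_mean), and t_g = 11000 − 3000·z(rpm) −
2000·z(ep_mean), floored at 600 s. The intercept and volume slope place
J near 1 #/(m³ s) at 85 mL falling to ~3×10⁻² at 9.3 L, and t_g around
10⁴ s — the magnitudes the packaged fixture table reports. Each
configuration's induction times are then sampled exactly from the model
CDF; the default 80 times per configuration is the sample size generally
considered adequate for resolving an induction-time distribution, with
mild configuration-level scatter (σ = 0.03 on log10 J, 300 s on t_g) on
top of the mapping.

What passing tests on this fixture does show: the pipeline's plumbing,
leakage-freedom, the reduction logic, and that the model zoo +
attribution can recover a known monotone feature→kinetics mapping from
realistic collinear features. What it does not show: that real CFD
fields have these correlation structures, or that real nucleation
kinetics are linear in these features.

## Hydrodynamics

Re = ρND²/μ, u_tip = πND, ε̄ = N_p ρ N³ D⁵ / V with power numbers 1.3
(pitched-blade) and 1.07 (retreat-curve). The denominator volume in ε̄
is the working liquid volume, not the vessel capacity. Fluid properties
are required inputs with an isopropanol-solution preset (ρ = 800 kg/m³,
μ = 2.4 mPa·s). The CFD `power_draw` column and the computed ε̄ are kept
as distinct fields: related quantities, different provenance. Loaded
feature tables are validated for presence of all 19 columns, positivity
(axial/radial means may be signed), and q25 ≤ q50 ≤ q75 per family, with
errors naming the offending column/row; derived scalars are appended and
never overwrite CFD columns.

## Regression workflow

* J is modelled as log10 J (its values span two decades across scales);
  all J-side RMSE/R²/band metrics live on that scale.
* Numeric features are standardized with training-split statistics only;
  the impeller type becomes two binary indicators (left binary, not
  re-standardized). Zero-variance training columns raise by name.
* Collinearity pruning visits columns in canonical order (volume,
  impeller speed, the 19 CFD columns in table order, Re, u_tip, ε̄) and
  drops the later member of any pair with |Pearson r| > 0.95 — a
  deterministic tie-break; the categorical column always survives.
* The zoo: linear, ridge, LASSO, random forest, gradient boosting, kNN
  on the reduced set, univariate linear benchmarks on single named
  scale-up features, and constant-value benchmarks (overall training
  mean, or per-impeller-type means). Hyperparameters come from small
  fixed grids (ridge/LASSO penalty: 6 log-spaced values in [1e-3, 1e2];
  forest/boosting: depth {2, 3} × trees {50, 200}; k ∈ {2, 3, 5})
  selected by leave-one-out RMSE over the 14 training rows, with a fixed
  seed for the stochastic learners. Standardization is refit inside each
  LOO fold.
* R² uses a worse-than-mean convention: negative raw values are reported
  as NaN (such a model is better replaced by the mean), as is the
  zero-variance-actuals case.
* Error-band metrics report the percentage of predictions within the
  estimator MAE at M = 5 and M = 20 — the bands are the *measurement*
  uncertainty of the targets, so a model inside them is as good as the
  data can distinguish. For J the bands are the mean absolute
  log10-errors, applied on the scale the models predict.

## Ensembles and attribution

An ensemble is one J model plus one t_g model pushed through the model
CDF (J back-transformed from log10, t_g floored at 0). Scoring takes
residuals at the *observed* induction times — between the empirical
cumulative probability and the predicted curve interpolated on its grid
— so a perfect model scores zero regardless of grid. The headline RMSE
pools all residuals before the square root; the mean of per-configuration
RMSEs is reported alongside. A predicted t_g above all observed times is
allowed but flagged (`late_onset_configs`): the ensemble then predicts
zero nucleation probability at every observation, the characteristic
failure of constant-t_g scale-up rules at unseen scales.

Feature attributions are interventional Shapley values computed exactly
by coalition enumeration (≤ 12 players; seeded permutation sampling
beyond): v(S) is the model prediction averaged over background rows
(the training split) with the features in S pinned to the explained
row. The categorical impeller type is one player. Exactness buys the
additivity axiom to float precision and the closed form
β·(x − mean(x)) for linear models. The reported direction per feature
is the sign of the correlation between feature value and attribution; a
known limitation is that tree models can absorb a weak effect into a
correlated stronger feature, leaving the weak feature's attribution near
zero with an unstable sign.

## Pipeline, seeds, problem sizes

`run_pipeline` derives one sub-seed per stochastic stage (study
generation, benchmark, training, attribution) from the root seed via
`numpy.random.SeedSequence`, records them in `manifest.json` together
with per-stage wall times, and writes every intermediate table as CSV;
runs with the same configuration are byte-identical. The default run
fabricates the 17-configuration study (80 times per configuration),
fits kinetics by MLE, computes error bands from a 1000-dataset MLE
benchmark, trains both model zoos, ensembles the best-LOO multivariate
pair against the no-CFD benchmark pair (tip-speed univariate J +
per-impeller constant t_g), and attributes the ensemble members. The
test suite and the acceptance script use these sizes, except that
full-grid direct-fit benchmarks cap at 1000 datasets per M (the
closed-form routes are vectorised and effectively free).

## Known limitations

* No censored-data likelihood; series where some runs never nucleated
  must be truncated before loading, biasing fits toward faster kinetics.
* Single-nucleus Poisson only — no Weibull or two-step alternatives.
* The fabricated CFD tables are schema- and correlation-realistic, not
  physically simulated; conclusions about real vessels require real CFD.
* With 14 training configurations, the nonlinear learners sit at the
  edge of what leave-one-out validation can support; grid choices are
  deliberately small and shallow.
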