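# Methods

This note documents the model implemented by `radtse`, its assumptions,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## The tumor-growth model

Total tumor volume is the sum of six compartments.  Proliferating cells
`V1` grow at rate `kg` [1/day] and die naturally at rate `kk` [1/day];
dying cells pass through a three-stage transit chain `V2 → V3 → V4`, each
stage at rate `kk`, before leaving the system.  The initial condition

    V_i(0) = V0 (kk/kg)^(i-1),  i = 1..4,   U1(0) = U2(0) = 0

is the composition under which the untreated tumor grows exactly
exponentially at net rate `kg − kk`; `V0` [mm³] is the initial
proliferating volume.  With the reference estimates (`kg = 0.44`,
`kk = 0.30`) the untreated doubling time is `ln 2 / 0.14 ≈ 5` days.

Radiation acts twice:

* **Short-term (per fraction).**  At each application of dose `D_R` [Gy],
  a fraction `F = 1 − exp(−(1 + a C)(α D_R + β D_R²))` of `V1` is moved
  instantaneously to `U1` — the linear-quadratic cell-kill model with
  `β = α / 10` (α/β ratio fixed at 10 Gy) potentiated by the
  radiosensitizer plasma concentration `C` [µg/mL] through the potency
  `a` [mL/µg].  `U1` cells divide once (two daughters enter `U2`, hence
  the factor 2 in its inflow) and then die through the transit chain —
  this reproduces the observation that lethally irradiated cells survive
  one or a few cycles.  Impulses conserve total volume.

* **Long-term (accumulated dose).**  The growth rate is multiplied by an
  inhibition factor `I` driven by the accumulated dose, scaled by
  `(1 + b C)` for the radiosensitizer (potency `b` [mL/µg]).  Three
  functional forms are supported: exponential `exp(−γ D̃)`, saturating
  `1 − γ D̃ / (ID50 + D̃)` and linear `1 − γ D̃` (the default; the linear
  form may go negative, which is read as net shrinkage and is exactly the
  regime the stasis machinery depends on).

**Dose-scale convention for γ.**  The effective dose argument is
`D̃ = D_acc (1 + b C) / dose_scale` with `dose_scale = 10` Gy, i.e. γ is
expressed per 10 Gy of accumulated dose.  Under this convention the
reference γ values reproduce the package's worked inhibition numbers
(γ₁ = 0.027 → 16% at 60 Gy; γ₂ = 0.044 → 26%; γ₁ with C = 1 µg/mL of the
first compound → 20%) and yield stasis doses on the scale the TSE analysis
reports.  γ₃ = 0.02 evaluates to 12% at 60 Gy at the printed rounding
(a 13% figure circulates for that case; the difference is rounding of γ₃).
Similarly, the per-fraction kill at 2 Gy is 13.4% with β included; the
α-only figure is 11.3%.  Both are printed by the worked example; the
simulation always includes β.

`I` is re-evaluated after each impulse from the updated accumulated dose
and the concentration active at that application, and held constant
between impulses and after the last fraction.  The exposure driver is a
single constant concentration per application (observed-Cmax convention);
no PK compartment model is used.

## Trajectory computation

Between impulses the system is linear with constant coefficients and a
lower-triangular matrix, so trajectories are computed by an exact
piecewise-analytic propagator rather than a generic ODE solver.  The
damage-chain response to the exponentially evolving `V1` and decaying `U1`
is written in terms of the functions `φ_j(z) = (e^z − Σ_{i<j} z^i/i!)/z^j`,
evaluated by Taylor series below |z| = 0.5 and by an `expm1`-seeded
recurrence above.  This is numerically exact through the stasis resonance
`kg·I → 0`, where naive particular-solution formulas suffer catastrophic
cancellation.  Segments longer than 250 days are split so exponential
arguments stay far from overflow.

The inner loop is JIT-compiled (numba) and vectorized across subjects; a
pure-NumPy implementation of the same mathematics is kept as the reference
path, and the test-suite asserts agreement between the two, against
`scipy.linalg.expm` propagation on random segments (≤ 1e−8 relative), and
against a tightly-toleranced stiff initial-value integrator.

## Tumor static exposure (TSE)

A TSE curve is the set of pairs (concentration, total dose) that hold the
tumor at stasis under a fixed fractionation — above the curve the model
predicts shrinkage and eventual eradication.  The stasis test is
one-sided: total-volume derivative at the evaluation time `t* = 60` days
at most `ε = 1e−4` mm³/day, with the total dose split evenly over
5 fractions/week × 6 weeks (weekend gaps preserved, fractions on days
0–4, 7–11, …, 35–39).  `t*` is counted from treatment start; the
derivative collapses algebraically to `kg (I V1 + U1) − kk V4`.

Three constructions:

* **analytic** — for the linear variant only,
  `D = dose_scale (1 − kk/kg) / (γ (1 + b C))`; it ignores the short-term
  effect entirely (and hence the potency `a`).
* **simulated median** — the smallest concentration meeting the stasis
  test at each grid dose, found by bisection (the derivative is monotone
  in both exposures); this accounts for both effects and therefore sits
  at or below the analytic curve.
* **population percentile** — Monte-Carlo: virtual subjects are drawn
  with independent lognormal between-subject variability on γ, α and
  `V0`; the empirical nearest-rank percentile of the per-subject
  requirement is taken per dose.  The radiation-alone requirement (the
  curve's C = 0 crossing) and per-compound doses at a fixed
  concentration are computed per subject by bisection on total dose,
  vectorized in lockstep across the population.

All searches run on the shared fast propagator; a 1000-subject percentile
computation takes seconds.  Searches use bisection tolerances of
1e−4 µg/mL (concentration) and 0.01 Gy (dose); brackets are expanded by
doubling, and an exposure axis that cannot reach stasis (an inert
compound, or dose zero) raises an explicit unbounded-requirement error —
curve construction drops such grid points instead.

**Limit behaviour.**  As `t* → ∞` with `ε` tightened correspondingly, the
simulated median curve converges to the analytic one.  With `ε` held
fixed the convergence is slow wherever the within-treatment kill is deep
(eradicated trajectories keep the absolute derivative under `ε` across a
range of doses); the convergence test therefore uses `ε = 1e−6` at
`t* = 600` days (drug-free and low-concentration cases) and `t* = 2000`
days at higher concentrations, with a 3% agreement band.

**Ranking.**  Compounds are ranked by the total dose their percentile
curves require at a common concentration (8 µg/mL by convention);
ascending dose = descending potency.  The reference 95th-percentile run
at `n = 1000` reproduces the compound ordering Rs1 < Rs2 < Rs3.  The
radiation-alone 95th-percentile dose computes to ≈ 190 Gy under these
settings (seed spread ≈ 180–195 at n = 1000).

## The population model and synthetic studies

Nonlinear mixed effects: study-specific medians for γ and `V0` (fixed
study covariates; three studies), global medians for `kg`, `kk`, `α` and
the per-compound potencies, independent lognormal between-subject
variability on γ, α, `V0` (printed magnitudes read as 100·ω), and a
combined residual error `y = f (1 + ε₁) + ε₂` with ε₁ ~ N(0, σ_prop²),
ε₂ ~ N(0, σ_add²), truncated at zero.  σ_prop is a fraction (0.35 = 35%
CV); the loader notes this at load time.

The bundled study designs mirror the three xenograft studies: Mon–Fri
2 Gy fractions for 6 / 1 / 6 weeks, twice-weekly caliper observations
(days 0, 3, 7, 10, …), group sizes 9–10, per-arm mean Cmax as the
constant exposure (study 2's highest-dose arm is followed to ~120 days;
vehicle arms are followed 24 days, which keeps their unchecked exponential
growth within a realistic sacrifice volume).  Seeding splits one master
seed into independent substreams per arm (parameters and residuals
separately), so identical seeds give bit-identical datasets and single
arms can be regenerated without the rest.

What the generator does **not** emulate: dropout and humane-endpoint
censoring, measurement-day jitter, within-subject PK variability,
body-weight covariates, and detection limits (volumes are truncated at
zero rather than censored at a caliper floor).  Passing recovery tests on
these data therefore show estimator self-consistency under the stated
population model, not robustness to those real-data features.

## Estimation

`fit_population` maximizes a first-order-conditional (FOCE)-type Laplace
approximation of the marginal likelihood: per subject, the joint density
is maximized over the random-effect vector η (Gauss–Newton steps with the
exact gradient including the error-model interaction terms, backtracking
line search, warm starts across outer iterations; modes clipped to
|η| ≤ 8), and the marginal contribution is assembled from the mode value,
the Gauss–Newton curvature log-determinant and the Ω normalization.
Residual variance is evaluated at the model prediction (extended least
squares), which keeps the estimator consistent under the generating
model.  The outer optimizer is L-BFGS-B on log-transformed parameters
with finite-difference gradients (step 1e−4) inside a ±5 log-unit box;
the inner modes converge to an η-step below 1e−7, which keeps the outer
objective effectively path-independent despite the warm starts.
Inadmissible probes (e.g. `kk ≥ kg`) and overflowing trajectories return
a large penalty.

For model comparison the final −2 ln L is re-evaluated by adaptive
Gauss–Hermite quadrature (5 nodes per dimension, centered at the Laplace
modes with the Gauss–Newton curvature): with between-subject variability
as large as here (ω ≈ 0.5–0.64) the Laplace error is O(1) per subject and
can exceed an AIC penalty unit; the quadrature value is what AIC uses.
Relative standard errors come from the inverse observed information
(finite-difference Hessian of the deviance on the log scale, delta
method), and EBE shrinkage is reported as `1 − SD(η̂)/ω`.

`fit_individual` is a plain maximum-likelihood fit of one subject's
(γ, α, V0); parameters whose perturbation cannot change the prediction
(radiation parameters of an unirradiated subject) are flagged
unidentifiable and left at their start value.

**Known limitations.**  Variant discrimination by AIC is weak at
realistic study sizes when between-subject variability is at the
reference magnitudes: per-subject random effects absorb most of the
shape difference between the linear and exponential inhibition functions,
and the generator's zero-truncation floor slightly favours the bounded
variants for eradicated tumors.  The model-recovery test therefore
demonstrates selection on data with the variability switched off, where
the comparison is exact; at full variability the three shapes are close
to statistically indistinguishable at these sample sizes.  Drug-potency
parameters (`a`, `b`) are estimated with low precision at group sizes of
9–10 — recovery errors of 10–30% are typical, consistent with their
weak identifiability — while the structural medians and the ω magnitudes
recover well (the acceptance suite asserts medians within 15% and ω
within 50% at the bundled three-study design).

## Sensitivity analysis

Local sensitivities of `V_tot(t*)` are central differences at ±5%
relative perturbation, reported as |p ∂V/∂p| normalized to the largest
value within each treatment group; study-indexed parameters are lumped
(γ₁..γ₃ report as γ), and the summary takes mean and SD across the groups
a parameter affects.  At the reference estimates the two dominant
parameters are `kg` and `kk`.

## Problem sizes used by the test-suite

The suites run at desk scale: percentile curves in unit tests use tens of
subjects on coarse dose grids; the headline 95th-percentile doses use the
full 1000-subject population (seconds on the fast path); the
parameter-recovery test fits the complete bundled three-study design
(134 subjects, ~20 free parameters, a few minutes); the VPC calibration
uses 120 replicates of a reduced two-study layout.
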