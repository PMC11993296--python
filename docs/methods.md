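# Methods

## The model

`pltrecon` implements a semi-mechanistic model of platelet reconstitution
after allogeneic hematopoietic cell transplantation (allo-HCT).  Observed
platelet counts are the sum of two circulating pools,

    PLT(t) = PLT_PAT(t) + PLT_GT(t),

produced by two parallel transit ("maturation-chain") submodels of the
Friberg type, one for the patient's own hematopoiesis and one for the graft.

**Patient submodel.**  Proliferating stem cells (HSC_PAT) feed three transit
compartments (TR1–TR3) and finally the circulating pool, all coupled with a
single transit rate K_PAT = (n+1)/MMT_PAT with n = 3 transit compartments and
MMT_PAT = 6.1 days.  Conditioning chemotherapy inhibits proliferation by the
fraction rho = 0.945 on the closed interval [t_start, t_stop] (day −6 to −2
by default):

    dHSC_PAT/dt = K_PAT (1 − DRUG(t)) HSC_PAT − K_PAT HSC_PAT.

All five patient compartments are initialized at the pre-HCT baseline
(90.5 × 10⁹/L), which is the steady state of the untreated chain.
Anti-thymocyte globulin (ATG) is handled kinetic-pharmacodynamically: each
dose (mg) enters a virtual amount that declines first-order
(dATG/dt = −K_INT·ATG) and multiplies platelet elimination linearly,
K_PAT·PLT_PAT·(1 + α·ATG(t)).

**Graft submodel.**  Transplanted cells (Graft1₀ = 72.4 × 10⁹/L-equivalents)
pass through two transit compartments with rate K_GR = 2/TTBM (TTBM = 1.5 d)
into the graft HSC pool, which proliferates under two regulators:

    dHSC_GT/dt = K_GT (Graft1₀ / PLT_GT)^γ (1 − HCT(t)) HSC_GT
                 − K_GT HSC_GT + K_GR Graft2,

with K_GT = (n+1)/MMT_GT (MMT_GT = 7.0 d), the feedback exponent γ = 0.19
(endogenous up-regulation, e.g. thrombopoietin, when counts are low), and a
transplant-associated effect compartment HCT that starts at 4.22 on day 0
and declines first-order with K_EL = 0.353/d (half-life 2.0 d).  Because
HCT(0) > 1, the proliferation term is initially *negative*: early graft
arrivals are destroyed rather than amplified, which is what postpones the
take-off of graft platelets and shapes the nadir.  The graft chain then
mirrors the patient chain into PLT_GT.

**Day-0 events.**  At transplant, three boluses enter the system: the graft
dose into Graft1, the HCT-effect magnitude into HCT (treated as the limit of
a short zero-order input), and a platelet boost of 20.1 × 10⁹/L into PLT_PAT
(donor platelets carried with the graft), multiplied by 2.75 for related
donors.  Each platelet transfusion adds 10.6 × 10⁹/L to PLT_PAT at its
recorded time.  The boost values are implemented as the amounts added at the
event time (parameter semantics), not as guaranteed next-day increments; at
K_PAT ≈ 0.66/d roughly half of a bolus remains after one day.

**Total protein.**  Serum total protein (TP) multiplies the graft
proliferation term by (TP(t)/5.43)^0.197, evaluated last-observation-
carried-forward between measurements; the multiplier is neutral before the
first measurement and after a forecast cutoff (an unobserved future
covariate has no effect).  The multiplier is applied to the production term
as a whole, so while HCT(t) > 1 a *higher* TP transiently deepens the dip
before raising the recovery; pointwise dominance of the higher-TP subject
holds from the nadir onwards.

## Population model

Parameters with a reported coefficient of variation carry log-normal
inter-individual variability: value = typical × exp(η), η ~ N(0, ω²),
ω² = ln(1 + CV²).  The eight such parameters (CV as a fraction): baseline
platelets (1.150), rho (1.523), day-+1 boost (2.897), transfusion boost
(0.679), graft dose (0.829), MMT post-HCT (0.909), γ (0.487), HCT-effect
magnitude (0.871).  Because rho is a fraction, log-normal draws above 1 are
clipped to 1 (full proliferation arrest); with a typical value of 0.945 this
affects a substantial minority of draws and is the simplest reading that
respects both the published CV and the physical bound.  Residual error on
observations is combined proportional + additive, sigma² = (0.20·f)² + 2²,
chosen as a conventional default (the source residual model is not
published) and fully configurable.

## Numerical choices

* Integration is segmented at every bolus time, conditioning boundary and
  TP change point, so dose events are exact discontinuities; within each
  segment the right-hand side is smooth and jit-compiled.  Default solver
  LSODA with rtol 1e-8 / atol 1e-10 for simulation; a Radau retry handles
  the rare stiff segment.  Estimation uses rtol 1e-6 / atol 1e-8.
* The feedback ratio clamps PLT_GT at a floor of 1e-3 × 10⁹/L.  Sensitivity:
  moving the floor across 1e-9…1e-1 shifts the typical nadir time by ~0.5 d
  and its value by ~3%; all qualitative behavior is unchanged.
* The proliferation term uses max(HSC_GT, 0) so the destructive early phase
  cannot drive the compartment negative; trajectory readouts clip tiny
  negative solver excursions to zero.
* Daily readouts take the value at t = d exactly (post-bolus at event
  times).
* Engraftment is the first of three consecutive days ≥ 20 × 10⁹/L.  Counts
  start above the threshold and *fall* through it early after transplant, so
  a literal scan from day 0 would fire immediately; population summaries
  therefore scan from the post-HCT daily nadir — engraftment means
  *recovery*.  For the typical patient this gives day +17.  How subjects
  whose counts never drop below 20 should enter a population average is
  genuinely underdetermined; we include them (their engraftment day is their
  nadir day), which yields a population mean of ~14 days under the default
  cohort mix, whereas conditioning on a sub-threshold dip (53% of subjects)
  gives ~20.5 days.

## MAP forecasting

Individual random effects are estimated as the posterior mode of

    −2 log post = Σᵢ [(yᵢ − fᵢ(η))²/σᵢ² + ln σᵢ²] + ηᵀ Ω⁻¹ η,

with σᵢ from the residual model at the prediction and diagonal Ω from the
published CVs.  The fit uses all pre-transplant observations plus, in the
default `weekly` mode, the measurements nearest the day +7/+14/+21/+28
anchors up to the cutoff (mode `all` uses every observation up to the
cutoff).  Transfusion records and TP measurements enter only up to the
cutoff; the TP effect is neutral afterwards.

Optimization is L-BFGS-B on η from η = 0, ftol 1e-6, bounds ±3ω, with a
finite-difference step of 1e-3 — deliberately far above the integrator's
noise floor, which would otherwise corrupt the gradients.  Two safeguards
keep the search out of numerically explosive regions: parameter combinations
whose worst-case feedback-amplified proliferation rate
K_GT·(Graft1₀/floor)^γ exceeds 2000/d are treated as posterior cliffs
(objective 1e12), and a failed solve returns the same cliff value.

Prediction intervals are Monte-Carlo: η is sampled from the Laplace
approximation at the MAP (covariance 2H⁻¹ of the −2 log posterior Hessian),
each sample is simulated and residual error added; bounds are percentiles.
Finite-difference Hessians are noise-dominated in directions the data leave
flat, which would absurdly inflate the interval, so H is whitened by the
prior and its eigenvalues floored at the prior precision — no direction of
the approximate posterior is ever wider than the prior in its own scale
(with a full fallback to the prior covariance if the decomposition fails).
Sampled η are additionally clipped at ±3.5ω, and samples falling in the
unphysiological feedback regime are dropped (with a warning).

The thrombocytopenia score of a forecast is the negated mean of the last 12
predicted counts at the subject's own observation times within day +29…+180
(larger = more at risk); the binary call compares the mean with 75 × 10⁹/L
(strict).  Subjects with no in-window measurement are undefined, never
negative.

## ATG kinetic-pharmacodynamic defaults

α (slope, per mg) and K_INT (decline, 1/d) are not published.  The defaults
α = 0.01/mg and K_INT = 1.386/d (half-life 0.5 d) were calibrated once so
that a typical 800 mg/day course on days −4..−2 (i) crashes platelets
immediately after the first dose and (ii) places the global nadir during the
ATG course (continuous minimum near day −2, vs. day +10.5 without ATG).
Because equal daily doses accumulate while the feeding transit compartment
declines, the deepest excursion structurally follows the *last* dose; a
nadir strictly at day −3 is not attainable with daily dosing to day −2.

## Synthetic cohort

The generator emulates the study's data structure, not any real patient:

* composition: 57.4% ATG-treated (800 mg/day, days −4..−2), 26.8% related
  donors; conditioning −6..−2 for everyone;
* sampling: every 3 days on [−30, −8], daily on [−7, +42], every 3 days to
  +100, weekly to +180, with non-anchor visits thinned at random to a median
  of 58 measurements; the weekly forecasting anchors and all pre-transplant
  visits are always kept;
* total protein: a subject-level set point N(5.43, 0.82²) g/dL with
  mean-reverting within-subject noise (stationary SD 0.5, reversion 0.1/d,
  measured weekly), calibrated so the pooled marginal has median ≈ 5.43 and
  10th percentile ≈ 4.2 g/dL;
* transfusions: on each day in +1..+30 where the simulated (pre-bolus) truth
  is below 12 × 10⁹/L a transfusion bolus is applied immediately and fed
  back into the integration;
* observations: the noise-free truth at the sampled times perturbed by the
  residual-error model, floored at zero.  The generating parameters and the
  noise-free outcome label are retained for recovery testing.

What the generator does *not* emulate: diagnosis mix, GvHD, relapse and
mortality (informative dropout), transfusion refractoriness, measurement
batch effects, or any correlation between random effects — the published
priors are diagonal.  Tests passing on this cohort therefore demonstrate
internal consistency of the method under the stated priors, not clinical
performance on real data.

## Problem sizes used in the test suite

The acceptance checks run at desk scale: 1000 subjects for the engraftment
average, 50 subjects (mode `all`) for the parameter-recovery regression, one
seeded 30-subject cohort forecast at all four cutoffs for the AUROC
ordering, and 1e4–1e5 draws for Monte-Carlo distribution checks.

## Known limitations

* The published typical values are taken as fixed priors; no population
  re-estimation is attempted, so cross-validation examines fold-to-fold
  metric stability only.
* MAP estimation is a local search from η = 0; strongly multimodal subjects
  can settle in a secondary mode.
* Parameters that mainly shape the trajectory *after* day +28 (graft dose,
  post-HCT maturation time) are only partially identified by day-28 data;
  their MAP estimates are strongly shrunk toward the prior (regression
  slopes of recovered on true log-parameters ≈ 0.4–0.7), which is a
  property of the information content, not of the optimizer.
* The K-PD ATG submodel uses calibrated, not estimated, α and K_INT.
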