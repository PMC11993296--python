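# pltrecon

Semi-mechanistic modelling of **platelet reconstitution after allogeneic
hematopoietic cell transplantation (allo-HCT)**: population simulation,
MAP (empirical-Bayes) forecasting of individual 180-day platelet profiles
from early post-transplant data, and evaluation of thrombocytopenia
prediction.  Written for pharmacometricians and transplant researchers who
want a tested, scriptable implementation of this model class without access
to protected clinical data — a fully synthetic cohort generator reproduces
the statistical structure of a transplant registry.

## The model

Platelet counts are the sum of a patient-derived and a graft-derived pool,

```
PLT(t) = PLT_PAT(t) + PLT_GT(t),
```

each produced by a Friberg-type transit chain (proliferating HSCs → three
maturation compartments → circulation, transit rate K = (n+1)/MMT).
Conditioning inhibits the patient chain's proliferation by ρ = 0.945 during
day −6..−2; ATG doses drive a kinetic-pharmacodynamic compartment that
multiplies platelet elimination by (1 + α·ATG(t)).  The graft enters at
day 0 and proliferates under a feedback term (Graft1₀/PLT_GT)^γ and a
transplant-effect compartment, `(1 − HCT(t))`, with HCT(0) = 4.22 declining
at K_EL = 0.353/d (half-life 2.0 d).  Retained covariates: ATG, donor
relation (related donors get a 2.75× larger day-+1 platelet boost), and
serum total protein, (TP/5.43)^0.197 on graft proliferation.  Parameters
carry log-normal inter-individual variability at the published %CVs
(ω² = ln(1+CV²)).  See `docs/methods.md` for the full equations,
assumptions and numerical choices.

Individual forecasting minimizes the standard MAP objective

```
-2 log post = Σᵢ [(yᵢ − fᵢ(η))²/σᵢ² + ln σᵢ²] + ηᵀ Ω⁻¹ η
```

over the random effects η, using all pre-transplant counts plus the weekly
post-HCT counts up to a cutoff (+7/+14/+21/+28).  The forecast's
thrombocytopenia call compares the predicted mean of the last 12 counts in
day +29..+180 with 75 × 10⁹/L.

## Worked example

```sh
python examples/01_simulate_typical_patient.py
```

```
pre-conditioning baseline :   90.5 x10^9/L
post-HCT nadir            :   12.8 x10^9/L at day +10.50
platelet engraftment day  : +17
day-180 plateau           :   80.0 x10^9/L
```

The baseline is the steady state of the patient's own marrow; conditioning
depletes it with a delay set by the 6.1-day maturation time, the graft takes
off once the transplant effect has decayed (half-life 2 d), and the typical
patient recovers 20 × 10⁹/L sustainably on day +17 before settling at a
graft-dominated plateau.  Forecasting a synthetic subject:

```sh
python examples/03_forecast_individual.py
```

```
subject: ATG=False, donor=unrelated, 0 transfusion(s)
fit used 20 observations (converged=True)
predicted mean of last 12 in-window counts: 63.7 x10^9/L
thrombocytopenia call (< 75): True (true label: True)

  day   predicted    95% PI
   35      62.9   [ 34.6,  101.4]
   60      63.6   [ 38.1,   97.1]
   90      63.7   [ 34.9,   89.8]
  120      63.7   [ 37.9,   89.1]
  180      63.7   [ 38.2,   92.9]
```

Other examples cover covariate effects (`02`), cohort-level AUROC
evaluation (`04`) and synthetic-cohort generation with CSV round-trip
(`05`).  The same functionality is scriptable from a shell:

```sh
pltrecon generate --n 50 --seed 1 --out cohort/
pltrecon forecast --dataset cohort/dataset.csv --cutoff 28 --out forecasts
pltrecon evaluate --dataset cohort/dataset.csv --out summary.json
```

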