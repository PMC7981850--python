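# Methods

## The dilution model

A bleed of hemoglobin mass *L* (g) out of a circulating volume *BV*
(litres) lowers the blood Hb concentration, once plasma volume has
re-equilibrated, by roughly ΔHb ≈ *L*/*BV*. Every estimator in this
package is a variant of inverting that relation. The sex-specific
estimators at the core,

```
L_female = 42.212 + (0.160·h³ + 0.015·w + 0.083) · ΔHb
L_male   = 61.767 + (0.165·h³ + 0.015·w + 0.272) · ΔHb
```

(*h* height in m, *w* weight in kg, ΔHb = HB_pre − HB_post in g/L, *L* in
g), are an ordinary-least-squares fit of directly measured
controlled-bleed losses on the dilution signal. Each slope term is ≈ 0.45
times the corresponding coefficient of Nadler's blood-volume equation
(male BV = 0.3669·h³ + 0.03219·w + 0.6041 L; female BV = 0.3561·h³ +
0.03308·w + 0.1833 L), so the fitted structure is interpretable as
*L* ≈ intercept + 0.45·BV·ΔHb. The 0.45 proportionality absorbs the fact
that a single blood draw ~24 h after the bleed catches re-equilibration
incomplete; the sex-specific intercept absorbs loss components invisible
to dilution. The package freezes the Nadler constants in one table and
guards the transcription with a static test that every coefficient ratio
lies in [0.449, 0.466].

Assumptions and validity limits: normovolemia, no pre-existing anemia, a
loss large enough to move Hb measurably, and a post-bleed sample taken
about a day after the procedure. Negative estimates are deliberately
returned unclamped (with a machine-readable flag): clamping would bias
residual analyses, and an honest prediction interval for a small dilution
includes zero.

### Legacy calculators

The registered comparison formulas use the Nadler estimated blood volume
EBV (mL) and hematocrit fractions. Their printed sources predate this
package; the forms implemented are the canonical ones from the
surgical-blood-loss literature:

| id | native quantity | form |
|---|---|---|
| meunier | blood mL | EBV · ΔHb / HB_pre |
| gross | blood mL | EBV · ΔHct / Hct_mean |
| ward | blood mL | EBV · ln(Hct_pre/Hct_post) |
| bourke | blood mL | EBV · ΔHct · (3 − Hct_mean) |
| mercuriali, lisander | RBC mL | EBV · ΔHct + transfused RBC mL |

Mercuriali and Lisander coincide exactly whenever no blood was transfused;
the suite asserts this as a property. Benchmarks convert every native
output to grams of Hb (RBC mL ÷ 2.87, blood mL ÷ 6.79) before computing
the Hb-equivalent MAE, so formulas predicting different quantities are
judged on one scale. Hematocrit is represented as a fraction internally;
percent-looking inputs (> 1) are divided by 100 with a warning, since the
literature mixes conventions.

## Prediction intervals

For a new donor with design row *x* = (1, h³ΔHb, wΔHb, ΔHb), a fitted
model with coefficients β̂, coefficient covariance *V* and residual
variance *s²* gives

```
L̂ ± t_{(1+γ)/2, df} · sqrt(s² + xᵀVx),     γ = 0.90 by default.
```

Because the derivation data showed heteroscedastic residuals, *V* defaults
to the HC3 heteroscedasticity-consistent estimator (HC0–HC3 selectable).
The shipped default fitted model keeps the published coefficients exactly
and calibrates *s²* and *V* on the default synthetic cohort (n = 2000 per
sex, fixed seed); every output that uses it is labelled
`synthetic-calibrated`, because the original cohort is not public and no
real-data residual scale exists. An empirical check in the suite shows the
90% intervals cover ≈ 90% of fresh synthetic donors.

## Synthetic cohorts

The generator emulates a bone-marrow-donor ("controlled bleed") cohort in
which the harvested product's Hb mass is weighed — ground-truth loss. Study
conditions built into the defaults: two-thirds male; height Normal per sex
(male 182 ± 7 cm, female 170 ± 6.5 cm; mixture mean 178 cm); weight =
BMI·h² with log-normal BMI (median 24.7 kg/m², IQR ≈ 22.3–27.4, giving
mean weight ≈ 79 kg); age 18 + Gamma(1.6, 7.5) years capped at 60
(right-skewed, median ≈ 28); pre-procedure Hb Normal per sex (male 152,
female 135, sd 10 g/L — reference-interval fixture values, declared in the
generator report's provenance, as are the platelet and log-normal
leukocyte models).

The bleed itself is generated by reading the dilution model generatively:

1. the realized dilution δ (g/L) is drawn from 2 + 56·Beta(3.21, 4.62)
   (mean 24.95, sd 9.27), independent of hb_pre, and hb_post = hb_pre − δ;
2. the true loss is L = intercept_sex + slope_sex(h, w)·δ, the formula's
   own structure, which ties loss to donor size — physically sensible,
   since harvest volumes are capped by body weight;
3. the *observed* loss adds Gaussian measurement noise on the harvested
   mass, sd 25 g by default.

Two calibration facts motivated this design. First, the strong (≈ 0.81)
pre/post-Hb correlation fixes the dilution variance at roughly half the
hb_pre variance; drawing the loss independently of donor size cannot reach
that correlation with a realistic Hb spread, while the size-linked
mechanism hits it exactly. Second, placing the residual noise on the
observed harvest mass (rather than on hb_post) makes refitting the
published structure a classical errors-on-the-response regression, so
coefficient recovery is unbiased — noise on hb_post would instead create an
errors-in-variables attenuation that biases every refit. The 25 g default
reproduces an explained variance of ≈ 0.55 for the dilution signal,
matching the modest precision such formulas show on real cohorts. With
`loss_noise_sd = 0` the formula reproduces every observed loss exactly,
which the suite asserts to 1e-9 g.

Hematocrits derive from Hb via hct = Hb/330 (1/MCHC) plus Gaussian noise
(sd 0.011), yielding Hb↔Hct correlations of ≈ 0.95–0.97; platelets and
leukocytes are uninformative covariates by construction. Missingness
emulates lost post-procedure CBCs: by default each record is blanked with
probability 77/478, and a deterministic exactly-*k* variant (without
replacement) supports headline complete-case counts (478 → 401). The
calibration constants were fixed once against the target summaries and
frozen; the suite asserts at n = 5000 that mean loss (113 ± 3 g), mean
height (178 ± 2 cm), mean weight (79 ± 2 kg) and the pre/post-Hb
correlation (0.81 ± 0.05) are realized.

What the generator does **not** model: fluid-replacement kinetics and the
time course of re-equilibration, anemia, pregnancy, transfusion during the
procedure, measurement drift between analyzers, and any skew or outliers
in the loss-measurement error (it is Gaussian). Passing tests therefore
demonstrate internal consistency and correct statistical machinery on a
faithful mechanism, not clinical performance on real patients.

## Refitting pipeline and diagnostics

The derivation design log-transforms weight, age, BMI and leukocyte count
(their raw distributions are right-skewed), replaces the collinear
hb_post/hct_post with the differences hb_diff/hct_diff, and adds the
interaction Nadler-BV × hb_diff. Standard scaling (subtract mean, divide
by sd) is applied only for learners that need it; interpretable linear
fits run unstandardized. Variable selection is backward elimination: drop
the single least-significant variable with p ≥ α (default 0.05), refit,
repeat; ties break by column order and the intercept is never dropped. The
pruning trace is recorded in the results object.

The diagnostics battery computes: the condition number of the
correlation-scaled design (multicollinearity); added-variable
(partial-regression) slopes, which equal the OLS coefficients when each
relationship is linear; Breusch–Pagan (heteroscedasticity); Jarque–Bera
and Q-Q quantile pairs (residual normality); leverage vs normalized
squared residuals (outliers); an HC3 refit of the significance table; and
an MM-type robust regression. The robust fit uses a high-breakdown start —
exact solves on 200 random elemental subsets, keeping the candidate with
the smallest MAD residual scale — refined by iteratively reweighted least
squares with the Tukey bisquare ψ; on clean data its coefficients must lie
within one classical standard error of OLS, which is asserted. With n < 30
the asymptotic tests are reported as not applicable rather than silently
computed. Simulation tests verify the battery's operating characteristics:
both tests' type-I error is 5% ± 2% over 1000 homoscedastic-Gaussian
replicates at n = 401, and Breusch–Pagan detects covariate-scaled noise at
n = 2000.

### Model selection

Seven learners are compared: linear regression, ridge (α grid around 5),
AdaBoost (100 trees), random forest (40 trees, depth 4), RBF support
vector regression (C = 9, ε = 0.9), k-nearest neighbours (k = 20) and a
(64, 32, 16) ReLU network — the reference hyperparameters sit inside every
grid. A single seed drives the 25% holdout split, the five-fold CV fold
assignment and stochastic learners; test MSE and explained variance
(population-variance convention, EV = 1 − Var(y−ŷ)/Var(y); the divisor
cancels) are reported per learner. On linear-truth synthetic data, linear
and ridge agree within 10% test MSE, as asserted.

## Numerical and interface choices

* Heights are metres in the API, centimetres in files and CLI flags
  (clinical charts use cm; the formula uses m). A height > 3 in the API is
  rejected with a cm-remediation hint.
* Hb is g/L canonically; the CLI accepts g/dL behind an explicit flag
  (×10).
* Cohort CSVs parse numerics with exact `float()` so write→read→write
  round-trips byte-identically; malformed cells are collected into a
  per-row issue list, never silent NaNs. Listwise deletion is the only
  missing-data policy.
* The problem sizes used by the test suite and acceptance script (n = 401
  to 5000 cohorts, 40 replicate refits, 1000 diagnostic replicates) keep
  every Monte-Carlo standard error a factor of a few below the asserted
  tolerances while running the whole suite in seconds.
* Coverage-style claims (CI coverage of refitted intercepts, PI coverage)
  are asserted over replicate seeded cohorts rather than a single seed,
  since any single 95% interval misses 5% of the time by construction.

## Known limitations

The prediction intervals shipped by default are synthetic-calibrated and
should not be quoted for clinical use. The legacy-formula transcriptions
follow the canonical literature forms; minor variants circulate. The
generator's loss range (~46–235 g) is slightly narrower at the low end
than the 29–233 g of real harvests, a consequence of the size-linked loss
mechanism; means, IQRs and correlations are calibrated, higher moments are
not.
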