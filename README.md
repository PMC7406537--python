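# mixls

Two-stage mixed-effects location-scale modelling for intensive longitudinal
data (EMA / daily-diary studies).

Classic mixed models let subjects differ in their *means*.  Intensive
longitudinal designs — dozens of momentary reports per subject — also make
subject differences in *variability* estimable, and that variability is often
the scientific quantity of interest (mood lability, erraticism of behaviour).
`mixls` models both:

- **Stage 1** fits a mixed-effects location-scale (MELS) model by maximum
  likelihood: a random location effect (or several) shifts each subject's
  mean, a random **scale** effect shifts each subject's log within-subject
  variance, and both the between-subject and within-subject variances carry
  log-linear covariate models.  The within-subject variance can additionally
  depend on the subject's own location effect (linearly or quadratically), or
  location and scale effects can covary freely.
- **Stage 2** treats the subjects' location and scale effects as regressors
  for a subject-level outcome.  Because those effects are latent, it draws
  *plausible values* from each subject's empirical-Bayes posterior, refits the
  subject-level regression (linear, logistic, or ordinal) once per draw, and
  pools the results with Rubin's multiple-imputation rules so that stage-1
  uncertainty propagates into the stage-2 standard errors.

## Quick start

```python
from mixls import MELS, Stage2Spec, draw_plausible_values, fit_stage2, \
    read_longitudinal_csv

data, report = read_longitudinal_csv("diary.csv", id_column="id")

model = MELS(data, "y", mean=["dow", "sex"], bs_var=["sex"],
             ws_var=["sex"], ncov=1)
result = model.fit()
print(result.summary())
```

```text
Log Likelihood = -7799.560
Akaike's Information Criterion = -7808.560
Schwarz's Bayesian Criterion = -7823.402
Variable                  Estimate     AsymStdError z-value      p-value
------------------------- ------------ ------------ ------------ ------------
BETA (regression coefficients)
Intercept                 39.34476     1.02729      38.29945     0.00000
dow                       0.34748      0.08584      4.04823      0.00005
sex                       1.00773      1.30484      0.77230      0.43994
ALPHA (BS variance parameters: log-linear model)
Intercept                 4.31372      0.17401      24.78983     0.00000
sex                       -0.08834     0.22597      -0.39096     0.69583
TAU (WS variance parameters: log-linear model)
Intercept                 4.75454      0.14432      32.94494     0.00000
sex                       -0.20708     0.19475      -1.06328     0.28766
Random scale standard deviation
Std Dev                   0.39872      0.07782      5.12377      0.00000
Random location (mean) effect on WS variance
Loc Eff                   -0.14462     0.00813      -17.79445    0.00000
```

Stage 2 — does a subject's mean level or volatility predict a subject-level
outcome?

```python
subject = data.subject_table(["mood_lability", "sex"])
draws = draw_plausible_values(result.empirical_bayes(),
                              n_imputations=500, seed=11)
s2 = fit_stage2(subject, draws,
                Stage2Spec(outcome="mood_lability",
                           outcome_type="continuous", regressors=["sex"]))
print(s2.summary())
```

```text
Average Log Likelihood = -334.161 (sd= 3.199)
Akaike's Information Criterion = -339.161
Schwarz's Bayesian Criterion = -347.407
Variable                  Estimate     AsymStdError z-value      p-value
------------------------- ------------ ------------ ------------ ------------
Intercept                 1.15258      0.13614      8.46595      0.00000
sex                       0.34449      0.18731      1.83909      0.06590
Locat_1                   0.66710      0.09837      6.78190      0.00000
Scale                     0.14177      0.12950      1.09473      0.27363
Locat_1*Scale             0.08035      0.13338      0.60241      0.54690
Residual_Variance         1.65573      0.17388      9.52249      0.00000
```

`Locat_1` and `Scale` are the standardized random location and scale effects;
interactions with observed regressors or between the two effects are
controlled through `Stage2Spec(interactions=..., include_scale=...,
suppress_effect_interactions=...)`.

For several random location effects (e.g. random slopes) use `MEMLS`:

```python
from mixls import MEMLS
model = MEMLS(data, "y", mean=["weekend"], random_slopes=["weekend"], ncov=1)
```

## Command line

The whole two-stage workflow runs from one command and writes plain-text
results plus a re-runnable definition file:

```sh
mixls --data diary.csv --id id --outcome y \
      --mean dow sex --bs-var sex --ws-var sex --ncov 1 \
      --stage2-outcome mood_lability --regressors sex \
      --interact-location sex --seed 11 --out-prefix results/runA
mixls --def-file results/runA.def       # byte-identical re-run
```

Outputs: `<prefix>_stage1.txt`, `<prefix>_ebvar.csv` (empirical-Bayes means
and posterior (co)variances per subject), `<prefix>_stage2.txt`,
`<prefix>.def`, and optionally `<prefix>_draws.csv`.

## Documentation

`docs/methods.md` describes the statistical model, the estimation algorithm
(adaptive Gauss–Hermite quadrature, Newton–Raphson with Levenberg–Marquardt
damping), the plausible-value machinery, and the package's numerical design
choices and limitations.
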