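# centilecharts

Statistical construction of gestational-age-related reference and standard
centile charts, for the people who build them: biostatisticians and
perinatal epidemiologists turning fetal or newborn anthropometry (birth
weight, head circumference, femur length, ...) into smooth
centile curves and Z-scores. The package covers both of the standard study
designs — cross-sectional (one measurement per subject) and longitudinal
(repeated, possibly triplicate, measurements per subject) — together with
the model-selection and diagnostic machinery used to choose between
candidate models.

## Methods

**Fractional-polynomial mean–SD.** Assuming the measurement is normal at
each gestational age *t* with smoothly varying mean and SD, any centile is

> C₁₀₀α(t) = μ(t) + Z_α · σ(t)

with Z_α the normal equivalent deviate (Z = 1.88 for the 97th centile,
−1.88 for the 3rd). μ(t) is fitted by least squares over all fractional
polynomials (FPs) of a chosen degree — powers from
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}, power 0 meaning ln t, repeated powers
adding ln-multiplied terms — and σ(t) by regressing the absolute
residuals on age and scaling the fitted curve by √(π/2), the half-normal
correction.

**LMS and its extensions.** The LMS method summarizes the age-conditional
distribution by three smooth curves — Box-Cox power L(t), median M(t),
coefficient of variation S(t) — with centiles

> C₁₀₀α(t) = M(t)·(1 + L(t)·S(t)·Z_α)^(1/L(t))   (L ≠ 0),  
> C₁₀₀α(t) = M(t)·exp(S(t)·Z_α)          (L = 0)

and the SDS given by the exact inverse. This is the BCCG distribution in
the GAMLSS framework; the LMST (Box-Cox *t*) and LMSP (Box-Cox power
exponential) extensions add a kurtosis parameter τ(t), and the SEP3 / ST3
two-piece families model skewness and kurtosis directly. Each parameter
curve is an FP, a penalized cubic B-spline at a target effective degrees
of freedom (edf: 1 = constant, 2 = line, 3 ≈ quadratic), or a constant,
fitted by maximizing the penalized likelihood. Models are compared by
GAIC(k) = deviance + k·edf (AIC: k = 2; BIC: k = ln n), by worm plots
(detrended Q-Q plots by age group), and by the percentage of observations
beyond the fitted 3rd/97th centiles (expected: 3%).

**Multilevel models for longitudinal data.** For designs with repeated
visits and triplicate measurements, the package fits (by full ML) a
two-level random-intercept model, a two-level random-intercept-and-slope
model (on triplicates collapsed by mean, median, or random selection),
and a three-level model that keeps all replicates and separates
visit-level from replicate-level variation. Marginal centiles come from
the FP fixed curve plus an FP-smoothed total-SD curve derived from the
variance components. The published fetal head circumference (FHC)
standard equations (FP2 mean, FP3 SD, in mm and exact GA weeks) are built
in for chart evaluation without refitting.

Synthetic generators reproduce both study designs — term-heaped newborn
GA distributions, and a 14-to-42-week visit schedule every 5 ± 1 weeks
with triplicates and realistic visit-count and missingness patterns — and
return the generating truth so that fit-and-recover tests close the loop.

## Worked example

```python
import centilecharts as cc

records, truth = cc.gen_newborn(cc.CrossSecConfig(n=5000, seed=42))
ga, y = records["ga_weeks"].to_numpy(), records["value"].to_numpy()

model = cc.fit_mean_sd(ga, y, mean_degree=2, sd_degree=1)
print(model.mean_curve_.powers)          # (-2.0, 3.0)
print(float(model.centile(40.0, 3.0)))   # 2713 g
print(float(model.centile(40.0, 50.0)))  # 3410 g
print(float(model.centile(40.0, 97.0)))  # 4107 g
print(model.zscore(40.0, 2600.0))        # -2.19
```

The fitted 3rd and 97th centiles at 40 weeks sit symmetrically ±1.88
fitted SDs around the median, and a 2600 g newborn at 40 weeks scores
−2.19 SD — below the 3rd centile, the usual screening flag for
small-for-gestational-age. Coverage on the training sample
(`centilecharts.diagnostics.coverage`) shows 2.54% below the fitted 3rd
and 3.30% above the fitted 97th centile, consistent with the nominal 3%.
The built-in FHC standard evaluates to a median of 333.9 mm (3rd: 309.6,
97th: 358.3) at 40 weeks:

```python
cc.published_fhc(40.0, 50.0)   # 333.9 mm
```

A command-line workflow mirrors the library
(`centilecharts simulate | fit-crosssec | fit-long | centiles | zscore |
diagnose`); see `centilecharts --help`.

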