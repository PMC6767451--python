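# Methods

This note records the models implemented, the numerical choices behind
them, what the synthetic generators do and do not emulate, and the design
decisions taken where more than one reasonable implementation existed.

## Fractional polynomials

An FP of degree m in a positive covariate x has linear predictor
β₀ + Σⱼ βⱼ·x^pⱼ with powers from the restricted set
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}; power 0 denotes ln x, and a power
repeated r times contributes x^p·(ln x)^0..(r−1). Canonical power tuples
are non-decreasing; enumerating them with repetition gives 8 FP1, 36 FP2
and 120 FP3 models (C(8+m−1, m)). Some descriptions of the FP2 family
quote 32 models; direct enumeration of non-decreasing pairs with
repetition over an 8-element set gives 36, and the package implements 36
rather than silently matching the smaller count.

Best-power search is exhaustive (weighted) least squares over the
enumeration, keeping the tuple with the smallest residual sum of squares.
Ties are broken by the lexicographically smallest tuple so that refits
are reproducible; numerically rank-deficient candidate bases are skipped
with a warning rather than aborting the search. Gestational age is used
in natural weeks with no rescaling (`scale_shift` defaults to 0), because
published chart equations in this field are written in raw GA weeks.

## The mean–SD method

The mean curve is an FP fit of the measurement on GA; the SD curve is an
FP fit of the absolute residuals on GA multiplied by √(π/2), since under
conditional normality the absolute residuals are half-normal with mean
σ·√(2/π). `sd_degree` defaults to 1 (a single power is usually enough;
the published FHC SD needs degree 3, which is supported). Optional
reweighting performs exactly one weighted refit of the mean with weights
1/σ̂², then re-estimates the SD — the effect is known to be small, so no
iteration to convergence is attempted. A fitted SD that is non-positive
anywhere on the observed GA range is a fitting error naming the region,
except in the degenerate noiseless case (all |σ̂| below ~10⁻⁸ of the
response scale), where σ̂ ≈ 0 and the centiles legitimately collapse onto
the mean. Evaluation outside the fitted GA range is permitted but
flagged, since chart tables are usually published on round-week grids
that can extend slightly past the data.

Optionally the response is analysed as log(y) or as the shifted log
log(y + k); centiles are back-transformed.

## Distribution families

Seven families are available, in the GAMLSS parameterizations: NO(μ, σ);
PE(μ, σ, τ) — the power exponential, scaled so Var = σ², with τ = 2
normal; BCCG(μ, σ, ν) — the LMS model, with μ the median, σ the CV, and
ν the Box-Cox power; BCT and BCPE — the same transform with a truncated
t(τ) or standard PE(τ) for the transformed variable; and the two-piece
SEP3 and ST3 with Fernandez–Steel skewing (scale ν below the mode, 1/ν
above). The Box-Cox families use the truncated-and-renormalized
convention on y > 0 (normalizer Φ(1/(σ|ν|)) and its t/PE analogues), as
in standard LMS practice. The Box-Cox branch switches to the log form
below |ν| < 10⁻⁸, and both branches agree to ~10⁻⁶ relative at the
switch. All quantile functions are analytic inverses (normal/t quantiles
and inverse incomplete gamma), so quantile∘cdf round-trips hold to
~10⁻¹⁶ and random generation is inverse-CDF from a seeded generator.

Parameter counts and constraints: σ > 0 always; μ > 0 for Box-Cox
families; τ > 0 where present; ν > 0 for SEP3/ST3 (it is a scale ratio
there) but unrestricted for the Box-Cox families (it is a power).

## Penalized-likelihood centile fitting

Each distribution parameter is a smooth function of GA: a fractional
polynomial, a constant, or a penalized cubic B-spline. Splines use
uniform knots extended three beyond each boundary (Eilers–Marx
construction) with a second-order difference penalty, so straight lines
lie exactly in the penalty null space — with clamped boundary knots a
linear trend is spuriously penalized near the edges, which shows up as
systematic centile flaring at the extremes of the age range. The
smoothing constant λ is solved by bisection (on a bracket scaled by
tr(B'WB)/tr(P) to keep the linear algebra well-conditioned) so that the
realized edf, tr[(B'WB + λP)⁻¹B'WB], hits the requested target; targets
may be fractional (e.g. 3.6). edf = 1 is a constant, 2 a straight line,
3 approximately a quadratic. Automatic λ selection (GCV/ML) is out of
scope; smoothness is specified by target edf, matching how such models
are usually reported.

Links: σ and τ on log, μ on identity, ν on identity for the Box-Cox
families. For SEP3/ST3, ν is a positive scale ratio and is fitted on the
log link — the one place the identity-ν convention is overridden, for the
same positivity-without-constraints reason σ and τ use log.

Fitting cycles over the parameters; each visit performs up to four
damped Newton steps on that parameter's coefficients with the others
held fixed. The per-observation score and curvature with respect to the
linear predictor are obtained by central differencing of the log-density
(h = 10⁻⁴·max(1, |η|)); curvatures are clipped to [10⁻⁶, 10⁸] to keep
the step positive definite. Steps are halved (up to 12 times) until the
penalized objective does not increase, and a step is never taken from a
valid parameter state into one where the density is undefined. The cycle
stops when the global deviance (−2 log L) changes by less than 10⁻⁴
(configurable; cap 500 cycles), and non-convergence raises an error
carrying the deviance trace. This cyclic scheme is a design decision
validated by parameter recovery on simulated data, not a re-implementation
of any particular published backfitting algorithm.

Model comparison uses GAIC(k) = deviance + k·Σedf; the fit report's AIC
and BIC fields are exactly GAIC(2) and GAIC(ln n). Stepwise class
selection finds the best model per parameter-count class by GAIC and
promotes to a more complex class only on strict improvement (margin
configurable, default 0), returning the full ranked table so
non-statistical criteria — fit at the age extremes, common family across
sexes — can override the automatic choice.

## Multilevel models

Three model kinds for replicate longitudinal data: `ri2` (two-level
random intercept on collapsed triplicates), `ris2` (adds a random slope
on raw GA), `ris3` (all replicates, adding a visit-level random
intercept). The fixed part is an FP of GA (default powers (2, 2)).
Estimation is full ML via statsmodels MixedLM so deviances are
comparable across fixed-effects structures; several optimizers are tried
and a result is accepted only with a finite log-likelihood, because
quasi-Newton methods can report spurious convergence when a variance
component sits on the zero boundary (boundary components are flagged in
the fit). The random slope multiplies raw GA by default; GA-centering is
offered as an option and only reparameterizes the intercept–slope
covariance. Triplicates are collapsed by mean by default, with median
(more robust to a single aberrant replicate) and seeded random selection
as alternatives.

Marginal centiles use mean(t) = fixed FP and total variance
var₀ + 2·cov·t + var₁·t² + var_visit + var_resid (terms per model kind);
the total SD is evaluated on a grid and represented as an FP (default
degree 3, exact if the SD is itself an FP3). The derivation path of a
published closed-form SD equation (empirical residual SDs vs.
model-implied total SD) is generally not reported; this package
implements the model-implied route.

The published FHC standard — mean −28.2849 + 1.69267·GA² −
0.397485·GA²·ln GA; SD 1.98735 + 0.0136772·GA³ − 0.00726264·GA³·ln GA +
0.000976253·GA³·(ln GA)², mm, natural logs, exact GA weeks — is built in
and valid on 14–42 weeks (evaluation outside logs a warning).

## Synthetic designs

The cross-sectional generator draws a completed week from a weight table
(defaults proportional to the per-week newborn counts of the emulated
study: <2% below 34 weeks, mode at 39–40) plus a uniform within-week
fraction — only completed-week counts are ever reported for such designs,
so uniform-within-week is the natural choice — and samples the
measurement from any supported family with parameter curves supplied as
callables of GA. The default truth is BCCG with median 200·GA − 4600 g,
CV 0.11, power 0.5: term median ~3.4 kg with mild right skew, a
realistic birthweight shape.

The longitudinal generator schedules visits every 5 ± 1 weeks (uniform
jitter) from week 14, truncated at 42 weeks; the number of visits is
drawn from the emulated study's visit-count table (93.0% of subjects
with ≥4 visits; the table reproduces its 20 030 total visits in
expectation over 4233 subjects). Each subject gets an intercept and
slope deviation from a bivariate normal; each visit adds N(0, var_visit)
noise and each of three replicates adds N(0, triplicate_sd²) measurement
error, masked completely at random at rate 117/60 090. Default variance
components (var₀ = 74.31, cov = −2.81, var₁ = 0.1872, var_visit = 4,
triplicate_sd = 3 mm) were obtained by least-squares fitting the
quadratic total variance of the intercept+slope model to the square of
the built-in FHC SD curve over 14–42 weeks, so the published equations
double as the generator's truth; the quadratic can track the FP3 SD to
within 1.15 mm (worst at the 14-week edge). The triplicate SD is a
realistic ultrasound replicate error, chosen once — replicate variances
are not printed in the source material.

What the generators do **not** emulate: site/country as a modelled level,
GA-measurement error, informative missingness or informative visit
timing, and secular or between-site heterogeneity. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated sampling models, not robustness to those real-data features.

## Diagnostics

Worm plots use equal-count GA bins (default 9; groups under 10 points
merge with a neighbour) and Blom plotting positions (i − 3/8)/(n + 1/4);
deviations are ordered Z-scores minus theoretical normal quantiles, with
a plain least-squares cubic per group (a penalized-spline trend is
sometimes used instead; the cubic is labelled as such). Coverage tables
report the percentage strictly below (above) each fitted centile with
exact binomial 95% intervals. Comparison tables apply presentation
offsets (e.g. "deviance − 11 000") only at display time. Diagnostics
return data structures; matplotlib rendering is a thin optional layer.

## Problem sizes and tolerances

Recovery and calibration checks run at n = 3 000–10 000 cross-sectional
records and 150–1 000 longitudinal subjects — sizes at which Monte-Carlo
error is small relative to the tolerances asserted (e.g. coverage within
±0.5 percentage points of 3% at n = 10 000; variance components within
10% relative at 1 000 subjects; SDS sample SD within ±0.03 of 1). The
acceptance script uses n = 10 000 for both of its pipelines.

## Known limitations

- No automatic smoothing-parameter selection; edf must be specified.
- No closed-test FP power-selection procedure and no covariates other
  than GA.
- Box-Cox tail quantiles near the support boundary (strongly negative ν
  with large σ) grow without bound; requesting a centile outside the
  support raises rather than saturating.
- The three-level model assumes homoscedastic replicate error; replicate
  variance that grows with GA is not modelled.
- Nonparametric quantile regression is deliberately out of scope.
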