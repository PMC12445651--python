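# Methods

This note documents the statistical machinery, the synthetic-data model and
the design decisions behind `iganpt`.

## The prediction tool being validated

The IIgAN-PT is a Cox proportional-hazards calculator of the risk of a
composite kidney outcome — the first of a 50 % decline in eGFR or end-stage
kidney disease (eGFR < 15 mL/min/1.73 m², dialysis or transplantation) —
within 80 months of kidney biopsy. Its inputs are eGFR, mean arterial
pressure, 24-h proteinuria, age, the Oxford MEST histology scores, prior
RAS-blocker and immunosuppressant use and (in the "with race" variants) race.
A patient's linear predictor is

    LP = Σⱼ βⱼ (fⱼ(xⱼ) − cⱼ)

with per-term transforms `fⱼ` (identity, natural log, indicator) and
centering constants `cⱼ`, and the absolute risk at horizon `t` is
`1 − S₀(t)^{exp(LP)}`. The "with race" variants violate proportional hazards
for Chinese race, so the published tool applies a piecewise hazard at 36
months; the engine accumulates the cumulative hazard segment-wise:

    risk = 1 − exp(−[H₀(min(t, 36)) e^{LP+β_early}
                     + max(0, H₀(t) − H₀(36)) e^{LP+β_late}]),  H₀ = −ln S₀.

`H₀` is linearly interpolated between the tabulated baseline-survival times,
with `S₀(0) = 1` assumed when the table starts after zero. Horizons outside
the tabulated span are an error (the tool is undefined beyond 80 months).

**Coefficient files.** Constants are data, not code: every model variant is a
JSON file `{model_id, variant, terms[], race_piecewise?, baseline_survival[]}`
so transcribed sets can be dropped in and audited. The four sets shipped
under `src/iganpt/data/` are *synthetic stand-ins* — magnitudes chosen to
mimic the published tool's covariate structure and give a realistic LP
spread (SD ≈ 1.2) — because the published constants live in source-paper
supplements that are not distributed here. Their `provenance` field says so.
A fifth `toy` set supports tests and documentation.

**Risk groups.** Patients are split at the 16th/50th/84th LP percentiles.
Quantiles use linear interpolation at position `1 + (n − 1)p` on the order
statistics; boundary rules are low `< Q16`, intermediate `≤ Q50`, higher
`≤ Q84`, highest `> Q84`. This convention exactly reproduces the published
tie-free group sizes 109/230/229/109 (n = 677) and 91/192/192/91 (n = 566).
Boundary ties inherit the lower-group rule and trigger a warning, since the
printed counts assume tie-free LPs.

**Drug remapping.** The novel-therapy validation recodes ERA and SGLT2i as
RAS blockade and Nefecon, hydroxychloroquine and telitacicept as
immunosuppression. The operation copies the record, never unsets an existing
flag, and is idempotent.

**CKD-EPI.** The 2009 creatinine equation with the published tabulated
sex-specific leading constants (female 144, male 141; κ = 0.7/0.9,
α = −0.329/−0.411) and no race coefficient; creatinine in µmol/L is divided
by 88.4.

## Validation metrics

All metrics are evaluated at a configurable horizon, default 60 months (the
5-year risk, matching the study cohort's median follow-up).

* **C-statistic (Chambless-type).** Each subject's probability of having the
  event by the horizon is derived from the overall Kaplan–Meier curve: 1 for
  observed events by the horizon, 0 for subjects observed beyond it, and the
  conditional probability `1 − S(h)/S(c)` for subjects censored at `c ≤ h`.
  The C-statistic is the probability-weighted proportion of concordant
  case/control pairs (marker ties count ½). With complete follow-up through
  the horizon this reduces *exactly* to pairwise concordance, which is the
  oracle used in the tests; an IPCW estimator (scikit-survival) provides an
  independent cross-check under light censoring. The two estimators can
  differ under heavy censoring.
* **Calibration slope.** The Cox coefficient of the LP as sole covariate;
  1 means the predicted risk spread is correct, < 1 means over-dispersed
  (too-extreme) predictions.
* **Royston–Sauerbrei D / R²_D.** LPs are rank-transformed to Blom scores
  `Φ⁻¹((r − 3/8)/(n + ¼))` scaled by `1/κ`, `κ = √(8/π)`; `D` is the Cox
  coefficient on that covariate and `R²_D = (D²/κ²)/(π²/6 + D²/κ²)`. Exact
  rankits are unnecessary at the sample sizes used. For a true standard
  normal LP with unit coefficient, `R²_D → 1/(1 + π²/6) ≈ 0.378`, an identity
  verified by simulation.
* **ICI.** The observed risk is smoothed by a Cox regression on a restricted
  cubic spline (3 knots at the 10th/50th/90th percentiles, Harrell basis;
  knot count configurable) of `cll(p) = ln(−ln(1 − p))`; the ICI is the mean
  absolute difference between each subject's smoothed observed risk at the
  horizon and their predicted risk. Predictions at exactly 0 or 1 are
  clipped to `[1e−6, 1 − 1e−6]` with a warning. The published report names
  the ICI but not the smoother; the spline-Cox smoother is this package's
  choice.
* **Decile calibration / risk-group comparison.** Ten LP-decile groups (same
  interpolated-quantile convention as the risk groups, for internal
  consistency) with mean predicted risk vs Kaplan–Meier observed risk and
  95 % CI; the same per risk group, plus event counts.

## Survival core

Kaplan–Meier and Cox fitting stand on lifelines behind this package's
interfaces. KM confidence bands use the exponential-Greenwood (log(−log))
transformation so they stay inside [0, 1] — they feed the calibration-plot
CIs. Cox fits use Efron tie handling (the ecosystem default the study's
software used) with Newton iteration tightened to a log-likelihood change
below 1e−9, max 100 steps. Monotone likelihood (separation/divergence) is
detected — convergence failure, solver warnings, or |coef| > 8 — and flagged
rather than silently reported; a lightly ridge-penalized refit supplies
finite numbers in that case, marked non-converged. The risk-group analysis
fits indicators against the low-risk reference and obtains the trend p-value
from a Wald test on a separate Cox fit of the ordinal group score (0–3); the
published tables print "P-value for trend" without naming a method, so the
ordinal-Wald choice is documented here.

## eGFR slopes

One linear mixed model (statsmodels MixedLM, REML by default) on long-format
eGFR: fixed effects time, risk-group × time interaction, group main effects
and baseline adjusters (age, sex, MAP, 24-h proteinuria, MEST scores);
random intercept and slope per subject. The per-group slope is the fixed
time effect plus the group's interaction term, CI from the fixed-effect
covariance, reported in mL/min/1.73 m² per year whatever the internal time
unit (fitting in months and rescaling ×12 agrees with fitting in years).
Subjects with fewer than two observations are dropped with a warning; a
singular random-effect covariance triggers a flagged refit with random
intercepts only.

## Synthetic cohort

The study's patient data are not shareable, so the generator emulates its
published baseline table: truncated-normal age (median 22, IQR 17–29) and
MAP (99, 90–108), log-normal proteinuria (1.4, 0.8–2.5), a two-component
normal mixture for eGFR calibrated to the median/IQR *and* the printed
<30 / 30–60 / 60–90 / ≥90 category fractions, Bernoulli/ordinal MEST scores
(M1 50.8 %, E1 36.9 %, S1 75.9 %, T1 26.4 %, T2 8.7 %), RASB 33.7 %,
immunosuppressant 7.8 %, all-Chinese race. Dependence is induced by a
Gaussian copula with a fixed, documented correlation matrix (eGFR lower with
older age and higher T score; proteinuria higher with MAP, T, M and E).
The published report gives marginals only — the correlations are declared
assumptions. Every subject receives at least one novel drug; a 82/677
fraction gets ERA/SGLT2i only and the rest get combinations weighted toward
hydroxychloroquine-containing regimens, mirroring the cohort's most common
combinations.

Event times follow `h(t|x) = θ h₀(t) exp(β · LP(x))` with Weibull baseline
`H₀(t) = (t/λ)^k`, sampled by inverse transform; censoring is log-normal
dropout (median 57.6 months, log-SD 0.97, matching the cohort's follow-up
IQR of 2.2–8.1 years) clipped to [12, 246] months. The shipped coefficient
sets' baseline-survival tables tabulate the same Weibull (k = 1.8, λ = 162
months), so θ = 1, β = 1 is a world in which the tool is exactly the true
model. The defaults θ = 0.5, β = 0.5 emulate the treated study cohort —
novel-therapy hazard reduction plus LP attenuation — and λ was calibrated
once so this default shows a 5-year observed risk of ≈ 9.8 %, the study's
anchor. Under these defaults the pipeline reports calibration slope ≈ 0.5,
ICI ≈ 0.14 and `R²_D` ≈ 16–20 %, the qualitative (and largely quantitative)
pattern of the published validation.

Trajectories are per-subject linear eGFR paths: slope mean by LP quartile
(defaults near −2.9 … −2.55 mL/min/1.73 m²/year, the near-flat profile the
study reported), subject-level slope SD 1.2, 6-monthly visits, visit noise
SD 4. When trajectories are generated, the composite outcome is re-derived
from the noiseless trajectory — the first crossing of max(50 % of baseline
eGFR, 15) inside the subject's observation window sets the event — keeping
the outcome definition literally true in synthetic data. The generator does
*not* emulate real-data features such as informative censoring, visit-driven
measurement, non-linear eGFR decline, correlated missingness or measurement
error in covariates; passing tests therefore demonstrate the correctness of
the pipeline, not the tool's performance on real patients.

## Scenario pipeline

Scenario (ii) filters to subjects whose novel therapy is a subset of
{ERA, SGLT2i}; scenario (iv) applies the drug remap; scenarios (iii)/(iv)
evaluate the post-biopsy model at the 12-month landmark. True landmark
covariates are not simulated longitudinally, so the landmark step perturbs
baseline values (eGFR drifting at N(−2.7·years, 3); log-normal proteinuria
jitter, SD 0.25 on the log scale; MAP jitter SD 4) and re-origins follow-up,
dropping subjects whose observation ends by the landmark — an explicit
assumption. Reports are written as JSON plus CSV tables (decile calibration,
group table, per-group KM curves); identical inputs and seed give
byte-identical files. Percentages in summary tables use half-up rounding to
one decimal, the published tables' style.

## Numerical and problem-size choices

* Monte-Carlo sizes in the tests/acceptance script were fixed a priori so
  simulation error is small relative to the asserted bounds: the
  self-consistency suite runs at n = 30 000 (per-decile KM standard error
  ≈ 0.01 against a 0.03 bound; at a few thousand subjects the upper-decile
  KM noise alone would approach the bound), the miscalibration suite at
  n = 5000, the `R²_D` identity at n = 10 000, slope recovery at n = 300.
* All randomness flows through `numpy.random.default_rng` seeds; every
  simulation in tests and scripts is seed-fixed and reproducible.
* Degenerate inputs fail loudly: empty samples, constant covariates,
  all-equal LPs, horizons beyond the baseline table, inverted IQR targets,
  empty decile groups.

## Known limitations

* The shipped coefficient sets are synthetic; validating the *published*
  tool on real data requires transcribing its constants into a JSON file.
* The Chambless-type C uses KM event-membership probabilities, which assumes
  censoring independent of the marker; under strong marker-dependent
  censoring it and the IPCW estimator diverge.
* The landmark covariates of scenarios (iii)/(iv) are perturbation-based
  stand-ins, not a joint longitudinal model.
* `R²_D` assumes approximate normality of the LP distribution; on heavily
  skewed LPs it is an approximation (as in the original proposal).
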