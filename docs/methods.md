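# Methods

## Model and estimation

The response Y is shoot dry weight (g/plant); predictors are SPAD (X1),
stomatal conductance Gs (X2, mmol·m⁻²·s⁻¹), shoot sap Na⁺ (X3, mM) and
shoot sap K⁺ (X4, mM), all in raw units — no centering or scaling
anywhere, so fitted coefficients are directly comparable to published
raw-unit slopes. The candidate set is the full quadratic polynomial:
intercept, 4 linear, 4 square and 6 cross terms (15 in total, fixed
canonical order, cross terms lexicographic i<j). The intercept is an
ordinary candidate, eligible for elimination; the bundled reference
model has none.

Slopes are minimum-norm least squares computed from the SVD of the
design; singular values below `rel_tol × s_max` (default `rel_tol =
1e-10`, configurable) are treated as zero. This one mechanism handles
duplicated or collinear columns in every stage (candidate fits,
auxiliary regressions) without forming normal equations. Leverages come
from the left singular vectors (h = diag U_r U_rᵀ), and the residual SD
uses denominator n − p with p the number of requested terms.

Predicted (holdout) residuals use the PRESS identity ẽᵢ = eᵢ/(1−hᵢᵢ),
which equals the prediction error of the model refitted without record
i; a leverage within `rel_tol` of 1 is an error naming the record. The
HC3 slope covariance is the sandwich built from ẽᵢ² — equivalently from
eᵢ²/(1−hᵢᵢ)² — with the truncated pseudo-inverse as bread. Slope
t-tests use t = β̂ⱼ/√Sⱼⱼ against t(n−p).

## Performance measures and the TSS convention

RMSE_HO = √mean(ẽ²), MAE_HO = mean|ẽ|, R²_HO = 1 − Σẽ²/TSS and
R²adj = 1 − (1−R²)(n−c)/(n−p). Both total-sum-of-squares conventions are
implemented: centered (TSS about the mean, c = 1) and uncentered
(TSS = Σy², c = 0). The pipeline defaults to the centered convention for
its headline numbers and reports both. The reason is empirical: on
synthetic data whose signal-to-noise matches the reference fit, the true
no-intercept quadratic structure has uncentered R²adj ≈ 0.97 but
centered R²adj ≈ 0.6–0.8 — only the centered convention lives on the
scale of reference values near 0.67, so it is the convention those
numbers must have come from. The adequacy ANOVA is separate and keeps
the natural null for the fitted structure: against the zero model
(uncentered, F(p, n−p)) when no intercept is present, against the
mean-only model (centered, F(p−1, n−p)) when one is.

The error-nullity check is a two-sided one-sample t-test that the mean
predicted residual is zero.

## Stepwise selection

Goal: the term set of maximum cardinality in which every slope is
significant (two-sided HC3 t-test, α = 0.05 by default). Three phases,
each accepted change being one recorded step:

1. backward elimination from all 15 candidates — drop the single term
   with the largest non-significant p, refit, repeat;
2. re-entry — each removed term is tentatively restored (canonical
   order) and kept only if the refit is again all-significant;
3. exchange — each (retained, removed) pair is tentatively swapped and
   kept only if all-significant and strictly better (more terms, or
   larger minimum |t|).

Phases 2–3 loop until a full pass changes nothing. Ties on the largest
p-value remove the later term in canonical order, so runs are
deterministic; p-values are recomputed after every accepted change. The
phase semantics are this package's reconstruction of a three-phase
stepwise family for which only the phase step counts and the
maximal-cardinality objective are documented; the engine is isolated in
one module so alternative semantics can be swapped in.

## Outlier screening

Operates on a fixed term structure (the selected set). Each cycle: fit,
convert every record's externally studentized residual — computed by the
closed-form deletion identity s₍ᵢ₎² = ((n−p)s² − eᵢ²/(1−hᵢᵢ))/(n−p−1) —
to a two-sided t(n−p−1) p-value, apply Benjamini–Hochberg step-up at
q = 0.30 over the current n records, and remove all flagged records at
once. Cycling stops when nothing is flagged, when a purge would leave
n ≤ p+1, or at 25 cycles. The BH family is per-cycle (m = current n);
numerically exact fits flag nothing.

## Diagnostics

*Heteroskedasticity*: a White-style auxiliary regression of the squared
predicted residuals on the full 15-term quadratic in the four raw
predictors, over the same records. Reported: the auxiliary overall-F
p-value and adjusted R² (centered, since the auxiliary model has an
intercept). Verdict homoskedastic iff p ≥ 0.05 and auxiliary R²adj <
0.05; the ceiling is deliberately small — any genuinely homoskedastic
fit has auxiliary R²adj near zero. Squared (not absolute) residuals are
used, matching the White/Breusch–Pagan family. A variance-modeling /
WLS "relaxing" branch is out of scope. Constant squared residuals are
reported as homoskedastic directly (p = 1, R²adj = 0).

*Normality*: JB = n/6·(skew² + excess-kurtosis²/4) with biased
(population) moment estimators; the null distribution is simulated with
`n_mc` standard-normal pseudo-samples of the same n (default 10,000),
and p = (1 + #{JB* ≥ JB})/(1 + n_mc) — the add-one estimator, never
exactly zero. Simulation is chunked, seeded and bit-reproducible; the
estimator-bias choice is immaterial because the simulated null uses the
same estimator.

## Prediction

A final model carries its term list, slopes, HC3 covariance S, residual
SD and degrees of freedom ν. E[Y|x⃗] is the linear form, Var[Y|x⃗] =
x⃗ᵀSx⃗ (clipped at zero; this is the variance of the estimated *mean*
response — the default intervals are confidence bands for the mean, and
a prediction-interval option adding the residual variance exists but is
off by default). Intervals are mean ± t₍(1+γ)/2, ν₎·√Var. The bundled
reference model uses ν = 119 (124 records minus 5 terms). Scenario
sweeps use the five documented grids (SPAD 10–50 step 1 → 41 points; K⁺
10–300 step 5 → 59; Gs 10–90 step 2 → 41; each against 3 × 5 fixed-level
combinations). With no cross terms, each variable's optimum is
−β_lin/(2β_quad) independent of the others: Gs ≈ 46.2 mmol·m⁻²·s⁻¹ and
K⁺ ≈ 209.5 mM for the reference slopes.

## Synthetic data

The generator emulates the glasshouse design the pipeline targets: 10
genotypes × 3 salinity levels (0/50/100 mM NaCl) × 5 replicates, trimmed
to 146 records by dropping trailing rows. Genotype baselines are drawn
uniformly from the middle half of each predictor range (SPAD 10–50, Gs
10–90, K⁺ 10–300, Na⁺ 0–400 mM leaf sap); each salinity step shifts cell
means by a fixed fraction of the range width (Gs −15%, K⁺ −15%, Na⁺
+30%, SPAD −5% per step — chosen once as a plausible salt response:
stomatal closure, K⁺ loss, Na⁺ accumulation, mild chlorophyll
condensation); replicates jitter normally with SD 5% of range; values
are clipped to the ranges. The response is the full-quadratic mean at
the reference slopes (Na⁺ carries no effect, mirroring the conclusion
the pipeline is meant to reach) plus N(0, 0.28²) noise, floored at zero
because dry weight is non-negative (the floor binds for ≈0.01% of
records). Planted outliers displace Y by ±shift·noise_sd (default 8σ).
Everything derives from one seed; identical seeds give byte-identical
CSVs.

What the generator does *not* emulate: genotype-by-treatment
interactions beyond additive shifts, measurement error in the
predictors, non-Gaussian noise, and any mechanistic physiology. Passing
tests therefore demonstrate correctness of the algorithms under the
assumed model, not validity of the model for real glasshouse data.

## Term-selection instability (a real property, not a bug)

With predictors confined to positive physiological ranges, the
no-intercept quadratic basis is strongly collinear (corr(X, X²) > 0.95
over such ranges). At the study's signal-to-noise (noise SD 0.28,
n = 146), alternative term sets routinely fit the planted surface as
well as — sometimes better than — the true one, with every slope
decisively significant under HC3 (verified against an independent OLS
HC3 implementation). A maximal-cardinality significance-driven selector
must then prefer them; measured exact recovery of the planted 5-term
set is below 10%, and even at near-zero noise it caps near 50% because
the re-entry phase gives each removed term a fresh α-level
false-inclusion chance. The *surface* is nevertheless recovered: fitted
values track the noiseless truth within the noise floor, slope estimates
on the true structure are nearly unbiased (median |bias| < 10% for the
linear terms), and outlier screening is unaffected. Users should treat
the selected term *labels* as one member of an equivalence class of
near-identical response surfaces, not as causal structure.

## Numerical choices and limitations

- Double precision throughout; no iterative solvers.
- SVD truncation `rel_tol = 1e-10` everywhere, configurable per call.
- Numerically exact fits (SSE below n·(rel_tol·scale)²) short-circuit
  outlier p-values to 1 and the adequacy p to 0.
- Zero-variance predicted residuals: nullity p is 1 (zero mean) or 0.
- Degenerate degrees of freedom (n ≤ p for tests, n ≤ p+1 for
  studentization) raise errors rather than returning NaNs; the pipeline
  wraps stage failures with the stage name.
- Pipeline reports echo the full configuration and seed; every number in
  a report is recomputable from input + config + seed.
- Problem sizes in tests and the acceptance script (50-replicate
  selection benchmarks, 100-replicate calibration checks, n_mc = 2000
  for Monte-Carlo calibration replicates) were chosen to keep each check
  to seconds while leaving Monte-Carlo error well inside the asserted
  bands; single runs use the full n_mc = 10,000 default.
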