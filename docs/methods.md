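# Methods

## Model

Let y_ijk be the value of biomarker k (k = 1..K) for patient i at their
j-th observation of that measure, at t years since disease onset.
Stacking measure-wise vectors Y_i = (Y_i1', ..., Y_iK')', the model on
the quantile-normalized scale is

    Y_i = X_i beta + Z_i b_i + e_i,
    b_i ~ N_Kq(0, D),    e_i ~ N(0, Sigma_i),

with X_i and Z_i block diagonal by measure.  Every measure's fixed block
contains the same columns — intercept, standardized age of onset,
reference-coded race/gender/skin subtype, three autoantibody
indicators, and a natural cubic spline of time (df 3, internal knots at
10 and 30 years, boundary knots at 0 and 40 years) — with
measure-specific coefficients.  The random block per measure is
[1, t, (t − (a−10))₊, (t − (a−3))₊], where the anchor a is the patient's
most recent observation time; hinge knots that would precede onset are
floored at 0.  The anchored hinges let the predicted recent trend bend
in the last decade and the last three years of follow-up without letting
early observations dominate.

### Residual structure

The residual law e_i ~ N(0, Sigma_i) needs a concrete Sigma_i.  We take
the trait-by-unit structure standard in multi-response mixed models:
measures recorded at the same visit (times within 1/365.25 years, i.e.
the same day) share an unstructured K×K covariance Sigma_e, and
residuals at distinct visits are independent, so Sigma_i is
block-diagonal by visit.  This makes the inverse-Wishart update
conjugate and encodes the clinically plausible "same-day shock" shared
across an echo or PFT panel.  Cross-visit residual correlation beyond
what Z_i D Z_i' induces is not modelled.

### Priors and sampling

Diffuse conjugate priors: beta_j ~ N(0, 1e8) independently;
D ~ IW(Kq + 1, 0.01 I); Sigma_e ~ IW(K + 1, 0.01 I) — the smallest
proper degrees of freedom in the conjugate class, with scale small
relative to unit-variance data.  All are configurable
(`PriorSpec`).  Estimation is a Gibbs cycle whose full conditionals are
all Gaussian or inverse-Wishart: (1) impute measures missing at an
observed visit from their conditional Gaussian given the observed
same-visit components (data augmentation — this is how arbitrary
missingness is absorbed); (2) per-patient random effects; (3) fixed
effects; (4) D; (5) Sigma_e.  Every multivariate normal draw goes
through a Cholesky factor with trace-scaled jitter (1e-10 · tr/dim,
up to 3 escalating retries) on failure; jitter events are counted and
reported.  Updates are vectorized across patients (batched Cholesky)
and across visits grouped by missingness pattern, giving roughly 1–3 ms
per iteration for cohorts of a few hundred patients, so the reference
schedule (50,000 iterations, burn-in 2,000, thinning 10) is minutes of
work and the scaled-down schedules used in the test suite (2,000–8,000
iterations) run in seconds.  Convergence is monitored with the
Gelman–Rubin potential scale reduction factor over fixed effects,
random effects, and the entries of D, with the conventional 1.1 alarm.

The sampler was validated three independent ways: against the exact
Gaussian GLS posterior of beta with covariances held fixed (including
under missing data); against a restricted-maximum-likelihood univariate
mixed-model fit (statsmodels MixedLM) for K = 1; and against a
separately coded, loop-based reference Gibbs sampler on a small cohort
with Sigma_e sampled and ~30% missing cells.

## Preprocessing

Each measure is mapped through its empirical CDF composed with the
standard-normal quantile function.  Plotting positions are Hazen,
(r − 0.5)/n, with average ranks for ties; values between order
statistics are interpolated linearly on the probability scale; values
outside the training range are clamped to probability 1/(2n) (or
1 − 1/(2n)).  Thresholds are pushed through the same map, so empirical
crossing frequencies are preserved exactly, and the inverse map reports
predictions on the clinical scale (without extrapolating beyond the
observed support).  Within cross-validation the transform is fitted on
training folds only.

## Prediction and CVSP

The conditional distribution of the K-vector at a future time given the
patient's stacked history is Gaussian with the usual conditioning
formulas on V_i = Z_i D Z_i' + Sigma_i; an empty history returns the
marginal (cold-start) moments, so a brand-new patient still receives
risks from covariates and population trends.  Event probabilities are
marginal per-measure tail areas at the transformed thresholds; by
default parameters are plugged in at posterior means (fast,
deterministic), with optional averaging of probabilities over posterior
draws.  Joint multi-event probabilities are available in principle from
the same conditional Gaussian but only marginals are reported.

CVSP: patients are randomly partitioned into 5 folds; one model
(including its own quantile transforms and anchors) is fitted per
training complement; each patient's pooled visit times are walked from
first to last, emitting at each step the prediction of the next visit
given only strictly earlier data, from the fold model that excluded the
patient.  A patient with n pooled visits yields exactly n instances
(cold start included).  Observed labels at an instance come from the
measure actually recorded at the target visit; instances where an
event's measure was not recorded are excluded from that event's AUC.
Pooled (not per-fold-averaged) ROC curves give the CV-AUC; confidence
intervals are DeLong, computed on the logit scale.  At prediction time
the anchor is the latest history time, so hinge knots move forward as
history accrues; during fitting the anchor is fixed at the patient's
last training observation.

## Comparators

The event table has one row per (event, patient, pooled target visit)
with the event's measure observed at the target and at least one prior
visit.  Predictors: most recent and second most recent prior values of
the measure (spline-expanded, natural splines with df 2, boundary knots
at the training 5th/95th percentiles, one internal knot at the median),
most recent prior value of each other measure, the count of past events
of the measure, and the common covariates.  Predictors that do not
exist yet remain missing and are completed by multiple imputation
(scikit-learn's IterativeImputer with posterior sampling, m = 5
completions by default, 10 iterations); predicted probabilities are
averaged across completions.  LM1 omits the second-to-last value and
event count, LM2 adds the former, LM3 both.  Logistic fits are
unpenalized with an L2 fallback on separation.  The random forest uses
the LM3 covariate set (500 trees, sqrt(p) features per split) and is
evaluated on out-of-bag probabilities.  Fold assignments are shared
with CVSP so comparisons are paired.

## Diagnostics

Residuals Y_i − X_i beta-hat are standardized either marginally
(divided by the square roots of diag(V_i); this is what per-measure Q-Q
plots display) or whitened by the inverse Cholesky factor of V_i, which
removes within-patient correlation and makes the joint-Gaussianity KS
test exact under the model; whitened is the default for testing.
Calibration uses a Hosmer–Lemeshow-form statistic over quintiles of
predicted probability (ties to the lower group; expected counts floored
at 0.5 events when degenerate, with a warning).  With true (not fitted)
probabilities its null mean is the group count.  The empirical
correlation matrix bins observations to the nearest integer year
(years 0–10, one value per patient-year, mean if several) and reports
pairwise-complete correlations, leaving cells with fewer than 3
complete pairs missing.

## Synthetic cohorts

The generator draws from the model's own data-generating process and
then warps each measure to a clinical-like scale, so the pipeline's
quantile normalization has real work to undo.  Default conditions,
chosen to mimic a scleroderma registry cohort:

- K = 4 measures (pFVC, pDLCO, EF, RVSP); m = 300 patients.
- Baseline covariates: age of onset ~ N(45, 13²) clipped to [18, 80];
  race 60/25/15% white/black/other; 80% female; 60% limited cutaneous
  subtype; ACA/RNAPol/Scl-70 prevalences 30/20/25%.
- Visit process: first visit uniform over 0–20 years since onset
  (patients present at varying disease durations), then 5–15 visits
  with exponential gaps of mean 1 year, truncated to [0, 40] years;
  each measure independently skipped at a visit with probability 0.2
  (at least one measure always observed).
- Random effects: D = R ⊗ diag(1.0², 0.05², 0.08², 0.12²) for
  (intercept, slope, 10-y hinge, 3-y hinge), with measure correlations
  0.7 (pFVC–pDLCO), 0.4 (EF–RVSP), 0.2 otherwise.  Residuals: SD 0.5
  per measure, correlations 0.5 / 0.25 / 0.15 in the same pattern.  The
  random-intercept SD is twice the residual SD: strong between-patient
  heterogeneity, the regime where history-based prediction pays off.
- Warps: pFVC and pDLCO affine (82 + 15z, 75 + 16z); EF left-skewed,
  72 − 14·exp(−0.45z); RVSP right-skewed, 22 + 9·exp(0.5z).  Identity
  warps are available for exact-Gaussian studies.  Under the defaults
  the mild-event rates per observation are roughly 25% (pFVC ≤ 70),
  15–20% (EF < 50) and 5–10% (RVSP ≥ 45), with severe events several
  times rarer — common mild events, rare severe ones.

What the generator does **not** emulate: informative (MNAR) visit
schedules, measurement batch effects, covariate missingness, secular
drifts, or registry-specific cleaning artifacts.  Passing tests show
the machinery is correct and well calibrated when its assumptions hold;
they do not certify performance on real registry data.

## Simulation-study designs in the test suite

Two designs deserve explanation because identifiability, not
correctness, drives them:

- **Variance-component identifiability.**  At clinic-like visit
  densities (~1/year) the variances of the anchored 10-y and especially
  3-y hinge effects are only weakly identified — each patient
  contributes one to three observations inside the window, and for
  patients with short follow-up the 10-y hinge is nearly collinear with
  intercept and slope.  Their posteriors then shrink noticeably toward
  the diffuse inverse-Wishart prior (confirmed to vanish under dense
  schedules).  Likewise, when patients enter the study late, the
  intercept variance *at onset* is an extrapolation confounded with the
  slope variance.  The parameter-recovery study therefore uses an
  identifiable design — K = 2, intercept+slope random effects, entry
  within 3 years of onset, 8–14 visits at mean 1.5-year gaps, identity
  warps — where posterior means are unambiguous estimates of the truth.
  Practitioners fitting the full q = 4 structure should read the hinge
  variance estimates as partially prior-informed.
- **Conjugate oracle.**  The fixed-covariance check compares the
  empirical covariance of sampled fixed effects to the exact GLS
  posterior covariance; the Monte-Carlo error of an empirical
  covariance grows with dimension, so the check uses a compact fixed
  block (intercept + time spline, 8 coefficients) and a long thinned
  chain.

Problem sizes throughout the suite (cohorts of 24–300 patients, chains
of 2,000–42,000 iterations, 50 replicate fits at 5,000 iterations) were
chosen as the smallest scales at which each property is cleanly
decided.

## Numerical and policy choices

- Duplicate (patient, time, measure) rows are averaged with a warning;
  same-day repeats have no canonical resolution.
- Event labelling at exact thresholds uses strict inequality for EF and
  inclusive for pFVC/RVSP, matching the printed clinical definitions;
  for continuous model probabilities the distinction is immaterial.
- Category dictionaries (race, gender, skin subtype) are fixed
  package-wide; age is standardized with fixed constants (45, 13), so
  encodings are deterministic and simulated truth coefficients are
  directly comparable to estimates.  Unseen levels raise.
- Fold assignment is a seeded permutation with round-robin allocation:
  patient-level, sizes within one of each other.
- AUC ties use midranks; DeLong intervals are logit-scaled.  Whether
  the resampling unit for the CI should be the instance or the patient
  is genuinely open; instances are used, so intervals are slightly
  anticonservative under within-patient correlation.
- Posterior storage is per chain in memory, exportable to HDF5;
  predictions default to plug-in posterior means.

## Known limitations

- Residuals are Gaussian by construction of the marginal transform, but
  joint Gaussianity is an assumption — check it with the whitened
  residual diagnostics; a heavy-tailed conditional law would need a
  different predictive family.
- The hinge variance components are weakly identified at sparse visit
  schedules (above); D's posterior is then prior-sensitive even though
  predictions, which integrate over b, remain well calibrated.
- No time-to-first-event summaries; risks are per-visit marginal
  crossing probabilities.
- The imputation engine models all predictors as Gaussian conditionals,
  a simplification for the binary covariate flags.
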