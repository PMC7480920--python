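# Methods

## Problem and model

The package compares longitudinal biomarkers as clinical-trial outcome
measures for early Alzheimer's disease.  Each biomarker's natural history
in a diagnostic group is modelled as a linear mixed-effects model with
random intercept and slope per subject:

    y_ij = β₀ + β₁ t_ij + b₀ᵢ + b₁ᵢ t_ij + ε_ij,
    (b₀ᵢ, b₁ᵢ) ~ N(0, D) unstructured,  ε_ij ~ N(0, σ_w²) i.i.d.

Times are months at every interface and are converted to years inside the
fitting code, so slopes are per-year.  Estimation is REML (ML is available
as an engine option through statsmodels).  No demographic covariates enter
the default model; the fitting functions operate on exactly the columns
`subject_id`, `visit_month` and one value column, so covariate-adjusted
residuals can be passed in instead if a user needs adjustment.

The per-arm sample size for detecting a slope difference Δ with power 1−β
at two-sided α on the visit schedule t₁…t_J is the standard linear-mixed-
model slope formula

    n = 2 (z_{1−α/2} + z_{1−β})² (σ_b² + σ_w²/ssq) / Δ²,   ssq = Σⱼ(tⱼ−t̄)².

σ_b² is the *slope* random-effect variance D₂₂ only — the intercept
variance does not affect the precision of a within-subject slope — and
σ_b² + σ_w²/ssq is exactly the sampling variance of one subject's OLS
slope, which is what makes the formula the classical two-sample normal
calculation applied to per-subject slopes.  The power function uses the
dominant-tail normal approximation Φ(Δ√(n/(2(σ_b²+σ_w²/ssq))) − z_{1−α/2});
the neglected opposite tail is < 1e-6 in any regime with meaningful power,
and the function inverts the sample-size formula to 1e-9.

Two treatment mechanisms define Δ as a fraction f (default 0.30) of a
slope: "full" uses the whole group slope (therapy could halt progression
entirely); "disease_specific" uses the group-minus-control slope (therapy
can at best restore normal-aging progression).  Δ enters squared, so only
its magnitude matters; a disease-specific slope whose sign opposes the
group slope is accepted with its magnitude rather than rejected, since the
formula is agnostic to direction.

## Schedules

`build_schedule(duration, frequency)` generates months {0, f, 2f, …} up to
the duration; when the frequency does not divide the duration the last
visit is the largest attainable multiple (an `anchor_end` flag appends a
final visit at the duration itself).  The baseline visit is always included
and counted as an assessment.  Sweeps hold the reference biomarker (plasma
NfL by default) at its own fixed frequency and report
ratio = n_reference / n_biomarker, so values above 1 mean the biomarker
needs fewer subjects than the reference.

## Estimation engines

Two REML engines maximise the same restricted likelihood:

- **statsmodels MixedLM** — the default for one-off fits and the
  independent reference in the test suite.
- **native** — a profiled-REML solver specialised to the
  random-intercept/slope model.  Subjects sharing an observation-time
  pattern share every design-derived matrix, so the objective reduces to a
  few 2×2 solves per unique pattern (Woodbury identity), and β and σ_w²
  are profiled out, leaving a 1–3 parameter Nelder-Mead search over the
  log-Cholesky factor of D/σ_w².  Moment-based starting values come from
  the covariance of per-subject OLS estimates corrected for their sampling
  variance; bootstrap refits warm-start from the full-data solution.  This
  engine exists because resampling-based uncertainty quantification needs
  tens of thousands of refits of a tiny model, which a general-purpose
  mixed-model implementation cannot deliver at that cost.

The unit suite fits both engines on shared datasets and requires the native
optimum never to score worse on the REML criterion, with estimates agreeing
to optimiser tolerance whenever both land on the same optimum (MixedLM
occasionally stops at an inferior local solution on unbalanced data).

Non-convergence follows a fallback ladder — unstructured D, then diagonal,
then random-intercept-only (σ_b² = 0) — and is always reported in the fit's
`converged`/`method` fields; downstream consumers refuse non-converged fits
unless forced, and bootstrap replicates that fail are recorded as missing
rather than silently dropped (the convergence rate is part of the result,
and a result with >50% failed replicates is flagged unusable).

## Cohort construction

Diagnostic groups follow amyloid status and the Clinical Dementia Rating:
controls are amyloid-negative with CDR 0, preclinical AD amyloid-positive
with CDR 0, mild AD amyloid-positive with CDR 0.5–1; everything else is
excluded with a recorded reason, making the assignment a partition.
Amyloid status is anchored to baseline by regressing each subject's
longitudinal PET SUVR on time and thresholding the OLS intercept
(positive iff > 0.79, strict); subjects without PET fall back to CSF
Aβ42 (positive iff < 880 pg/mL).  CSF P-tau181 > 27 pg/mL defines tau
positivity for the sensitivity analysis.  The boundary conventions are
strict inequalities throughout, chosen for internal consistency.

Derived measures: the PACC cognitive composite is the *sum* of four
z-scored subtests (MMSE, delayed logical memory, Trail-Making B with its
sign flipped because it is a completion time, delayed ADAS word recall);
visits missing any subtest get a missing PACC rather than a pro-rated one,
because an equally weighted sum is ill-defined under partial data.  The
temporal cortical composite is the surface-area-weighted mean thickness
over entorhinal, fusiform, inferior and middle temporal regions of both
hemispheres, again with no partial composites.

Standardization z-scores each biomarker against the pooled baseline
observations of all eligible subjects (all three groups), so slopes read as
SD/year on one common scale; the reference mean/SD and its provenance are
stored with every transform.  Eligibility requires at least two
post-baseline observed visits in each of MRI, plasma NfL and cognition
(a visit counts for a modality when any of its columns is observed).  The
overlapping-visit sensitivity keeps, per subject, only visit clusters where
all three modalities were observed within ±1.5 months of a common nominal
visit, merging matched rows onto the nominal time.

## Synthetic cohorts

The generator draws per-subject (b₀, b₁) from the bivariate normal implied
by the parameter table and adds i.i.d. Gaussian noise on an ADNI-like
0/6/12/24/36/48/60-month grid, thinned by monotone dropout (per-visit
retention probabilities; once out, always out) and independent per-modality
missingness (whole modality unobserved at a visit).  Auxiliary fields —
longitudinal PET SUVR around a per-subject latent intercept, baseline CSF
Aβ42/P-tau181, CDR global — are group-conditioned normals placed far enough
from the published cutoffs that group labels are recoverable essentially
always; their realism is explicitly a non-goal.

The default parameter table is *illustrative*: the source regime prints no
variance components numerically, so values were chosen once, from the
closed form under truth, to satisfy the documented qualitative orderings —
plasma NfL has the highest within-subject noise (resid SD 0.65 vs 0.12–0.15
for MRI) and the smallest between-subject slope SD (0.05–0.06); MRI
composites progress faster than pNfL in disease groups; disease slopes
exceed control slopes everywhere, with the pNfL preclinical−control gap
fixed at 0.04 SD/year and the mild−control gap at 0.06 SD/year — and to
place the implied required-n ratios (pNfL needing ~2× the subjects of MRI
composites in a 30-month preclinical design) in the published ballpark.
They are not estimates of any cohort.  One root seed drives everything;
per-subject streams are keyed by (seed, subject index) so cohorts are
reproducible regardless of generation order.

What passing tests on these cohorts establish: the estimation, power,
sweep and bootstrap machinery is correct *under the model it assumes*
(linear trajectories, Gaussian components, ignorable missingness).  What
they do not establish: behaviour under nonlinear trajectories, practice
effects, informative dropout, batch effects, or the actual variance
components of any real cohort — required-n values from the bundled defaults
are demonstrations, not trial advice.

## Uncertainty quantification

The bootstrap resamples subjects (never observations) with replacement,
relabelling duplicates as distinct subjects, refits, and re-evaluates the
closed form on the continuous n (the ceiling is applied only for reporting,
to avoid ceiling-induced ties in the resampling distribution).  Intervals
are percentile 95% with B = 250 by default (B = 100 supported).  Paired
comparisons reuse one subject resample for both biomarkers and use the
add-one two-sided p-value 2·min(#{d≤0}+1, #{d≥0}+1)/(B+1), whose floor is
2/(B+1).  Under the disease-specific mechanism the control fit is
re-estimated inside every replicate from its own resample, so control-slope
uncertainty propagates into the interval.

The Monte-Carlo validator simulates balanced complete-data two-arm trials.
Its default test statistic exploits an exact identity of that design: the
mixed-model GLS estimate of the treatment-by-time interaction equals the
difference in arm means of per-subject OLS slopes, whose sampling variance
is σ_b² + σ_w²/ssq — so the pooled two-sample t on per-subject slopes is
the exact-degrees-of-freedom version of the interaction Wald test and runs
vectorised.  A full per-trial LME-refit engine (`engine="lme"`) exists and
agrees with the fast path within Monte-Carlo error in the test suite.

## Numerical choices and problem sizes

- Normal quantiles from scipy; n rounded up after all real-valued
  computation, never below 1.
- Native-engine optimisation: Nelder-Mead, xatol 1e-6 (1e-8 on the polish
  restart), multi-start from the moment estimate plus a coarse diagonal;
  residual variance floored at 1e-300 inside the profiled criterion so
  noise-free degenerate inputs collapse gracefully to the exact fit.
- Sweep grids propagate per-cell errors (zero slope, degenerate variance)
  in an `error` column instead of aborting.
- Test-suite problem sizes were chosen to keep the full run in a few
  minutes while leaving Monte-Carlo noise well below the asserted bands:
  2,000 simulated trials per parameter set (binomial SE ≈ 0.9 points at
  80% power), 200 recovery replicates of 500-subject cohorts, 50 outer
  bootstrap-coverage replications at B = 150.

## Known limitations

- The closed form assumes complete follow-up; no dropout inflation is
  applied (a retention adjustment would multiply n and is deliberately not
  a default, since the formula's source has no dropout term).
- Percentile intervals can undercover for strongly skewed n distributions
  at small cohort sizes; BCa intervals are not implemented.
- The native engine handles exactly the random-intercept/slope model with
  an optional subject-level binary covariate — nothing more general.
- Group assignment trusts baseline CDR and the amyloid cutoffs; no
  measurement-error model for the classifiers.
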