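# trialpower

Which progression biomarker powers an early Alzheimer's disease trial with
the fewest participants?  `trialpower` answers this the way trial
statisticians do: fit a random-intercept/random-slope model to each
candidate outcome measure (plasma neurofilament light, MRI volumetrics and
cortical-thickness composites, cognitive composites) in each diagnostic
group, then convert the fitted slope and variance components into the
per-arm sample size required to detect a fractional slowing of progression.

It is aimed at biostatisticians and trial designers who have (or can
simulate) long-format longitudinal biomarker tables and want reproducible,
uncertainty-quantified sample-size comparisons across candidate endpoints,
trial durations and sampling frequencies.

## The model and the formula

For subject *i* at time *t_ij* (years from baseline), each biomarker in each
group follows

    y_ij = β₀ + β₁ t_ij + b₀ᵢ + b₁ᵢ t_ij + ε_ij,
    (b₀ᵢ, b₁ᵢ) ~ N(0, D),   ε_ij ~ N(0, σ_w²),

estimated by REML.  A two-arm trial that measures the biomarker on the
schedule t₁…t_J and must detect a slope difference Δ with power 1−β at
two-sided level α needs, per arm,

    n = 2 (z_{1−α/2} + z_{1−β})² (σ_b² + σ_w² / Σⱼ(tⱼ−t̄)²) / Δ²

where σ_w² is the within-subject (residual) variance, σ_b² = D₂₂ is the
between-subject variance of individual slopes, and Σ(tⱼ−t̄)² encodes trial
duration and sampling frequency.  Δ is a fraction (default 30%) of either
the whole group slope ("full" treatment mechanism) or the group-minus-control
slope ("disease-specific" mechanism).  Uncertainty in n comes from a
subject-level percentile bootstrap; between-biomarker differences use paired
resampling on the shared subject pool.  A Monte-Carlo trial simulator
provides an independent check of the closed form.

A bundled synthetic-cohort generator emulates an ADNI-like observational
study — three groups (amyloid-negative controls, preclinical AD, mild AD),
0/6/12/24/36/48/60-month visits, monotone dropout, per-modality missingness,
and auxiliary amyloid PET / CSF / CDR fields — so the entire pipeline runs
and is tested without access-restricted data.

## Worked example

The closed form, by hand and by the package: σ_w² = 1.0, σ_b² = 0.1, an
18-month trial with visits every 6 months (t = 0, 0.5, 1.0, 1.5 years, so
Σ(tⱼ−t̄)² = 1.25), Δ = 0.3, α = 0.05, power 0.80:

```python
>>> from trialpower import build_schedule, n_per_arm, power_at_n
>>> sched = build_schedule(duration=18, frequency=6)
>>> res = n_per_arm(sigma_w_sq=1.0, sigma_b_sq=0.1, schedule=sched, delta=0.3)
>>> round(res.n_continuous, 2), res.n_per_arm
(156.98, 157)
>>> round(power_at_n(res.n_continuous, 1.0, 0.1, sched, 0.3), 9)
0.8
```

157 subjects per arm, and the power function inverts the formula exactly.
Simulating 2,000 trials at that n (`trialpower infer mc-power --sigma-w 1.0
--sigma-b 0.3162 --slope -1.0 --n 157 --duration 18 --frequency 6`) gives an
empirical power of ≈0.79 — the closed form and the simulation agree.

A full synthetic analysis from the shell:

```sh
trialpower synth --n-control 300 --n-preclinical 300 --n-mild 300 \
    --seed 1 --out cohort.csv
trialpower run --config run.yaml     # see RunConfig for the keys
```

The run writes `sample_sizes.csv` (per biomarker × group), `sweep.csv`
(duration × frequency grids with ratios against plasma NfL), per-fit JSON,
and a manifest with the config hash.  Under the default generator regime a
30-month preclinical-AD trial needs roughly 120 subjects per arm with the
temporal cortical composite and roughly 210 with plasma NfL (MRI's low
visit-to-visit noise wins), while the sweep shows plasma NfL catching up
monotonically as trials lengthen toward 60 months — its high within-subject
noise averages out, and its small between-subject slope variance becomes
the binding term.

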