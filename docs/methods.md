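# Methods

## The problem

Pre-therapy dosimetry of ¹³¹I for benign thyroid disease requires the
time-integrated activity (TIA) of the thyroid — the integral over time of
the fraction of administered activity retained in the gland — which is the
quantity multiplied by an S-value to obtain the absorbed dose.  A full
time–activity curve needs several patient visits; single-time-point (STP)
dosimetry estimates the TIA from one measurement by borrowing strength
from a population model.  `thyrostp` implements that pipeline end to end:
structural retention models with closed-form TIA, nonlinear mixed-effects
(NLME) population estimation, STP and no-time-point estimators, the EANM
standard-operating-procedure (SOP) closed forms, and the accuracy metrics
used to compare them — together with a synthetic-cohort generator, since
the clinical dataset the design is based on is not publicly available.

## Structural models

Retention (fraction of administered activity) at time `t` hours after
administration:

```
a4c(t) = λ₁/(λ₂+λ₁−λ₃) · (e^{−(λ₃+λp)t} − e^{−(λ₁+λ₂+λp)t}) + a₁·e^{−(λ₁+λ₂+λp)t}
a3b(t) = the same with a₁ ≡ 0
```

with biological rates λ₁, λ₂, λ₃ ≥ 0 (1/h), the ¹³¹I physical decay
constant λp = ln 2 / 192.528 h, and a blood-pool background amplitude
a₁ ≥ 0 that absorbs residual count rate left after the thigh-background
subtraction.  `a3b` is the EANM SOP bi-exponential; `a4c` adds the
background term and is the reference structural model.  Internally `a3b`
is `a4c` with `a1` structurally fixed to 0, so one code path serves both.

Numerics: the first term has a removable singularity at λ₁+λ₂ = λ₃.  It
is evaluated as `λ₁·t·e^{−(λ₃+λp)t}·φ(x)` with `φ(x) = (1−e^{−x})/x`,
`x = (λ₁+λ₂−λ₃)t`, computed from the two bounded exponentials directly
with Taylor fills for |x| < 1e−5 (value) and |x| < 1e−3 (derivative) —
continuous, overflow-free for any admissible parameters and either sign
of x.  The TIA simplifies algebraically to

```
TIA = λ₁ / ((λ₃+λp)(λ₁+λ₂+λp)) + a₁/(λ₁+λ₂+λp)      [units: h]
```

which contains no singular denominator at all, so no limit branch is
needed there.  Administered activity is normalized to 1, so the TIA is in
(fraction of administered activity)·hours.

## Population model and estimation

Patient *i* has `θᵢ = exp(μ + ηᵢ)` with `ηᵢ ~ N(0, diag(ω²))` on the log
scale — log-normal individual parameters with diagonal covariance, which
enforces positivity and is as much structure as ~73 patients support.
Observations are `y = f(t; θᵢ) + g·ε`; the residual error `g` is
proportional by default (`g² = σ²·(f² + 1e−8)`, the tiny floor keeps
weights finite), with additive and combined variants selectable.

Estimation alternates:

1. **Penalized nonlinear least squares** jointly in μ and all ηᵢ
   (batched Levenberg–Marquardt across patients with analytic model
   gradients; damped Gauss–Newton for μ; random effects re-centred each
   round to remove the μ/η aliasing).
2. **Variance step**: `ω²ₖ ← mean(η̂²ₖ + Vₖₖ)` where `V` is the
   Gauss–Newton Laplace posterior covariance, and σ by maximum likelihood
   with the propagated-model-variance correction `diag(J V Jᵀ)` added to
   the residual second moments (without it the MAP residuals understate σ
   and the variances drift).  The update is backtracked in log space
   against the reported objective so each outer iteration is monotone.

The reported objective is the Laplace approximation of the −2 log
marginal likelihood at the empirical-Bayes modes.  Because the
alternating scheme targets the penalized data likelihood — which ignores
the curvature (log-determinant) sensitivity of the marginal — it carries
a small bias for strongly nonlinear parameters (clearest on λ₃); a final
derivative-free polish of μ against the full Laplace objective
(`FitConfig.laplace_polish`, on by default) removes most of it.

Multi-start: `n_starts` (default 1000) log-uniform fixed-effect vectors
within bounds (rates 1e−5–1 /h, a₁ 1e−4–0.5) are screened with a pooled
relative-least-squares objective; the best `n_refine` (default 5) are
refined fully.  Convergence: relative objective change < 1e−6 or
`max_outer` (default 500) iterations, flagged rather than raised.  The
fit returns the best objective snapshot visited, so the returned
objective is never worse than at any refined starting point.  Everything
is deterministic given the seed.

Empirical-Bayes individual estimates are the MAP modes of the conditional
distribution given the fitted population; each patient's TIA is the
closed form evaluated at their mode.

## The five TIA estimators

- **rTIA** — reference: all-time-point `a4c` population fit,
  empirical-Bayes TIA per patient.
- **s1TIA / s2TIA** — single-time-point: for each (patient, time point)
  the population model (`a4c` → s1, `a3b` → s2) is refitted on all other
  patients' complete profiles plus the target's single observation; the
  target's empirical-Bayes TIA is reported.  A `frozen_prior` mode (fit
  the others, MAP the target) is available as a cheaper approximation.
  Grid cells warm-start from the one all-data fit and derive per-cell
  seeds from the global seed and cell index, so results are independent
  of execution order.  Patients lacking the requested late time are
  skipped, not imputed.
- **hTIA** — EANM SOP closed forms:
  `0.97·A(t)·2^{t/5.5 d}·5.5 d/ln 2` for 1 d ≤ t ≤ 3 d and
  `A(t)·t/0.357` for 4 d ≤ t ≤ 8 d, boundaries inclusive, times accepted
  in hours.  The gap (3 d, 4 d) raises an error: the SOP defines no
  formula there and the study only uses 24/48/96/120 h.  No decay
  correction is added — the measured activity already includes it.
- **nTIA** — no-time-point: the closed-form TIA of the arithmetic mean of
  the patients' individual parameters from the all-time-point fit (one
  value for the whole cohort); with no individuals supplied, the
  population typical values are used instead.

The jackknife report perturbs each STP fit by removing one other patient
at a time and summarizes the spread (mean, population SD) of the target's
TIA, and audits that the target contributed exactly one observation to
every replicate dataset.  Both aspects are reported because "robustness
of an STP fit" can reasonably mean either.

## Accuracy metrics

Per patient `RD = (sTIA − rTIA)/rTIA`; per (method, time point) group the
mean RD, the **population** SD (divide by n — this makes
`RMSE = √(meanRD² + SDRD²) = √(mean RD²)` an exact identity; a sample-SD
mode exists for sensitivity checks), the MAPE (mean |RD|), and counts of
|RD| strictly exceeding 5/10/20%.  Percentages are fractions internally
and ×100 only in reports.  The paired Wilcoxon signed-rank test uses the
exact statistic distribution for ≤ 25 non-zero differences (rank-sum
convolution; mid-ranks for ties, made integral by doubling) and a
tie-corrected normal approximation beyond; zero differences are dropped,
and an all-zero comparison returns a degenerate flag rather than a p.

## Synthetic cohorts

`default_population()` is declared configuration, not an estimate of any
clinical population: typical values λ₁ = λ₂ = 0.04 /h, λ₃ = 0.0015 /h,
a₁ = 0.05; 30% log-normal CV on each parameter (diagonal); combined
residual error, 10% proportional with a 0.002 additive floor so late
low-activity samples retain variance; the study sampling design
(2/6/24/48 h for all, 96 h for 53 of 73 or 120 h for 20, one patient
missing the 6-h point → 364 records).  The typical curve peaks near 36 h
at a retention of ≈ 0.40 with a terminal biological half-life of ≈ 2.7
weeks, qualitatively consistent with ¹³¹I thyroid kinetics.  Negative
noisy observations are truncated at zero and flagged.  Cohorts of other
sizes rescale the 53:20 late-time split proportionally.

What the generator does *not* emulate: detector physics, disease-subgroup
kinetics (Graves' vs goitre), covariate structure, or the real cohort's
parameter correlations and heterogeneity level.  Passing tests therefore
demonstrate correctness and internal consistency of the pipeline under a
declared data-generating process — not clinical accuracy on real data.

## Known limitations and observed behaviour

- **λ₃ identifiability.**  At the study design the physical decay
  (0.0036 /h) dominates the terminal slope over λ₃ (0.0015 /h) and each
  patient contributes one late sample, so the typical-value estimate of
  λ₃ has an inherent sampling scatter of roughly ±25% at n = 73 — a
  property of the design's information content, not of the optimizer (a
  gold-standard adaptive Gauss–Hermite likelihood with variances fixed at
  truth scatters at least as much).  TIA-level quantities are much better
  behaved (reference-TIA MAPE ≈ 8%).
- **TIA-level heterogeneity compression.**  30% per-parameter CV induces
  only ≈ 18% between-patient CV in the TIA (numerator and denominator of
  the closed form are correlated).  Consequently the no-time-point
  estimate's MAPE (~18%) exceeds every correctly-specified method but not
  the deliberately mis-specified `a3b` fit (~20–23% at 120 h with
  a₁ = 0.05 background); cohorts with stronger true heterogeneity would
  reverse that ordering.
- The grid's warm-started cells use a reduced iteration budget; the
  jackknife with a joint refit per replicate is O(n²) fits per time point
  and is intended for small cohorts or the `frozen_prior` mode.
- Simulation sizes used in the shipped tests (cohorts of 6–73 patients,
  5–10 seeds per stochastic check) are the package's chosen compromise
  between statistical resolution and a test suite that runs in minutes.
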