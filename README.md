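# thyrostp

Single-time-point (STP) ¹³¹I thyroid dosimetry with population biokinetic
modelling.

Individual pre-therapy dosimetry for benign thyroid disease needs the
thyroid's **time-integrated activity** (TIA) — the integral over time of
the fraction of administered ¹³¹I retained in the gland — but measuring a
full time–activity curve takes several patient visits.  `thyrostp`
implements the alternative: estimate each patient's TIA from a *single*
retention measurement by embedding it in a nonlinear mixed-effects (NLME)
population model, and quantify how accurate that shortcut is relative to
full-curve dosimetry.  It is aimed at medical-physics and pharmacometrics
researchers studying STP dosimetry protocols.

## The model

Thyroid retention (fraction of administered activity) at `t` hours after
administration follows a sum of exponentials

```
a4c(t) = λ₁/(λ₂+λ₁−λ₃) · (e^{−(λ₃+λp)t} − e^{−(λ₁+λ₂+λp)t}) + a₁·e^{−(λ₁+λ₂+λp)t}
```

with uptake/washout rates λ₁, λ₂, λ₃ ≥ 0, the ¹³¹I physical decay
constant λp = ln 2 / 192.528 h, and a blood-pool background amplitude a₁
(`a3b` is the same curve with a₁ ≡ 0, the EANM-SOP bi-exponential).  The
TIA has the closed form `λ₁/((λ₃+λp)(λ₁+λ₂+λp)) + a₁/(λ₁+λ₂+λp)`.
Patients share population-typical parameters with log-normal
inter-individual variability; fitting is multi-start NLME with
empirical-Bayes individual estimates (see `docs/methods.md`).

Five estimators are compared per patient: **rTIA** (all-time-point
reference), **s1TIA**/**s2TIA** (single-time-point NLME with `a4c`/`a3b`),
**hTIA** (EANM SOP closed forms, e.g. `A(t)·t/0.357` for 4–8 d), and
**nTIA** (no measurement at all: population-mean parameters).  Accuracy is
summarized by the relative deviation RD, RMSE = √(meanRD² + SDRD²), MAPE,
exceedance counts (|RD| > 5/10/20%), and a paired Wilcoxon signed-rank
test.  Because the motivating clinical dataset is not public, a
synthetic-cohort generator reproduces its sampling design (n = 73;
2/6/24/48 h for all, 96 h for 53 or 120 h for 20; 364 records) from a
declared population model with known ground truth.

## Worked example

```python
import numpy as np
from thyrostp import SOEFParams, analytic_tia, evaluate_soef, htia
from thyrostp.cohort import default_population, generate_cohort
from thyrostp.nlme import FitConfig
from thyrostp.stp import TIAEstimate, reference_fit, run_stp_grid
from thyrostp.metrics import build_table

p = SOEFParams(lambda1=0.04, lambda2=0.04, lambda3=0.0015, a1=0.05)
print(f"retention at 24 h: {evaluate_soef(p, 24.0):.4f}")
print(f"TIA: {analytic_tia(p):.2f} h")
print(f"hTIA from A(120 h)=0.30: {htia(0.30, 120.0):.2f} h")

cohort = generate_cohort(default_population(), 20, seed=7)
pop, individuals = reference_fit(list(cohort.records), FitConfig(seed=8))
fe = pop.fixed_effects
print(f"fitted typical values: lambda1={fe.lambda1:.4f} lambda2={fe.lambda2:.4f} "
      f"lambda3={fe.lambda3:.5f} a1={fe.a1:.4f}")

rtias = [TIAEstimate(i.patient_id, "rTIA", i.tia) for i in individuals]
s1, _ = run_stp_grid(list(cohort.records), "a4c", [120.0], FitConfig(seed=8))
r = build_table(s1, rtias)[0]
print(f"s1TIA @120 h vs rTIA: mean RD {100*r.mean_rd:.1f}% +/- {100*r.sd_rd:.1f}%, "
      f"RMSE {100*r.rmse:.1f}%, MAPE {100*r.mape:.1f}%, n={r.n}")
```

prints

```
retention at 24 h: 0.3891
TIA: 94.41 h
hTIA from A(120 h)=0.30: 100.84 h
fitted typical values: lambda1=0.0366 lambda2=0.0364 lambda3=0.00145 a1=0.0475
s1TIA @120 h vs rTIA: mean RD -2.6% +/- 2.5%, RMSE 3.7%, MAPE 2.9%, n=5
```

Reading it: the typical patient retains 39% of the administered activity
at 24 h and accumulates a TIA of 94 h; the generating values
(0.04, 0.04, 0.0015, 0.05) are recovered from 20 noisy patients to within
a few percent; and a single 120-h measurement reproduces the full-curve
reference TIA to ~3% on average — the central point of STP dosimetry.

The same workflow is available from the shell:

```sh
thyrostp pipeline --seed 1 --n 73 --out-dir out/
```

which simulates a design-matched cohort, runs the reference fit, both STP
grids, the EANM SOP and no-time-point estimates, and writes the accuracy
table (`metrics.csv`) plus a checksum manifest.  Subcommands `simulate`,
`fit`, `stp`, `eanm`, `metrics` expose the individual stages.

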