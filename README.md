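# cdlr — cutoff-dose logistic regression for inner-ear NTCP modelling

`cdlr` models the probability of radiation-induced inner-ear toxicity
(tinnitus, hearing impairment) as a function of the dose each inner ear
receives during radio(chemo)therapy of nasopharyngeal carcinoma. It is
aimed at radiation-oncology outcome modellers who want to derive organ-at-risk
dose constraints from per-ear toxicity data, and at methodologists who want
to study how well such constraints can be recovered from cohorts of
realistic size.

## The model

The normal tissue complication probability (NTCP) of an inner ear is a
two-parameter logistic function of its dose `D` (Gy):

```
NTCP(D) = 1 / (1 + exp(-D·β + γ))
```

`β` (1/Gy) sets the steepness of the dose-response curve and `γ` its
offset. Derived quantities:

- **TDx** — the dose at which the modelled complication probability is `x`:
  `TDx = (γ + logit(x)) / β`. TD25 is the usual dose constraint; TD50 is
  the curve midpoint `γ/β`.
- **m** — the maximum slope of the sigmoid, attained at TD50; analytically
  `β/4`, computed here (as is conventional in NTCP reporting) by a
  numerical central difference.

Fitting works on binned data: per-ear observations (dose, binary toxicity
event) are grouped into 5-Gy half-open dose bins, each bin contributes its
observed incidence `events/total` at a representative dose, and `(β, γ)`
minimise the count-weighted least-squares objective

```
SSE(β, γ) = Σ_bins  n_bin · (incidence_bin − NTCP(dose_bin))²
```

via a deterministic grid-seeded quasi-Newton search. Because patient-level
cohorts of this kind are not publicly deposited, the package includes a
synthetic cohort generator that reproduces the study conditions (38
patients × 2 ears, mean doses uniform on 15–60 Gy, events drawn Bernoulli
from a true curve) so that the whole pipeline is testable end to end.

## Worked example

```python
from cdlr import (bin_observations, constraint_report, fit_cdlr,
                  simulate_cohort, study_like_defaults)

# published mean-dose curve: beta = 0.0517 / Gy, gamma = 3.3587
cfg = study_like_defaults("mean", seed=7)
report = constraint_report(cfg.true_params, doses=[45.0, 50.0])
print(report.summary())

# recover the curve from a synthetic cohort
obs = simulate_cohort(cfg)               # 76 per-ear observations
fit = fit_cdlr(bin_observations(obs, "mean"))
print(f"fitted TD50 = {fit.report.td50:.1f} Gy from {fit.n_bins} bins")
```

prints

```
TD25 = 44 Gy
TD50 = 65 Gy
m    = 0.013 per Gy
NTCP(45 Gy) = 26.3%
NTCP(50 Gy) = 31.6%
fitted TD50 = 71.5 Gy from 9 bins
```

i.e. keeping the mean inner-ear dose below 44 Gy limits the modelled
toxicity probability to 25%, the 45–50 Gy constraint range quoted elsewhere
in the literature corresponds to a 26–32% risk, and a single 76-ear cohort
recovers TD50 only to within several Gy — small cohorts carry substantial
sampling noise (the tests quantify this over hundreds of replicates).

The same pipeline is scriptable from a shell:

```sh
cdlr simulate --seed 7 --out cohort.csv
cdlr fit --input cohort.csv --fit-out fit.json --binned-out binned.csv
cdlr predict --params fit.json --prob 0.25
cdlr report --params fit.json --at 45 --at 50
```

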