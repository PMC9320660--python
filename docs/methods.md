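# Methods

## Model

The package implements cutoff-dose logistic regression (CDLR) for
normal-tissue complication probability (NTCP) of the inner ear. The
probability that an ear exposed to dose `D` (Gy) develops toxicity is

    NTCP(D) = 1 / (1 + exp(-D·β + γ)),

a logistic sigmoid with slope parameter `β` (1/Gy) and dimensionless offset
`γ`. The parametrisation is monotone increasing for `β > 0`, crosses 50% at
`TD50 = γ/β`, and is symmetric about that midpoint. Derived quantities:

- `TDx = (γ + logit(x)) / β` — the dose at complication probability `x`
  (closed-form inversion; TD25 is the conventional planning constraint);
- `m` — the slope at TD50 in probability per Gy. Analytically
  `m = β·p·(1−p)` at `p = 0.5`, i.e. `β/4`; it is computed by a central
  difference at TD50 (step 0.01 Gy by default), which agrees with `β/4` to
  better than 1e−6 while matching the numerical-derivative convention of
  the NTCP literature.

Assumptions inherited from the analysis design: each ear is an independent
observation (no within-patient correlation), toxicity is a single binary
endpoint with no time-to-event or severity structure, dose is a scalar
summary (mean or maximum organ dose) with no volume-effect or fractionation
correction, and chemotherapy ototoxicity is not modelled as a covariate.

## Fitting

Per-ear observations are grouped into half-open dose bins
`[anchor + k·w, anchor + (k+1)·w)` with width `w = 5` Gy and anchor 0 Gy by
default. Each non-empty bin contributes its incidence (events/total) at a
representative dose; empty bins are dropped — they would carry zero weight.
The representative dose is the bin midpoint by default; a `member_mean`
mode (mean of the member doses) exists because either convention is
defensible and the two differ for unevenly filled bins.

Parameters minimise the count-weighted least-squares objective

    SSE(β, γ) = Σ_i n_i · (p_i − NTCP(d_i; β, γ))²,

with `n_i` the bin totals. Incidences of exactly 0 or 1 enter as-is; the
fit is on the probability scale, not the logit scale, so no continuity
correction is needed. This binned WLS route is the estimator of record
here; a per-observation Bernoulli likelihood would weight the data
differently and is deliberately not the default.

Optimisation is deterministic: a vectorised 60×60 grid over
`β ∈ [0.001, 0.5]`, `γ ∈ [0, 20]` picks the best seed, L-BFGS-B with the
analytic gradient refines it (`β` floored at 1e−9 to keep the curve
monotone increasing), and a second refinement from a moment-style start
(`β₀ = 4·Δincidence/Δdose`, `γ₀ = β₀·median dose`) guards against the grid
box clipping an optimum; the better optimum wins. Convergence uses scipy's
L-BFGS-B criteria tightened to `ftol = 1e−14`, `gtol = 1e−12`;
non-convergence is flagged on the result, never silent. The test suite
checks the optimiser against an independent brute-force oracle (dense
200×200 grid plus Nelder-Mead polish) on randomly generated series.

## Numerical choices

- The sigmoid is evaluated through `scipy.special.expit`, which saturates
  gracefully instead of overflowing for extreme exponents. In IEEE double
  the value reaches exactly 0 or 1 once `|βD − γ|` exceeds ≈37; the strict
  open-range and inversion round-trip properties are therefore asserted on
  the non-saturated domain (round trips to 1e−9 relative where
  `p ∈ (1e−4, 1 − 1e−4)`; the tails are ill-conditioned for `logit`).
- Doses are reported to whole Gy and `m` to three decimals only at the
  display/serialization layer (`ConstraintReport.summary`, CLI output);
  every stored value keeps full double precision.
- Binned CSV output uses `%.17g` formatting and the incidence is recomputed
  from the counts on read-back, making the table round-trip exact.

## Synthetic cohorts

No patient-level dataset of this kind is publicly deposited, so the
generator produces cohorts with the statistical structure the analysis
assumes: `n_patients × ears_per_patient` ears, each dose drawn i.i.d. from
a uniform (default) or triangular distribution on a configured range, each
event Bernoulli with probability given by a true CDLR curve at that dose.
One RNG stream (`numpy.random.default_rng(seed)`) is consumed in a fixed
order — all doses, then all events — so a seed pins the cohort exactly.

`study_like_defaults` encodes the study conditions: 38 patients × 2 ears;
mean-dose metric uniform on 15–60 Gy with true `(β, γ) = (0.0517, 3.3587)`;
max-dose metric uniform on 30–75 Gy with `(0.0994, 6.8876)`. The uniform
default reflects that only the dose range, not the dose histogram, is
known. Under the mean-dose defaults the expected event rate — the average
of the true curve over the dose range — is 0.215, close to the ~24% crude
toxicity rate reported for such cohorts.

What the generator does **not** emulate: within-patient correlation between
ears (ears are sampled independently, matching an analysis that treats them
as separate data points), chemotherapy covariates, toxicity grades, or
censoring/follow-up structure. Passing recovery tests therefore show that
the estimator is correct under its own assumptions — not that real cohorts,
where ears within a patient are correlated and doses cluster, would yield
equally tight estimates.

## Problem sizes in the tests

Scientific checks use sizes chosen for statistical soundness: optimizer
oracle comparisons on 20 random small series; parameter recovery on 200
replicate cohorts of 2,000 ears (uniform 15–75 Gy so both curve tails are
sampled) plus 10 replicates of 20,000 ears for the bias check; generator
calibration on 500,000 ears, where the per-bin binomial standard error
(≈0.002) is well inside the ±0.01 assertion band — at a few tens of
thousands of ears that band would sit at ~1.6σ and fail by chance for a
large fraction of seeds.

## Known limitations

- The maximum-dose slope is reported as `m = β/4 = 0.0248 ≈ 0.025`. One
  published tabulation lists 0.02845 for this curve, which is inconsistent
  with its own `β` under the analytic identity (and with the accompanying
  text); the package follows the identity.
- Binned WLS discards within-bin dose variation; with 5-Gy bins and ~76
  ears, TD50 estimates from single study-sized cohorts scatter by several
  Gy (quantified in the recovery tests).
- No confidence intervals for `(β, γ)` are produced — the estimator of
  record reports point estimates only, and resampling uncertainty is out of
  scope here.
- `β = 0` (a flat curve) has no invertible dose-response; `tdx` and
  constraint derivation reject it rather than extrapolating.
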