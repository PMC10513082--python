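# Methods

This note documents the models implemented in `glp1ce`, the defaults chosen
where the design was genuinely open, and what the synthetic inputs do and do
not establish about real data.

## Parameter uncertainty model

Each parameter carries a family (gamma / beta / normal / fixed), a mean and
a range. The range is interpreted as a central 95% interval. Fitting matches
the mean exactly and chooses the remaining free shape parameter (gamma
shape, beta concentration, normal SD) to minimise the squared distance
between the fitted 2.5%/97.5% quantiles and the stated range. Several
published ranges pin the mean to an endpoint (negotiated drug prices whose
list price is the upper bound); the least-squares rule still yields a
usable distribution with the mean exact, which we prefer over rejecting the
row. Degenerate ranges (low = mean = high, and beta means of exactly 0
or 1) become point masses. PSA draws are jointly independent across
parameters — no correlation structure is imposed — and are reproducible
from `(seed, draw_index)` via independent `SeedSequence` spawns.

All monetary values are stored in USD (the source table was converted at
6.693 CNY/USD); the exchange rate is retained as metadata only.

## Risk engine

Twelve complication outcomes (MI, IHD, heart failure, stroke, PVD,
neuropathy, amputation, skin ulcer, renal failure, cataract, retinopathy,
and all-cause mortality) are modelled as one logistic-link equation per
outcome evaluated once per one-year cycle; risk-factor progression is a
deterministic annual drift. The true coefficient values of the validated
Chinese outcomes model this engine is shaped after are not publicly
printed, so the packaged defaults are *calibrated synthetic stand-ins*
produced by `glp1ce.synthetic.gen_risk_coefficients`: slope signs are fixed
a priori (risk increasing in age, HbA1c, blood pressure, smoking, prior
disease; renal risk decreasing in eGFR) and the intercept is solved in
closed form so the annual probability at a reference patient (age 55,
HbA1c 8.5%, BMI 26.5) equals a stated calibration target. Default targets
(e.g. MI 0.006/yr, stroke 0.010/yr, cataract 0.012/yr, mortality 0.010/yr)
were chosen once as realistic magnitudes for a middle-aged Chinese T2DM
cohort, at the scale of the baseline prevalences in the parameter table.
Any coefficient file in the documented JSON schema can be substituted.

Mortality is blended with a sex-by-age life table as
`max(p_model, q_natural)` — the natural-mortality floor reading of
"adjusted using population natural mortality"; an additive-hazards
alternative is exposed via `blending="additive"`. The packaged life table
is Gompertz–Makeham (`h(a) = 4e-4 + 2.2e-5·exp(0.092·a)`, female hazard
×0.55), deterministic, monotone from age 30, ages 18–100 with the terminal
row reused beyond; any `(sex, age, qx)` CSV can replace it.

Progression defaults: HbA1c +0.10 %/yr, BMI +0.05 kg/m²/yr, SBP
+0.50 mmHg/yr, DBP +0.20 mmHg/yr — a mild secular deterioration typical of
published diabetes models. Baseline covariates are sampled independently
(the source reports marginals only).

## Microsimulation conventions

* One-year cycles; within a cycle the order is death draw first, then
  macrovascular, then microvascular events, then accrual. Dying patients
  accrue that cycle (it counts as a life-year, with treatment cost and
  utility) plus the end-of-life cost; they fire no complication events.
* Chronic comorbidity flags are absorbing; severe hypoglycaemia recurs
  per-cycle (annual incidence 0.01 from year two; the first year uses the
  arm's trial adverse-event profile instead, to avoid double counting).
* The 6-month treatment effect is applied at initiation as
  `x ← x·(1 + change rate)` per endpoint. After the start of year six all
  arms switch to insulin glargine 8 IU/day: GLP-1RA and metformin costs
  stop, insulin plus a duration-banded antidiabetic-therapy cost
  (438.3 USD/yr for 5–10 years' duration, 657.45 beyond) begin. Risk
  factors then follow natural progression with no renewed treatment effect.
* Drug costing: pack price ÷ pack content × dose, titration steps costed
  at their own dose (e.g. exenatide 5 µg bid for 4 weeks; weekly drugs use
  52 weeks/yr, daily drugs 365 days/yr). The lixisenatide pen is costed as
  14 × 20 µg doses per pack, matching the marketed presentation.
* Adverse events (rates > 5%, plus hypoglycaemia) apply in the first
  treatment year only: each fired event subtracts the grade-1/2 disutility
  (hypoglycaemia its own disutility and per-event cost). No AE treatment
  cost is priced for non-hypoglycaemia events because none is published.
* Utility per cycle: `1 − 0.06 (uncomplicated T2DM) − active comorbidity
  decrements (event-year vs post-event values) − AE decrements − BMI term`,
  floored at 0. The BMI term is anchored at the patient's own baseline:
  −0.05/unit above it, +0.02/unit below it (the gain sign is
  flag-controlled, as the source is ambiguous about the direction of the
  per-unit-decrease entry).
* Discounting is end-of-cycle: value_t/(1+r)^t with t starting at 1, no
  half-cycle correction; r defaults to 0.05 and is itself a parameter
  (`Discount`), so the tornado analysis can evaluate it at 0 and 0.08.
* Lifetime horizon = simulation to age 110 (death forced at the cap);
  truncated horizons censor survivors and flag them.
* Common random numbers: 14 purpose-keyed streams (death, one per event,
  hypoglycaemia, adverse events) drawn in fixed shape and order every
  cycle for every patient, alive or dead, so arms with identical
  parameters are bit-identical and paired differences isolate treatment
  effects.

## Network meta-analysis

Arm-based normal likelihood with study baselines `mu_i`, basic parameters
`d_t` (reference fixed at 0) and heterogeneity `tau`; random effects use
the standard multi-arm covariance (tau², off-diagonal tau²/2) marginalised
into a per-study multivariate normal. Priors: N(0, 100²) on `mu` and `d`,
U(0, 5) on `tau`. The sampler is single-site random-walk Metropolis with
per-parameter step adaptation during burn-in targeting ~40% acceptance;
chains are independent by seed. Split-chain R-hat is reported per
parameter and any value above 1.05 flags the result as non-converged
(never silently accepted). Full-scale settings are 4 chains × 50,000 kept
after 10,000 burn-in; the tests and the acceptance script use 4 × 4,000
after 2,000, which converges (R-hat < 1.03) on the packaged nine-trial
network in a few seconds.

Endpoint scale: change rates of HbA1c/BMI/SBP/DBP are negative for active
treatment, so the default models mean *differences* of change rates; a
`log_ratio` scale is available for strictly positive data. Trials missing
an SD would be imputed from the endpoint's median SD across trials and
flagged; the synthetic datasets always carry SDs.

Consistency: the global design-by-treatment interaction test is a
frequentist weighted-least-squares Q decomposition (consistency model vs
design-specific effects; df = rank difference; I² = max(0, (Q−df)/Q)·100).
Node-splitting adds an offset parameter to the direct-evidence studies'
relative effect for the split comparison; its posterior is the
direct-minus-indirect difference and a two-sided posterior tail probability
is the p-value. Splitting requires both direct evidence and an indirect
path after removing the direct trials.

NMA outputs convert to per-arm absolute change rates by anchoring on a
reference arm's observed trial rate: `rate_arm = rate_ref + (d_arm −
d_ref)`. In the PSA, per-arm effects are drawn from normal distributions
(posterior mean, posterior SD or a configured SD).

## Decision analysis

NMB = λ·QALY − cost with λ = USD 12,728/QALY (per-capita-GDP threshold).
INMB between arms is the mean of *paired* per-patient NMB differences
(possible because of common random numbers) with a 2,000-resample
percentile bootstrap CI. ICERs carry dominance verdicts and are flagged
unstable when |ΔQALY| < 10⁻³ — with six near-equivalent regimens the ratio
is uninformative and INMB is the primary metric. The PSA nests a reduced
per-iteration cohort (default 1,000; tests use 100–200) under one joint
parameter draw plus one effect draw per iteration, simulating all arms
with the same simulation seed so within-iteration comparisons remain
paired. CEAC probabilities are the fraction of iterations in which each
arm attains the highest NMB, exact ties split uniformly; the default WTP
grid is 0–40,000 USD in steps of 400. The tornado analysis re-simulates
both arms at each parameter's low and high bound with common random
numbers fixed, reporting the top 10 by INMB range.

## Burden GLM

IRLS with gaussian/identity and gamma/log families (convergence: relative
deviance change < 1e-8 or 100 iterations; gaussian-identity reproduces the
normal-equations solution exactly). Exposures are HbA1c > 7% and
BMI > 25 kg/m² evaluated at the post-treatment (6-month) level — at
baseline essentially the whole cohort exceeds the HbA1c cut, so the
dichotomy is only informative after treatment effects. Covariates default
to the baseline characteristics (age, sex, blood pressure, duration,
cardiovascular history) minus the exposures, plus arm indicators when arms
are pooled; constant columns are dropped. Effects are reported as average
marginal effects on the outcome scale with delta-method SEs, so the
dollars-and-QALYs summary does not depend on the link.

## Problem sizes

Defaults mirror the full design (30,000-patient cohort, 50,000 PSA
iterations, 4 × 50,000-sample chains). The test-suite and acceptance-script
sizes — cohorts of 100–10,000, 100–500 PSA iterations, 4 × 4,000-sample
chains — were chosen so the full verification cycle completes in about a
minute while every property examined (recovery within Monte-Carlo error,
normalisation, determinism, closed-form identities) is scale-invariant.

## What the synthetic inputs do and do not show

The synthetic generators preserve the *structure* of the real inputs —
network topology and arm sizes of the nine trials, logistic risk equations
with signed gradients, Gompertz-like adult mortality, cost-like skewed
outcomes — with known ground truth, so passing tests demonstrate that the
estimators recover what generated the data (NMA contrasts, GLM effects),
that the simulator obeys its closed-form limits, and that the pipeline is
deterministic. They do not demonstrate calibration to real Chinese T2DM
epidemiology: absolute life expectancy, QALY levels and PSA win
probabilities depend on the unpublished risk-equation coefficients and
census life table, and will shift when real coefficient files are
substituted. Published-table arithmetic (breakdown sums, the NMB identity)
is checked directly against the shipped reference values.

## Known limitations

* Within-year event timing is not modelled (annual cycles, no
  continuous-time discrete events), and there is no adherence or
  discontinuation model.
* Baseline covariates and PSA parameters are drawn independently; real
  correlation (e.g. age with SBP) is not represented.
* The one-way sensitivity analysis varies one parameter at a time; for
  transition probabilities only effect-scale parameters are varied.
* Node-splitting assumes the direct evidence enters through two-arm
  studies (true of the packaged network).
* Gamma GLM marginal-effect SEs use the delta method, which can be
  optimistic in small samples.
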