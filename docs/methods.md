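# Methods

## Decision problem and model structure

The model compares two mutually exclusive strategies for a severe
thalassemia patient aged 1–28 at treatment start: allogeneic HSCT (with
a related or an unrelated donor, analysed separately against the
comparator, never head-to-head) and lifelong blood transfusion with
subcutaneous iron chelation (BT-ICT).  It is a five-state cohort Markov
model with one-year cycles and a 99-year horizon: HSCT year 1, HSCT
year 2, post-HSCT, BT-ICT, dead.  A transplant cohort enters HSCT year
1; the comparator cohort enters BT-ICT.  Graft failure routes to BT-ICT
permanently (`max_transplants=1`, the default) or to one repeat
transplant with a reset clock and full first-year payoffs
(`max_transplants=2`).  Death is absorbing with zero payoffs.

## Transition probabilities

Transplant-state mortality and graft failure follow two Weibull
proportional-hazards regressions: `H(t) = λ t^γ` with `t` in days,
`λ = exp(constant + coef·x)`, `γ = exp(ancillary)`.  The death model's
covariate is age at treatment start in years (coefficient 0.16/year);
the failure model's is donor type coded related = 0 / unrelated = 1
(coefficient +2.60, so the constant is the related-donor baseline).
Storing the shape as its log follows the convention of the survival
software family these coefficients come from; exponentiation guarantees
γ > 0.  Both fitted shapes are below one (exp(−0.61), exp(−0.74)):
hazards are front-loaded in the first years after transplant.

Per-cycle probabilities are cumulative-hazard increments
`tp(u) = 1 − exp{H(t−u) − H(t)}` with `u = 365` days and `t` the time
since the (most recent) transplant at the end of the cycle.  Within a
cycle death is resolved first and failure applies to survivors, which
conserves probability mass exactly; at these hazard levels the ordering
effect is second-order and is covered by the microsimulation
cross-check.

BT-ICT mortality uses published annual probabilities by attained age
band (0–1: 0.010, 2–5: 0.003, 6–10: 0.002, 11–15: 0.010, 16–20: 0.025,
21–30: 0.015, 31+: 0.345), with integer ages, inclusive upper bounds
and the last band extended indefinitely.  Graft failures adopt BT-ICT
mortality, costs and utility from the cycle after failure.

### Background mortality for cured patients

With the fitted shapes below one, the transplant death hazard decays,
and extrapolating it alone over 99 years leaves about 90% of an age-1
cohort alive at the horizon — a cured cohort would effectively never
die, and transplantation would never be dominated at any starting age,
contradicting the published dominance pattern (related HSCT dominated
from age 20, unrelated from 18).  The engine therefore gives post-HSCT
occupants the BT-ICT age-band probability as a competing risk on top of
the Weibull hazard (`background_mortality="post_hsct"`, the default);
`"none"` restores the pure-Weibull structure.  With the default the
model reproduces both published dominance flip ages exactly and most of
the published ICER table.  Using the thalassemia band table (rather
than a general-population life table) for cured patients is
conservative for ages 31+, where the band value (0.345/year) reflects
end-stage transfusion-dependent disease; this is the main structural
uncertainty of the reconstruction and the chief reason the youngest-age
related-donor ICER reconstructs below its published value (about
53,000 vs 80,700 THB/QALY; both sides of the 100,000 THB/QALY
threshold agree).  The published incremental columns imply a
post-transplant survival curve between the two structures that cannot
be recovered from the printed coefficients alone.

## Payoffs

Per-cycle state costs (2008 THB) and utilities, societal perspective:

| state       | direct medical      | non-medical + productivity       | utility |
|-------------|---------------------|----------------------------------|---------|
| HSCT year 1 | 491,985 (rel) / 735,839 (unr) | split share of 259,994 + 77,468 | 0.61 |
| HSCT year 2 | 42,694 / 45,840     | remaining share of the same totals | 0.61 |
| post-HSCT   | 11,638 / 6,385      | 37,384 + 19,171 (BT-ICT level)   | 0.93 |
| BT-ICT      | 35,788              | 37,384 + 19,171                  | 0.61 |

The survey totals for transplant non-medical and productivity costs
cover years 1–2 jointly; they are split 50/50 between the two years by
default (`hsct_year12_cost_split`, configurable 0–1; the split has a
small effect because the two years are adjacent in discounting).  The
governmental perspective zeroes the non-medical and productivity
columns.  Payoffs accrue at cycle start (occupancy before transitions),
the spreadsheet-model convention; a half-cycle option exists for
sensitivity analysis but mis-weights the one-cycle tunnel states and is
not the default.  Discounting is `(1+r)^−(k−1)` with r = 3%/year for
both costs and outcomes (range 0–6% in one-way analysis, fixed in PSA
because no SE is published for it).

## Parameter uncertainty

Each input is `(family, mean, SE)`; PSA draws are independent across
parameters, moment-matched: beta (α = m(m(1−m)/se² − 1), β = (1−m)(…))
for utilities and probabilities; gamma (shape = (m/se)², scale = se²/m)
for costs; normal on the coefficient's own scale for the six survival
parameters (equivalently lognormal on the hazard-ratio scale).  Age-band
death probabilities are published without SEs and are held fixed in the
PSA (±25% in one-way analysis).  Both arms are evaluated with the same
draw (common random parameters), since the propagated uncertainty is
parametric, not stochastic.

Independent sampling with the published marginal SEs (the constant's SE
is 2.00 on the log-hazard scale, the donor coefficient's 1.08)
overstates the joint uncertainty of a fitted regression, whose
coefficients are strongly correlated; the fit covariance is not
published.  The acceptability probabilities this package computes for a
one-year-old related transplant (≈58% at 100,000 THB/QALY, ≈66% at
300,000, at 1,000 iterations) are therefore lower than the published
81%/96%, while the qualitative result — acceptability declining
strictly with starting age — holds.  Anyone with access to the original
fit covariance could sample multivariate-normally instead and would
obtain tighter curves.

## Budget impact

Stacked incident cohorts: each fiscal year 2008–2022 adds 200 patients
(entry ages 1–10, uniform weights by default, configurable), all of
whom either continue BT-ICT or receive a related transplant.  Only
direct medical costs count.  A fiscal year's expenditure sums each
living cohort's current-cycle cost from the cohort engine — so the
transplant column automatically contains first-year transplants for the
incoming cohort, follow-up costs for earlier cohorts and transfusion
care for graft failures — and is discounted to 2008 by `(1.03)^−j`.
The incoming cohort always incurs its full first-cycle treatment cost
(therapy starts before any within-year death), which the cycle-start
accrual provides automatically.  Reconstructed table: first row
(7, 98, 91) million THB, initial incremental ≈ 90 million/year,
15-year totals 640 / 1,459 / 820 million (published: 647 / 1,468 /
821).

## Synthetic registry and fitting

The generator emulates the registry behind the survival models: 44
related and 23 unrelated transplants, integer ages uniform on 1–28
(the real distribution beyond mean 8 and range 1–28 is unknown, so the
distribution is a parameter), independent latent death and failure
times drawn by inverse transform `T = (−ln U/λ)^{1/γ}` from the two
Weibull models at their published means, administrative censoring at a
fixed 18-year horizon (the length of the accrual window; staggered
entry uniform over the window is available behind a flag).  What it
does not emulate: genotype subgroups, correlated risks or frailty,
staggered calendar entry by default — so passing recovery tests show
the fitter and pipeline are correct under the model's own assumptions,
not that the published coefficients are right for the real cohort.

The Weibull fitter maximizes the right-censored PH log-likelihood
(BFGS from a crude-rate start: constant = log(events/person-days),
coefficients 0, ancillary 0) with SEs from the numerical observed
information.  Competing events are treated as censored, matching the
two cause-specific fits.  It is cross-checked in the tests against an
independent AFT implementation via the AFT→PH reparameterization
(β_PH = −ρ·β_AFT, γ = ρ).  At n = 5,000 all six coefficients are
recovered within 3 SE; over 200 replicates at the registry's n = 67
the 95% Wald intervals cover each truth at 92–98% (slightly
conservative for the weakly identified donor coefficient, whose SE is
large at 23 unrelated patients).

## Numerical conventions

* Occupancy is conserved to 10⁻¹⁰ per cycle (hard error beyond 10⁻⁸).
* The per-cycle probabilities telescope: survivor-weighted tp summed
  over cycles equals 1 − S(T) to 10⁻¹² (tested).
* The cohort engine agrees with a 10⁶-individual microsimulation using
  the same per-cycle probabilities within 3 Monte Carlo SEs (tested).
* ICERs are reported raw; table output rounds to three significant
  figures.  Dominance verdicts: dominated ⇔ ΔC > 0 and ΔQ ≤ 0;
  dominant ⇔ ΔC ≤ 0 and ΔQ > 0; the south-west quadrant (including the
  null comparison) is labelled cost-saving with no ratio.
* CEAC ties (incremental NMB exactly zero) count as not cost-effective.
* All randomness flows through `numpy.random.Generator` seeds;
  identical seeds give bit-identical draws, PSA results and CLI output
  files.

## Problem sizes

Defaults used by the test suite and the acceptance script: 99-cycle
horizon; 1,000 PSA iterations; 10⁶ individuals in the microsimulation
cross-check; 5,000 patients for point recovery and 200 replicates of 67
for coverage; 15 fiscal years × 10 entry ages in the budget model.

## Known limitations

* The post-transplant background-mortality structure is a
  reconstruction choice (see above); the published point values imply
  an intermediate structure that the printed inputs cannot pin down.
* PSA dispersion is overstated absent the survival-fit covariance.
* No treatment-complication sub-states (complications are folded into
  state payoffs), no genotype heterogeneity, no alternative survival
  families, no extended dominance across three strategies, and no
  price-trend scenarios in the budget model.
* Currency is 2008 THB throughout; the PPP conversion (15.954 THB per
  PPP$) is a reporting convenience in the CLI only.
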