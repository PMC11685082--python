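# Methods

## Decision problem and model structure

Three first-line strategies for extensive-stage small cell lung cancer are
compared for a cohort starting at age 62: benmelstobart + anlotinib + EC,
anlotinib + EC, and EC alone (etoposide + carboplatin, four 21-day cycles in
every arm; benmelstobart and anlotinib continue until progression). Health
states are progression-free (PFS), progressive disease (PD), and death; the
cycle length is 21 days (one chemotherapy cycle) and the horizon 10 years
(174 cycles), by which time nearly the whole cohort has died.

Transition probabilities are time-varying and derived from extrapolated OS
and PFS curves:

- p(death, t) = max(1 − S_OS(t+1)/S_OS(t), background mortality at the
  cohort's current age), with the background per-cycle probability
  1 − (1 − q_annual)^(21/365.25) taken from an age-indexed life table;
- p(leave PFS, t) = 1 − S_PFS(t+1)/S_PFS(t);
- p(PFS→PD, t) = max(0, p(leave PFS) − p(death)).

The death hazard is applied identically from PFS and PD. With only arm-level
OS available there is no information to split post-progression mortality,
and this choice makes the cohort trace reproduce partitioned-survival state
membership exactly (PFS occupancy = S_PFS, alive = S_OS) whenever the
background floor does not bind — which is verified to 1e-9 in the tests. The
floor is applied per-arm; both the floor and the tunnel mechanics are module
options.

PD is subdivided into tunnel compartments indexed by cycles since
progression (35 compartments ≈ 24 months at 21 days/cycle, then a pooled
compartment), so costs that depend on time in PD can be attached exactly.
State membership used for accumulation is the average of cycle-start and
cycle-end occupancy (the life-table / half-cycle correction); one-off costs
(adverse events, end-of-life) attach to full transition counts instead.

## Survival reconstruction and extrapolation

Digitized KM step coordinates plus the number-at-risk table are converted to
pseudo individual-patient data by the Guyot iterative algorithm: within each
inter-risk-time interval a censoring total is proposed from the survival
drop, censor times are spread uniformly, per-step event counts are solved
from the KM ratios (rounded to integers with the fractional remainder
carried forward so cumulative events are preserved), and the censoring total
is adjusted until the implied number at risk matches the reported one. When
a reported total event count is available it pins the final interval; when
no risk table beyond baseline exists the fallback assumes no censoring
before last follow-up. Reconstruction is deterministic. Accuracy is limited
by the uniform-censoring assumption: with only administrative censoring the
round trip is exact; with interior dropout the error is on the order of one
event per late at-risk count (max |ΔS| ≈ 0.01 at n = 200, ≈ 0.008 at
n = 500 under 0.004 digitization noise).

Fourteen model families share one right-censored log-likelihood
Σ d·log f + (1−d)·log S, maximized by multi-start Nelder-Mead/BFGS chains
with a fixed jitter seed, so AIC = 2k − 2ℓ and BIC = k·ln n − 2ℓ are
comparable across the suite. Families without a closed-form likelihood:

- **Royston-Parmar**: a restricted cubic spline s(x) in x = log t models
  log H(t) (hazard scale), log[S⁻¹ − 1] (odds scale) or −Φ⁻¹(S) (probit
  scale). Boundary knots sit at the extreme log event times, internal knots
  at event-time quantiles; the internal-knot count is chosen from {1, 2, 3}
  by AIC (0 can be forced, recovering Weibull / log-logistic / log-normal
  exactly — a tested identity). Non-monotone spline candidates get −∞
  likelihood; starting values come from regressing the transformed KM
  estimate on the basis.
- **Fractional polynomials** (FP1/FP2) and **RCS** put the polynomial/spline
  on the log hazard; H(t) is accumulated by trapezoid on a 600-point
  log-spaced grid refined with the observation times, with the hazard
  treated as flat below the smallest grid point (t_min/50). FP powers come
  from the standard set {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (power 0 ↦ log t,
  a repeated power multiplies by log t); the best single power / pair is
  selected by AIC with the time axis rescaled by the median event time for
  conditioning. FP beta coefficients are counted as parameters; the power
  choice is not.
- **Mixture cure**: S(t) = π + (1−π)·S_u(t) with a configurable standard
  uncured family (default Weibull) and logit-parameterized π.

The generalized additive model family is out of scope (it was never selected
for any endpoint and would import penalized-smoothing machinery
disproportionate to its role). Automated selection is by AIC with BIC ranks
reported alongside; the visual plausibility check of extrapolations remains
a human step, which is why every selection table is exported.

Where independently fitted OS and PFS tails cross, evaluation clips
S_PFS := min(S_PFS, S_OS) pointwise, since the state partition requires
progression-free ⊆ alive. Scenario OS curves can be generated from a
reference arm under proportional hazards, S^HR.

## Costs, utilities, discounting

All costs are 2024 USD (7.13 RMB/USD). Per cycle and per cohort member:

- **PFS drugs**: EC backbone (325.67 + 65.87) cycles 1-4 only; benmelstobart
  3444.60 and/or anlotinib 403.46 every cycle while progression-free.
- **PD drugs**: mix-weighted per-cycle category costs (radiotherapy 26.33,
  topotecan 77.36, anlotinib 403.46, pembrolizumab 5026.09, best supportive
  care 332.85) with arm-specific category proportions; the immunotherapy
  fraction switches to best-supportive cost after 35 cycles (~24 months) in
  PD, implemented through the tunnel compartments.
- **Adverse events** (grade ≥ 3, incidence ≥ 5%): one-off incidence-weighted
  cost and disutility applied to the full cohort in cycle 1; a scenario
  re-applies them to each cohort fraction entering PD.
- **Follow-up**: 399.54 (laboratory) + 168.07 (imaging) per visit, prorated
  per cycle by the guideline visit interval (2 months in year 1, 3 months in
  years 2-3, 6 months in years 4-5, annual beyond).
- **End of life**: 7985.90 lump sum at the death transition (the last-three-
  months weighting is already inside that input).

Utilities are 0.84 (PFS) and 0.473 (PD), multiplied by (1 + uplift rate)
per arm (0.0471 / 0.0341 / 0.0190) up to a cutoff of 2 years — the uplift
reflects the observed EQ-VAS improvement on treatment, and the cutoff is a
configurable package default since no numeric trial cutoff is published —
and unadjusted after. Both streams discount at 5%/year evaluated at cycle
midpoints, pairing naturally with the half-cycle membership correction.
Life years are undiscounted by default (configurable). The one-off AE block
reproduces the published per-arm AE totals within 0.5%; the residual ~0.3%
is rounding in the source table.

## Uncertainty analysis

Every parameter carries (base, low, high, distribution). The PSA samples
costs from gamma and probabilities/utilities from beta distributions with
mean = base and sd = (high − low)/3.92, i.e. the printed range is read as a
95% interval; beta distributions are rescaled to [low, high], which also
accommodates negative disutilities. Degenerate ranges give point masses;
infeasible moments (one bundled disutility has base = bound) fall back to
uniform(low, high) with a warning. Draws pass through a Gaussian copula:
rank correlation 0.9 among the three uplift rates, −0.9 between the
chemotherapy and best-supportive proportions within each arm, everything
else independent; sampled mixes are renormalized to the simplex. Survival
fits are held fixed across PSA draws (curve-coefficient uncertainty is not
sampled by default). Acceptability is reported both pairwise versus EC
(P[incremental NMB > 0]) and by the winner rule (P[highest NMB], summing to
1 across strategies).

The tornado analysis varies one parameter at a time to its bounds and sorts
by ICER bar width. The price-threshold search bisects a drug's price
multiplier in [0, 1] to |ICER − WTP| < 1 USD/QALY, reporting 0% reduction
(flagged) when the comparison is already cost-effective at full price.

## Synthetic trial generator

The generator emulates the study conditions of the emulated trial: three
arms of 246/245/247 patients, Weibull event-time truths calibrated to the
published medians (OS 19.3 / 13.3 / 11.9, PFS 6.9 / 5.6 / 4.2 months;
shapes 1.3 for OS and 1.6 for PFS, reflecting the rising hazard of
ES-SCLC), exponential dropout at 4e-4/day plus administrative censoring at
30 months — leaving OS maturity above 60% and PFS above 80%, as reported
for the real trial. Ordering PFS ≤ OS holds per patient by construction:
progression time is drawn from the PFS marginal and OS = progression +
exponential post-progression survival whose rate is solved numerically so
the marginal OS median matches the target (a `min`-coupling fallback
exists). Digitization evaluates the KM estimate on a configurable grid with
optional uniform reading noise ≤ 0.005, clipped and re-monotonized.

What the generator does **not** emulate: covariates and subgroup structure,
accrual over calendar time, informative censoring, and the exact shape of
the real trial's hazards (only medians are matched). Passing tests
therefore demonstrate that the pipeline recovers known truths under
realistic trial geometry — not that the published absolute totals are
reproduced, which would require the undeposited trial curves. Arm
differences of ~1.4 months in median OS are within sampling noise at these
sample sizes, so seed-to-seed variability in the anlotinib-vs-EC ICER is
expected and real.

## Numerical choices and problem sizes

- Days internally; 30.4375 days/month; n_cycles = ceil(years·365.25/21).
- Optimizer: Nelder-Mead chained into BFGS from deterministic multi-starts;
  convergence 1e-8 (gradient) / 1e-10 (simplex).
- Guyot iteration cap 60 per interval; residual at-risk mismatch ≥ 2 raises
  a diagnostic naming the interval.
- Bisection: 100 iterations max, 1 USD/QALY tolerance.
- The automated pipeline default fits the seven standard families plus the
  three Royston-Parmar scales (FP/RCS/MCM/gengamma are available through the
  API and tested, but excluded from the default loop where their runtime
  buys little for AIC selection on these data).
- Test problem sizes: recovery suites use n = 1000 with 5 seeds; round-trip
  fixtures n = 200-500; the shared end-to-end fixture fits a reduced
  two-family list; the PSA machinery is checked at n = 10,000 draws.

## Known limitations

- The published analysis' absolute Table totals are not reproducible
  without the original digitized curves; only arithmetic identities among
  published numbers and qualitative decision patterns are asserted.
- The bundled life table is a synthetic Gompertz approximation to China
  2022 rates, adequate because the disease hazard dominates background
  mortality at every age the cohort reaches; any real life table can be
  supplied as CSV.
- The uniform-censoring assumption bounds reconstruction fidelity at small
  at-risk counts (see above).
- Half-cycle averaging smears tunnel-compartment boundaries by half a
  cycle, so the 24-month immunotherapy cap is soft by one half-cycle.
- FP models with strongly negative powers have non-integrable hazards near
  t = 0; the flat-below-grid approximation penalizes but does not formally
  exclude them.
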