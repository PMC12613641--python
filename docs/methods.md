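# Methods

This note documents the statistical machinery of `vaptrials`: the models,
the numerical choices behind them, the calibration of the synthetic data,
and what the package's validation does and does not establish.

## Trial setting and assumptions

All designs address a parallel-group, two-arm, 1:1-randomised superiority
trial whose endpoint is time from the start of the at-risk period (48 h of
invasive ventilation) to VAP onset, administratively censored at 28 days
("one month") of follow-up.  Throughout: one-sided type-I error
α = 0.025, target power 0.80 (0.90 is supported by argument), proportional
hazards, no dropouts, no competing risks.  A benefit (hazard ratio
HR < 1) maps to a positive z-statistic.

Scenario hazard ratios derive from the 28-day cumulative incidence in the
control arm, `p_SoC = 0.155`, and a relative reduction `r` via the
complementary-log-log relation `HR = ln(1 − p_SoC(1−r)) / ln(1 − p_SoC)`.
The package's scenario grid carries both the exact value and the 2-decimal
presentation value; sizing computations use the 2-dp value (0.79, 0.73,
0.68, 0.63, 0.58), which is the convention of the tables this package's
defaults emulate.

## Group sequential designs

**Information scale.**  Information fraction means fraction of the
maximum number of events; analyses are event-driven, not calendar-driven.
With 1:1 allocation the Fisher information at `n` events is `n/4`, and the
drift of the z-statistic is `−ln(HR)·√(n/4)`.

**Spending functions.**  Lan-DeMets forms for total error `e`:
O'Brien-Fleming-type `f(t) = 2(1 − Φ(Φ⁻¹(1 − e/2)/√t))` and Pocock-type
`f(t) = e·ln(1 + (e−1)·t)` (with Euler's e), used for both α and β.
These are the standard forms of the error-spending literature and of
mainstream trial-design software; they are validated end-to-end by the
operating characteristics they imply (e.g. 41%/11% interim efficacy and
futility stopping for the optimal one-interim OBF design).

**Boundary construction.**  Efficacy boundaries solve the α-spending
increments under the null *ignoring futility* (the non-binding
convention).  Futility boundaries solve the β-spending increments under
the design alternative with the efficacy boundaries in place; the final
futility bound is forced equal to the final efficacy bound, and an interim
futility bound is capped at the efficacy bound when the requested
increment cannot be spent.  Joint stage-wise probabilities come from the
canonical multivariate normal distribution of sequential z-statistics
(`corr = √(t_j/t_k)`) evaluated by Armitage sub-density recursion:
the continuation density is propagated on 301 Gauss-Legendre nodes per
stage over each continuation interval, truncated at ±8 around the stage
mean; boundary values are solved by bracketed Brent iteration to 1e−9.
The implementation is incremental (the committed sub-density is reused
across root-solve iterations), which keeps a ten-analysis design solve
under a second.  Cross-checks: cumulative boundary crossing under the null
matches the spending function to <1e−6, and a 10⁶-draw correlated-normal
Monte-Carlo oracle reproduces the type-I error within 3 standard errors.

**Sizing.**  Although futility is non-binding for α, the design is sized
with futility stops *enforced*, because the designs evaluated here always
stop on a futility crossing: the maximum event count is the smallest
integer whose rejection probability under the design HR — with both
boundary families active — reaches the target power.  The β-spending
bounds are re-solved at each candidate drift, so sizing is a
one-dimensional root solve in the drift.  Per-stage cumulative targets are
`ceil(t_k · n_max)`; event counts are rounded up only at the end of each
calculation chain.

**Expected events and interim timing.**  `E[n] = Σᵢ pᵢ·nᵢ` over all exit
stages (efficacy, futility, final).  The optimal single-interim timing
minimises `E[n]` under the design alternative over a grid (default 1%
steps on [0.05, 0.95], earlier fraction wins ties); the expected-events
curve is extremely flat near its minimum (the 64% and 65% points differ by
~0.002 events for the OBF design), so the grid convention is part of the
design definition, and the integration accuracy (≈1e−6) genuinely matters
for resolving the minimiser.

## Event-time model and patients

VAP onset follows a piecewise-exponential hazard with knots at days
{3, 7, 14, 28}.  The default calibration uses two free rates — one on
(0, 3], one shared by the later intervals — solved in closed form so that
the 28-day cumulative incidence is 0.155 and the median onset among
patients with an event is exactly 3 days (`F(3) = F(28)/2`):
`r₁ = −ln(1 − F₂₈/2)/3 ≈ 0.0269`, `r₂ = (−ln(1 − F₂₈) − 3r₁)/25 ≈ 0.0035`
per day.  With two parameters only those two summaries are matched; the
implied onset inter-quartile range (≈1.5–15 days) is wider than the
observed 1–6 days, so the model under-represents how front-loaded real
onsets are.  This affects look *timing* in calendar terms but not the
event-count-driven operating characteristics.

Intervention-arm event times use the HR-scaled hazard, equivalent to
`F_Inv(t) = 1 − (1 − F_SoC(t))^HR`, which reproduces the scenario grid's
intervention incidences exactly for the exact hazard ratios.

Patients are `ceil(events / P(event))`, rounded up to an even total, where
`P(event)` averages the 28-day cumulative incidence over the arm mixture
(every patient is fully followed for 28 days).  These patient counts are
internally consistent with the calibrated model but are **not** comparable
to counts produced from other fitted onset models: the event probability
is the one quantity in the pipeline that depends on the unpublished
details of any external cohort fit, which is why the package treats event
counts as primary and patient counts as derived reporting.

## Patient-level simulator

Accrual is deterministic and uniform at 47 patients per 28-day month
(only the mean rate is specified by the motivating cohort); arms are
balanced exactly with permuted blocks of two; event times are continuous,
so ties have probability zero.  A look occurs at the exact calendar time
the stage's cumulative event target is reached; patients enrolled by then
contribute follow-up truncated at the look.  The monitoring statistic is
the log-rank z (score statistic of the single-covariate Cox partial
likelihood at β = 0); the observed hazard ratio at a look is the Newton
solution of that partial likelihood (Breslow convention).  Both are
implemented directly on cumulative risk-set sums — a few hundred
microseconds per analysis — and are verified against lifelines'
`logrank_test` and `CoxPHFitter` in the test suite.  If a replicate cannot
reach the final event target, the final analysis uses all data at full
follow-up.

The central validation property is simulation/integration agreement: the
empirical stop fractions, power and expected events of a simulated GSD
match the analytic values within Monte-Carlo error (10,000 replicates in
the acceptance-level test).

## Sample size re-estimation

The initial SSR plan is sized at the *assumed* HR with **efficacy
boundaries only** (SSR's futility instruments are the observed-HR rule and
the cap, not a β-spending boundary), giving a small maximum-event
inflation (~1.6% for the one-interim OBF design) and an interim at 64% of
that plan.  Combination weights are fixed at `(√t, √(1−t))`; the final
critical value is the final α-spending boundary, so the combined statistic
has exactly the planned null crossing probability for any data-dependent
stage-2 size (verified at 10⁶ null draws: 0.0250).

At the interim with `n₁` events and statistic `z₁` (observed
`HR₁ = exp(−2z₁/√n₁)`):

1. stop for efficacy if `z₁` crosses the spending boundary;
2. stop for futility if `HR₁ ≥ 1`;
3. otherwise continue with the smallest stage-2 count `d₂` whose
   conditional power under `HR₁` reaches the target, floored at the
   planned stage-2 count (increase-only mode) or at one event (both
   mode), and truncated so `n₁ + d₂` never exceeds the optimized total
   maximum.

**Total-maximum optimisation.**  The total maximum is the smallest value
for which the simulated proportion of trials rejecting the null at either
stage — conditional power in the operational, simulation-proportion sense
— reaches the desired power at a stated optimisation HR, capped at twice
the fixed-design count under the assumed HR.  Because that proportion is
a Monte-Carlo estimate, equality with the target can only be asserted
within sampling noise: a cap that falls short by at most two binomial
standard errors is accepted as the optimum.  When even that fails, the
design abandons the second stage entirely — every non-efficacy trial
stops at the interim for futility.  This degenerate regime is exactly
what an over-optimistic plan produces (assumed HR 0.73 against a true
0.79): the recalculated increase always exceeds the cap, so the study
ends at the 206-event interim with whatever efficacy probability the
interim look provides.

SSR operating characteristics are estimated on the asymptotic z-scale
(stage-wise statistics drawn from their normal limits), which matches the
patient-level simulator's log-rank distribution and keeps ten-thousand
replicate studies under a second.  The reported "mean maximum" events
average the realized (re-calculated) maximum among trials entering the
second stage; "total maximum" is the largest realized total.

## Study pipeline defaults

Comparison 1 (interim-timing scan) exploits that a one-interim design's
geometry depends only on the spending family and timing, mapping one solve
per timing onto all scenarios.  Comparison 2 spans one to nine equally
spaced interims.  Comparison 3 crosses assumed HRs {0.53…0.79} with a
common true HR (including 1), with fixed and GSD columns computed
analytically and SSR columns simulated (default 5,000 replicates;
pipeline tests use smaller sizes chosen so Monte-Carlo error stays well
inside the asserted tolerances).

## What the synthetic data do and do not show

The synthetic cohort generator reproduces the headline summaries of the
motivating ICU cohort (size, accrual rate, incidence, median onset, a few
losses to follow-up) from the same two-rate model the designs use, so
fit-then-generate round trips are exact in distribution.  Passing tests
therefore demonstrate internal consistency of the whole chain — not that
the two-rate hazard is an adequate description of any real cohort: real
onset distributions are more concentrated (IQR 1–6 days), exhibit
competing risks (death, extubation, discharge), and their incidence varies
across settings.  Conclusions about *relative* design performance are
insensitive to this (they depend on event counts, not calendar time), but
absolute patient numbers and trial durations are calibration-dependent.

## Known limitations

* Competing risks and dropouts are out of scope; cumulative incidences
  are treated as arising from the censoring-free onset model.
* Binding futility, Haybittle-Peto and Wang-Tsiatis boundaries, Fisher's
  product combination, and multi-interim SSR are not implemented.
* The empirical median onset of a generated cohort is right-skewed around
  its target because the hazard drops sharply at day 3; the defining
  property (half of events before day 3) is exact.
* The SSR interim placement is specified on the initial plan's event
  scale and is not itself optimised.
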