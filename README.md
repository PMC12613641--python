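# vaptrials

Design evaluation for randomised superiority trials preventing
ventilator-associated pneumonia (VAP) — and, more generally, for any
two-arm time-to-event trial with a short, administratively censored
follow-up.  The package sizes and compares three families of designs:

* **fixed RCT** — no interim analysis;
* **group sequential designs (GSD)** — error-spending efficacy and
  non-binding futility boundaries (O'Brien-Fleming-type or Pocock-type
  Lan-DeMets spending), with event-driven interim analyses;
* **sample size re-estimation (SSR)** — a single interim at which the
  stage-2 event count is recalculated from the observed hazard ratio using
  the inverse normal combination test, subject to an optimized cap.

It is written for trial statisticians exploring adaptive designs in
settings like the ICU, where the endpoint (VAP within 28 days of the
at-risk period) is observed quickly relative to accrual, making interim
analyses genuinely informative.

## The mathematics in brief

For a hazard ratio HR under proportional hazards, a fixed design needs

```
n = (z_{1-α} + z_{1-β})² / (P_Inv · P_SoC · ln(HR)²)
```

events in total (Schoenfeld), and `n / P(event observed)` patients, where
the event probability comes from a piecewise-exponential onset model.
Scenario hazard ratios derive from risk reductions through
`HR = ln(1 − p_SoC(1 − r)) / ln(1 − p_SoC)`.

A GSD spends the one-sided type-I error α and type-II error β across
analyses at information fractions `t_k` (fractions of the maximum event
count) with Lan-DeMets spending functions; the sequential z-statistics are
jointly normal with `corr(z_j, z_k) = √(t_j/t_k)` and drift
`−ln(HR)·√(n_k/4)` at `n_k` events (1:1 allocation).  Boundaries,
crossing probabilities, the power-attaining maximum event count and the
expected number of events `E[n] = Σ p_i·n_i` are computed by recursive
numerical integration; the interim timing that minimises `E[n]` is found
by grid search.

The SSR design combines stage-wise z-statistics as
`(w₁z₁ + w₂z₂)/√(w₁² + w₂²)` with pre-specified weights `(√t, √(1−t))`,
which keeps the type-I error exact for any data-dependent stage-2 size.
At the interim the trial stops for efficacy on the spending boundary,
stops for futility if the observed HR ≥ 1, and otherwise continues with
the smallest stage-2 event count whose conditional power reaches the
target, truncated at a total maximum tuned by simulation and capped at
twice the fixed design.

A patient-level simulator (staggered accrual, piecewise-exponential event
times, log-rank monitoring, Cox hazard-ratio estimates at the looks)
cross-validates every analytic quantity.

## Worked example

```python
from vaptrials import GSDesign, max_events

design = GSDesign(info_fractions=(0.64, 1.0))   # one interim at 64%
summary = max_events(design, hr=0.79)           # scenario 1, 80% power
print(summary.n_fixed_events, summary.n_max_events,
      round(summary.expected_events))
print(round(summary.stop_probabilities.p_eff[0], 2),
      round(summary.stop_probabilities.p_fut[0], 2))
```

prints

```
566 617 502
0.41 0.11
```

i.e. the fixed design needs 566 events; adding one interim at 64% of the
maximum inflates the worst case to 617 events but stops the trial early
with probability 0.52 (0.41 for efficacy, 0.11 for futility), cutting the
*expected* event count to 502.  The scripts in `examples/` walk through
each capability — fixed sizing, GSD operating characteristics, the
patient-level simulator, SSR studies, and the synthetic cohort generator —
and print the numbers with a short interpretation.

## Scope notes

Patient counts are reported from this package's own calibrated onset model
(28-day incidence 15.5%, median onset 3 days); competing risks and
dropouts are not modelled.  See `docs/methods.md` for the full model
description, calibration choices and limitations.
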