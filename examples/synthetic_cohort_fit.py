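"""Generate a synthetic ICU cohort and re-fit the onset model.

The generator emulates the observational cohort summary that informs the
designs: 1,096 at-risk patients accrued at 47/month, 15.5% develop VAP by
day 28 with a median onset of 3 days, and 5 losses to follow-up.  The
occurrence/exposure fit on the generated data recovers the generating
hazards.
"""

from vaptrials import CohortSpec, fit_piecewise_exponential, generate_cohort
from vaptrials.events import calibrate_onset_model

cohort = generate_cohort(CohortSpec(), seed=0)
events = cohort[cohort.event_flag == 1]
print(f"patients: {len(cohort)}, VAP events by day 28: {len(events)} "
      f"({cohort.event_flag.mean():.1%})")
print(f"median onset among events: {events.time_days.median():.1f} days "
      f"(IQR {events.time_days.quantile(0.25):.1f}-"
      f"{events.time_days.quantile(0.75):.1f})")

truth = calibrate_onset_model()
fitted = fit_piecewise_exponential(cohort)
print(f"\n{'interval (days)':>16} {'true hazard':>12} {'fitted':>9}")
lo = 0.0
for knot, r_true, r_fit in zip(fitted.knots, truth.rates, fitted.rates):
    print(f"{f'({lo:g}, {knot:g}]':>16} {r_true:>12.5f} {r_fit:>9.5f}")
    lo = knot
print(f"\nfitted 28-day cumulative incidence: {fitted.cif(28.0):.3f}"
      "\n\nThe hazard is high in the first three days of the at-risk period"
      "\nand drops afterwards; the upper quartile of the fitted onset"
      "\ndistribution is later than in the real cohort because only the"
      "\nincidence and the median are calibration targets.")
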