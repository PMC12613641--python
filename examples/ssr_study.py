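"""Sample size re-estimation with the inverse normal combination test.

Emulates the greedy-design comparison: the initial plan assumes a
prevention effect 5 percentage points larger than the truth (so the trial
starts underpowered); at the interim (64% of the initial maximum) the
stage-2 event count is recalculated from the observed hazard ratio, capped
by an optimized total maximum (at most twice the fixed design under the
assumed effect).
"""

from vaptrials import SSRConfig, run_ssr_study

pairs = [(0.73, 0.79), (0.63, 0.68), (0.53, 0.58)]  # (assumed, true) HR
print(f"{'assumed':>8} {'true':>5} {'mode':>9} {'E[events]':>10} "
      f"{'mean max':>9} {'total max':>10} {'power':>6}")
for assumed, true in pairs:
    for mode in ("increase_only", "both"):
        r = run_ssr_study(assumed, true, SSRConfig(mode=mode),
                          optimization_hr=true, n_sims=5000, seed=1)
        label = "increase" if mode == "increase_only" else "both"
        print(f"{assumed:>8.2f} {true:>5.2f} {label:>9} "
              f"{r['expected_events']:>10.0f} {r['mean_max_events']:>9.0f} "
              f"{r['optimized_total_max']:>10} {r['power']:>6.2f}")

print("\nFirst pair: the increase needed at the interim exceeds the cap, so"
      "\nthe optimisation allows no second stage — every non-efficacy trial"
      "\nstops at the 206-event interim (low power, smallest trial).  The"
      "\nother pairs recover the 80% target power by enlarging stage 2,"
      "\nwhich a group sequential design sized with the wrong effect cannot.")
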