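"""Orchestration of the three design-comparison exercises.

* Comparison 1 — fixed design vs one-interim group sequential designs
  (O'Brien-Fleming and Pocock spending) as the interim timing scans a grid.
* Comparison 2 — one to nine equally spaced interim analyses.
* Comparison 3 — fixed vs GSD vs SSR when the assumed prevention effect is
  correct, over- or under-estimated, including a null (HR = 1) column.

All group-sequential quantities are deterministic numerical integration;
only the SSR columns are Monte-Carlo.  Patient counts are derived from the
package's own calibrated onset model (the probability of observing an event
by day 28); they are internally consistent but depend on that calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import design as gsd
from .events import calibrate_onset_model, mixture_event_probability, patients_from_events
from .ssr import SSRConfig, run_ssr_study

__all__ = [
    "Scenario",
    "default_scenarios",
    "load_scenarios",
    "run_comparison_1",
    "run_comparison_2",
    "run_comparison_3",
]

TABLE1_REDUCTIONS = (0.20, 0.25, 0.30, 0.35, 0.40)


@dataclass(frozen=True)
class Scenario:
    """One prevention-effect scenario of the study grid."""

    id: int
    p_soc: float = 0.155
    reduction: float = 0.30

    @property
    def p_inv(self) -> float:
        return self.p_soc * (1.0 - self.reduction)

    @property
    def hr(self) -> float:
        return gsd.hr_from_incidence(self.p_soc, self.reduction)

    @property
    def hr_2dp(self) -> float:
        """Hazard ratio at the 2-decimal presentation precision."""
        return round(self.hr, 2)


def default_scenarios() -> list[Scenario]:
    """The five-scenario grid: 15.5% control incidence, 20-40% reduction."""
    return [Scenario(id=i + 1, p_soc=0.155, reduction=r)
            for i, r in enumerate(TABLE1_REDUCTIONS)]


def load_scenarios(path) -> list[Scenario]:
    """Read scenarios from a YAML file: a list of mappings with keys
    ``id``, ``p_soc``, ``reduction``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [Scenario(id=int(s["id"]), p_soc=float(s["p_soc"]),
                     reduction=float(s["reduction"])) for s in raw]


def _patients(n_events: float, hr: float, p_soc: float = 0.155) -> int:
    model = calibrate_onset_model(target_cif28=p_soc)
    return patients_from_events(n_events, mixture_event_probability(model, hr))


# ---------------------------------------------------------------------------
# comparison 1: single-interim timing scan
# ---------------------------------------------------------------------------

def run_comparison_1(power: float = 0.80, grid=None, scenarios=None,
                     spendings=("obf", "pocock"), alpha: float = 0.025,
                     out_dir=None) -> pd.DataFrame:
    """Per-timing operating characteristics of one-interim designs.

    The boundary geometry, drift and stop probabilities of a one-interim
    design depend only on the spending family, error rates and timing, so
    they are solved once per timing and the event scale is then mapped onto
    each scenario through its hazard ratio.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 0.951, 0.01), 10)
    if scenarios is None:
        scenarios = default_scenarios()
    d_fix = norm.ppf(1 - alpha) + norm.ppf(power)
    rows = []
    for spending in spendings:
        for t in grid:
            dsgn = gsd.GSDesign(info_fractions=(float(t), 1.0),
                                alpha_spending=spending, beta_spending=spending,
                                alpha=alpha, power=power)
            bounds = gsd.compute_boundaries(dsgn)
            drift = bounds.drift
            inflation = (drift / d_fix) ** 2
            p_up, p_lo = gsd._stagewise_exit_probs(
                np.asarray(dsgn.info_fractions), drift,
                np.asarray(bounds.efficacy_z), np.asarray(bounds.futility_z))
            p_stop_ia = float(p_up[0] + p_lo[0])
            for sc in scenarios:
                theta = -np.log(sc.hr_2dp)
                n_fixed = (d_fix / theta) ** 2 / 0.25
                n_max = n_fixed * inflation
                expected = n_max * (1.0 - p_stop_ia * (1.0 - t))
                rows.append({
                    "spending": spending, "ia_fraction": float(t),
                    "scenario": sc.id, "hr": sc.hr_2dp,
                    "n_fixed_events": int(np.ceil(n_fixed)),
                    "n_max_events": int(np.ceil(n_max)),
                    "expected_events": expected,
                    "p_eff_ia": float(p_up[0]), "p_fut_ia": float(p_lo[0]),
                    "expected_patients": _patients(expected, sc.hr_2dp, sc.p_soc),
                    "max_patients": _patients(n_max, sc.hr_2dp, sc.p_soc),
                })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "comparison1_ia_timing.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# comparison 2: number of interim analyses
# ---------------------------------------------------------------------------

def run_comparison_2(power: float = 0.80, k_range=range(1, 10),
                     scenario: Scenario | None = None, spending: str = "obf",
                     alpha: float = 0.025, out_dir=None) -> pd.DataFrame:
    """Equally spaced interim analyses, one to nine, vs the fixed design."""
    sc = scenario or default_scenarios()[0]
    rows = []
    for k in k_range:
        dsgn = gsd.GSDesign.equally_spaced(k, alpha_spending=spending,
                                           beta_spending=spending,
                                           alpha=alpha, power=power)
        summary = gsd.max_events(dsgn, sc.hr_2dp)
        stops = summary.stop_probabilities
        rows.append({
            "n_interims": k, "scenario": sc.id, "hr": sc.hr_2dp,
            "n_fixed_events": summary.n_fixed_events,
            "n_max_events": summary.n_max_events,
            "expected_events": summary.expected_events,
            "cum_p_eff_interim": float(sum(stops.p_eff[:-1])),
            "cum_p_fut_interim": float(sum(stops.p_fut)),
            "expected_events_saving": 1.0 - summary.expected_events / summary.n_fixed_events,
            "max_events_increase": summary.n_max_events / summary.n_fixed_events - 1.0,
        })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "comparison2_n_interims.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# comparison 3: fixed vs GSD vs SSR under mis-specified effects
# ---------------------------------------------------------------------------

def _fixed_design_row(assumed_hr: float, true_hr: float, alpha: float,
                      power: float) -> dict:
    n_fixed = gsd.schoenfeld_events(assumed_hr, alpha, power)
    theta = -np.log(true_hr) if true_hr != 1.0 else 0.0
    attained = float(norm.sf(norm.ppf(1 - alpha) - theta * np.sqrt(n_fixed / 4.0)))
    return {"design": "fixed", "power": attained,
            "expected_events": float(n_fixed), "mean_max_events": float(n_fixed),
            "p_eff_ia": np.nan, "p_fut_ia": np.nan}


def _gsd_row(assumed_hr: float, true_hr: float, ia_fraction: float,
             alpha: float, power: float, spending: str) -> dict:
    dsgn = gsd.GSDesign(info_fractions=(ia_fraction, 1.0),
                        alpha_spending=spending, beta_spending=spending,
                        alpha=alpha, power=power)
    summary = gsd.max_events(dsgn, assumed_hr)
    stops = gsd.crossing_probabilities(summary.boundaries, dsgn, true_hr,
                                       summary.n_max_events)
    expected = gsd.expected_events(summary, stops)
    return {"design": "gsd", "power": stops.power,
            "expected_events": expected,
            "mean_max_events": float(summary.n_max_events),
            "p_eff_ia": float(stops.p_eff[0]), "p_fut_ia": float(stops.p_fut[0])}


def run_comparison_3(true_hr: float, assumed_hr_grid=None,
                     optimization_hr: float = 0.68, power: float = 0.80,
                     alpha: float = 0.025, ia_fraction: float = 0.64,
                     n_sims: int = 5000, seed: int = 0,
                     out_dir=None) -> pd.DataFrame:
    """Fixed, GSD and the two SSR modes across a grid of assumed hazard
    ratios, at a common true hazard ratio (possibly 1 for the null)."""
    if assumed_hr_grid is None:
        assumed_hr_grid = (0.53, 0.58, 0.63, 0.68, 0.73, 0.79)
    rows = []
    rng = np.random.default_rng(seed)
    for assumed in assumed_hr_grid:
        base = {"assumed_hr": assumed, "true_hr": true_hr}
        rows.append(base | _fixed_design_row(assumed, true_hr, alpha, power))
        rows.append(base | _gsd_row(assumed, true_hr, ia_fraction, alpha,
                                    power, "obf"))
        for mode in ("increase_only", "both"):
            cfg = SSRConfig(mode=mode, ia_fraction=ia_fraction,
                            desired_power=power, alpha=alpha)
            res = run_ssr_study(assumed, true_hr, cfg,
                                optimization_hr=optimization_hr,
                                n_sims=n_sims,
                                seed=int(rng.integers(2**31 - 1)))
            rows.append(base | {
                "design": f"ssr_{'increase' if mode == 'increase_only' else 'both'}",
                "power": res["power"],
                "expected_events": res["expected_events"],
                "mean_max_events": res["mean_max_events"],
                "p_eff_ia": res["p_eff_ia"], "p_fut_ia": res["p_fut_ia"],
            })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(Path(out_dir) / "comparison3_ssr.csv", index=False)
    return df
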