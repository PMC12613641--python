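"""Piecewise-exponential model of VAP onset and event-to-patient conversion.

The onset of ventilator-associated pneumonia after the start of the at-risk
period (48 h of invasive ventilation) is modelled with a piecewise constant
hazard, administratively censored at the 28-day follow-up horizon.  The
module provides fitting (occurrence/exposure estimators), the cumulative
incidence function, sampling, the probability that a randomized patient's
event is observed during the trial, and the conversion of a required number
of events into a required number of patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PiecewiseExponentialModel",
    "AccrualModel",
    "calibrate_onset_model",
    "fit_piecewise_exponential",
    "event_probability",
    "mixture_event_probability",
    "patients_from_events",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

#: Cohort CSV schema: one row per patient.  ``time_days`` is the VAP onset
#: time after the start of the at-risk period when ``event_flag`` is 1,
#: otherwise the censoring time.
COHORT_COLUMNS = ("id", "entry_day", "event_flag", "time_days")

DEFAULT_KNOTS = (3.0, 7.0, 14.0, 28.0)


@dataclass(frozen=True)
class PiecewiseExponentialModel:
    """Piecewise constant hazard on intervals ``(0, k_1], (k_1, k_2], ...``.

    ``knots`` are the right endpoints of the intervals, the last equal to the
    administrative follow-up ``horizon`` (28 days).  ``rates`` are hazards in
    events per day; ``len(rates) == len(knots)``.
    """

    knots: tuple[float, ...]
    rates: tuple[float, ...]
    horizon: float = 28.0

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        rates = tuple(float(r) for r in self.rates)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "rates", rates)
        if len(knots) != len(rates):
            raise ValueError("knots and rates must have equal length")
        if any(b - a <= 0 for a, b in zip((0.0,) + knots, knots)):
            raise ValueError("knots must be strictly increasing and positive")
        if any(r < 0 for r in rates):
            raise ValueError("hazard rates must be non-negative")
        if abs(knots[-1] - self.horizon) > 1e-9:
            raise ValueError("last knot must equal the follow-up horizon")

    # -- basic survival bookkeeping -------------------------------------
    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        lo = np.concatenate(([0.0], self.knots[:-1]))
        hi = np.asarray(self.knots)
        exposure = np.clip(t[..., None], None, hi) - lo
        exposure = np.clip(exposure, 0.0, None)
        return exposure @ np.asarray(self.rates)

    def cif(self, t):
        """Cumulative incidence ``F(t) = 1 - exp(-integral of the hazard)``."""
        return -np.expm1(-self.cumulative_hazard(t))

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def scaled(self, hr: float) -> "PiecewiseExponentialModel":
        """Model with every interval hazard multiplied by ``hr``
        (proportional hazards), so that ``F_hr(t) = 1 - (1 - F(t))**hr``."""
        if hr < 0:
            raise ValueError("hazard ratio must be non-negative")
        return PiecewiseExponentialModel(self.knots,
                                         tuple(r * hr for r in self.rates),
                                         self.horizon)

    def quantile(self, q):
        """Inverse CIF.  Returns ``inf`` where the target is never reached."""
        q = np.asarray(q, dtype=float)
        target = -np.log1p(-q)  # required cumulative hazard
        lo = np.concatenate(([0.0], self.knots[:-1]))
        widths = np.asarray(self.knots) - lo
        rates = np.asarray(self.rates)
        cum = np.concatenate(([0.0], np.cumsum(widths * rates)))
        idx = np.searchsorted(cum[1:], target, side="left")
        out = np.full(np.shape(target), np.inf)
        inside = idx < len(rates)
        i = idx[inside]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lo[i] + (target[inside] - cum[i]) / rates[i]
        out[inside] = t
        return out

    def sample(self, rng: np.random.Generator, size: int):
        """Draw onset times; values beyond the horizon mean "no event by 28 d".

        Returns ``(times, event_flags)`` with times capped at the horizon for
        censored patients.
        """
        u = rng.uniform(size=size)
        t = self.quantile(u)
        event = t <= self.horizon
        return np.where(event, t, self.horizon), event


@dataclass(frozen=True)
class AccrualModel:
    """Deterministic uniform accrual at ``rate`` patients per 28-day month."""

    rate: float = 47.0
    days_per_month: float = 28.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("accrual rate must be positive")

    def entry_days(self, n_patients: int) -> np.ndarray:
        """Calendar entry day of each of ``n_patients`` patients, evenly
        spaced at the accrual intensity."""
        spacing = self.days_per_month / self.rate
        return spacing * np.arange(n_patients)


def calibrate_onset_model(target_cif28: float = 0.155,
                          target_median_onset: float = 3.0,
                          knots: tuple[float, ...] = DEFAULT_KNOTS,
                          horizon: float = 28.0) -> PiecewiseExponentialModel:
    """Two-rate declining hazard matching the cohort summaries.

    One hazard ``r1`` on ``(0, 3]`` and one hazard ``r2`` beyond day 3 are
    solved so that (i) the 28-day cumulative incidence equals
    ``target_cif28`` and (ii) the median onset time among patients with an
    event by day 28 equals ``target_median_onset`` (i.e.
    ``F(median) = F(28) / 2``).  Both conditions have a closed-form solution.
    """
    if not 0.0 <= target_cif28 < 1.0:
        raise ValueError("target 28-day incidence must be in [0, 1)")
    if not 0.0 < target_median_onset < horizon:
        raise ValueError("median onset must lie inside (0, horizon)")
    if target_cif28 == 0.0:
        return PiecewiseExponentialModel(knots, (0.0,) * len(knots), horizon)
    k1 = target_median_onset
    if abs(k1 - knots[0]) > 1e-9:
        raise ValueError("first knot must equal the target median onset")
    h28 = -np.log1p(-target_cif28)
    r1 = -np.log1p(-target_cif28 / 2.0) / k1
    r2 = (h28 - r1 * k1) / (horizon - k1)
    if r2 < 0:
        raise ValueError("infeasible targets: median too late for the 28-day incidence")
    rates = (r1,) + (r2,) * (len(knots) - 1)
    return PiecewiseExponentialModel(knots, rates, horizon)


def fit_piecewise_exponential(cohort: pd.DataFrame,
                              knots: tuple[float, ...] = DEFAULT_KNOTS,
                              horizon: float = 28.0) -> PiecewiseExponentialModel:
    """Occurrence/exposure hazard estimates on fixed intervals.

    For each interval the hazard estimate is (events in interval) divided by
    (person-days at risk in interval).  Intervals with no exposure get rate 0
    with a logged warning.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    missing = set(("event_flag", "time_days")) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks columns {sorted(missing)}")
    times = cohort["time_days"].to_numpy(dtype=float)
    events = cohort["event_flag"].to_numpy(dtype=int).astype(bool)
    if np.any(times < 0) or np.any(times > horizon + 1e-9):
        raise ValueError("times must lie in [0, horizon]")
    lo = np.concatenate(([0.0], np.asarray(knots[:-1])))
    hi = np.asarray(knots, dtype=float)
    rates = []
    for a, b in zip(lo, hi):
        exposure = np.clip(np.minimum(times, b) - a, 0.0, None).sum()
        d = np.count_nonzero(events & (times > a) & (times <= b))
        if exposure <= 0:
            logger.warning("no exposure in interval (%g, %g]; hazard set to 0", a, b)
            rates.append(0.0)
        else:
            rates.append(d / exposure)
    return PiecewiseExponentialModel(tuple(float(k) for k in knots),
                                     tuple(rates), horizon)


def event_probability(model: PiecewiseExponentialModel,
                      accrual: AccrualModel | None = None,
                      analysis_horizon: float | None = None,
                      n_patients: int | None = None) -> float:
    """Probability that a randomized patient's event is observed by study end.

    With every patient fully followed for the 28-day horizon (the default,
    matching a maximum follow-up of one month from enrolment) this is simply
    ``CIF(horizon)``.  When ``analysis_horizon`` (a calendar day) and an
    accrual model are given, the CIF is averaged over entry times with each
    patient's follow-up truncated at the analysis.
    """
    if analysis_horizon is None:
        return float(model.cif(model.horizon))
    if accrual is None or n_patients is None:
        raise ValueError("accrual model and n_patients required with an analysis horizon")
    entry = accrual.entry_days(n_patients)
    follow = np.clip(analysis_horizon - entry, 0.0, model.horizon)
    return float(np.mean(model.cif(follow)))


def mixture_event_probability(model: PiecewiseExponentialModel, hr: float,
                              alloc_inv: float = 0.5,
                              alloc_soc: float = 0.5) -> float:
    """Arm-mixture average probability of observing an event by the horizon,
    with the control arm following ``model`` and the intervention arm the
    ``hr``-scaled hazard."""
    p_soc = float(model.cif(model.horizon))
    p_inv = float(model.scaled(hr).cif(model.horizon))
    return alloc_soc * p_soc + alloc_inv * p_inv


def patients_from_events(n_events: float, p_event: float) -> int:
    """Required patients: ``ceil(n_events / p_event)``, rounded up to an even
    total for 1:1 allocation."""
    if not 0.0 < p_event <= 1.0:
        raise ValueError(f"event probability must be in (0, 1], got {p_event}")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    n = int(np.ceil(n_events / p_event - 1e-9))
    return n + (n % 2)


# ---------------------------------------------------------------------------
# cohort CSV round trip
# ---------------------------------------------------------------------------

def _validate_cohort(df: pd.DataFrame, horizon: float = 28.0) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort lacks columns {sorted(missing)}")
    if not df["event_flag"].isin((0, 1)).all():
        raise ValueError("event_flag must be 0 or 1")
    t = df["time_days"].to_numpy(dtype=float)
    if np.any(t < 0) or np.any(t > horizon + 1e-9):
        raise ValueError("time_days must lie in [0, horizon]")
    if np.any(df["entry_day"].to_numpy(dtype=float) < 0):
        raise ValueError("entry_day must be non-negative")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    _validate_cohort(df)
    df.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate_cohort(df)
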