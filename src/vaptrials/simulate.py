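"""Patient-level simulation of event-driven group sequential trials.

Patients accrue at a fixed intensity, are randomized 1:1 in permuted blocks
of two, and acquire VAP onset times from a piecewise-exponential hazard
(control) or its hazard-ratio-scaled version (intervention), censored
administratively at 28 days of follow-up.  Interim looks trigger at the
exact calendar time the per-stage cumulative event target is reached; the
monitoring statistic is the log-rank z (positive = benefit), and the
observed hazard ratio at a look comes from a single-covariate Cox
partial-likelihood fit.  Decisions follow the design's efficacy/futility
boundaries, with futility crossings enforced as stops.

The log-rank statistic and the Cox fit are implemented directly in numpy:
event times are continuous so ties have probability zero, and the
single-binary-covariate case reduces to cumulative sums over the risk set,
which keeps ten-thousand-replicate studies inside a few minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import BoundarySet, GSDesign
from .events import AccrualModel, PiecewiseExponentialModel

__all__ = [
    "TrialOutcome",
    "InterimSnapshot",
    "logrank_z",
    "cox_hr",
    "simulate_patients",
    "simulate_trial",
    "empirical_operating_characteristics",
]


@dataclass(frozen=True)
class InterimSnapshot:
    """State of the trial data at one analysis."""

    stage: int
    calendar_day: float
    events_observed: int
    z_statistic: float
    observed_hr: float


@dataclass(frozen=True)
class TrialOutcome:
    """Terminal state of one simulated trial."""

    exit_stage: int
    decision: str  # 'efficacy', 'futility', 'final_reject', 'final_accept'
    events_used: int
    patients_enrolled: int
    snapshots: tuple[InterimSnapshot, ...]

    @property
    def rejected(self) -> bool:
        return self.decision in ("efficacy", "final_reject")


# ---------------------------------------------------------------------------
# monitoring statistics
# ---------------------------------------------------------------------------

def _risk_set_sums(time: np.ndarray, event: np.ndarray, arm: np.ndarray):
    """Sort by time and return per-event risk-set totals.

    Returns (event_arm, n_risk, n1_risk) for each event in time order, where
    n1 counts the intervention arm.  Censored observations tied with an
    event time are treated as still at risk (censoring after events).
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    a = arm[order]
    n = len(t)
    at_risk = n - np.arange(n)          # risk set size just before each time
    n1_after = np.cumsum(a[::-1])[::-1]  # intervention patients with time >= t_i
    return a[e], at_risk[e].astype(float), n1_after[e].astype(float)


def logrank_z(time: np.ndarray, event: np.ndarray, arm: np.ndarray) -> float:
    """Log-rank z-statistic, positive when the intervention (arm=1) has
    fewer events than expected under the null."""
    x, n, n1 = _risk_set_sums(time, event, arm)
    if len(x) == 0:
        return 0.0
    p = n1 / n
    score = float(np.sum(x - p))            # d logL / d beta at beta = 0
    var = float(np.sum(p * (1.0 - p)))
    if var <= 0:
        return 0.0
    return -score / np.sqrt(var)


def cox_hr(time: np.ndarray, event: np.ndarray, arm: np.ndarray,
           tol: float = 1e-8, max_iter: int = 25) -> float:
    """Hazard ratio (intervention vs control) from a Newton solve of the
    single-binary-covariate Cox partial likelihood (Breslow convention;
    continuous times make ties a measure-zero event)."""
    x, n, n1 = _risk_set_sums(time, event, arm)
    if len(x) == 0:
        return 1.0
    n0 = n - n1
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta)
        s0 = n0 + w * n1
        p = w * n1 / s0
        score = float(np.sum(x - p))
        info = float(np.sum(p * (1.0 - p)))
        if info <= 1e-12:
            break
        step = score / info
        beta += np.clip(step, -4.0, 4.0)
        if abs(step) < tol:
            break
    return float(np.exp(beta))


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def simulate_patients(model: PiecewiseExponentialModel, accrual: AccrualModel,
                      hr: float, n_patients: int, rng: np.random.Generator):
    """Generate one trial's patients.

    Returns ``(entry, time, event, arm)`` arrays; ``time`` is onset (event)
    or the 28-day administrative censoring time.  Arms are balanced exactly
    1:1 via permuted blocks of two.
    """
    if n_patients % 2:
        n_patients += 1
    entry = accrual.entry_days(n_patients)
    arm = np.tile([0, 1], n_patients // 2)
    flip = rng.random(n_patients // 2) < 0.5
    blocks = arm.reshape(-1, 2)
    blocks[flip] = blocks[flip, ::-1]
    arm = blocks.ravel()

    u = rng.uniform(size=n_patients)
    time = np.empty(n_patients)
    event = np.zeros(n_patients, dtype=bool)
    for a, m in ((0, model), (1, model.scaled(hr))):
        sel = arm == a
        t, ev = _invert(m, u[sel])
        time[sel] = t
        event[sel] = ev
    return entry, time, event, arm


def _invert(model: PiecewiseExponentialModel, u: np.ndarray):
    t = model.quantile(u)
    ev = t <= model.horizon
    return np.where(ev, t, model.horizon), ev


def _look_view(entry, time, event, look_day, horizon):
    """Data snapshot at a calendar day: enrolled patients only, follow-up
    truncated at the look."""
    enrolled = entry < look_day
    follow = np.clip(look_day - entry[enrolled], 0.0, horizon)
    t = np.minimum(time[enrolled], follow)
    e = event[enrolled] & (time[enrolled] <= follow)
    return enrolled, t, e


# ---------------------------------------------------------------------------
# trial execution
# ---------------------------------------------------------------------------

def simulate_trial(model: PiecewiseExponentialModel, accrual: AccrualModel,
                   hr: float, design: GSDesign, boundaries: BoundarySet,
                   stage_targets, n_patients: int,
                   rng: np.random.Generator) -> TrialOutcome:
    """Run one event-driven group sequential trial.

    ``stage_targets`` are the cumulative event counts triggering each
    analysis.  If the patient pool cannot produce the final target, the
    final analysis uses all data at full follow-up.
    """
    stage_targets = [int(s) for s in stage_targets]
    if len(stage_targets) != design.n_analyses:
        raise ValueError("one event target per analysis required")
    entry, time, event, arm = simulate_patients(model, accrual, hr,
                                                n_patients, rng)
    event_cal = np.sort(entry[event] + time[event])
    end_of_study = float(entry.max()) + model.horizon

    upper = boundaries.efficacy_z
    lower = boundaries.futility_z
    snaps = []
    for k, target in enumerate(stage_targets):
        final = k == design.n_analyses - 1
        if target <= len(event_cal):
            look_day = float(event_cal[target - 1]) + 1e-9
        else:
            look_day = end_of_study + 1e-9
        enrolled, t, e = _look_view(entry, time, event, look_day, model.horizon)
        z = logrank_z(t, e, arm[enrolled])
        obs_hr = cox_hr(t, e, arm[enrolled])
        n_events = int(e.sum())
        snaps.append(InterimSnapshot(k + 1, look_day, n_events, z, obs_hr))
        if z >= upper[k]:
            decision = "final_reject" if final else "efficacy"
            return TrialOutcome(k + 1, decision, n_events,
                                int(enrolled.sum()), tuple(snaps))
        if final or z <= lower[k]:
            decision = "final_accept" if final else "futility"
            return TrialOutcome(k + 1, decision, n_events,
                                int(enrolled.sum()), tuple(snaps))
    raise AssertionError("unreachable: final analysis always terminates")


def empirical_operating_characteristics(
        model: PiecewiseExponentialModel, accrual: AccrualModel, hr: float,
        design: GSDesign, boundaries: BoundarySet, stage_targets,
        n_patients: int, replicates: int, seed: int) -> dict:
    """Monte-Carlo operating characteristics across independent replicates.

    Returns power, per-stage efficacy/futility stop fractions, expected
    events and patients, the maxima across replicates, and Monte-Carlo
    standard errors for the headline proportions.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    K = design.n_analyses
    eff = np.zeros(K)
    fut = np.zeros(K)
    rejected = 0
    events_used = np.empty(replicates)
    patients = np.empty(replicates)
    for r in range(replicates):
        out = simulate_trial(model, accrual, hr, design, boundaries,
                             stage_targets, n_patients, rng)
        k = out.exit_stage - 1
        if out.decision in ("efficacy", "final_reject"):
            eff[k] += 1
            rejected += 1
        elif out.decision == "futility":
            fut[k] += 1
        events_used[r] = out.events_used
        patients[r] = out.patients_enrolled
    power = rejected / replicates
    return {
        "replicates": replicates,
        "power": power,
        "power_se": float(np.sqrt(power * (1 - power) / replicates)),
        "p_eff": tuple(eff / replicates),
        "p_fut": tuple(fut / replicates),
        "expected_events": float(events_used.mean()),
        "expected_events_se": float(events_used.std(ddof=1) / np.sqrt(replicates)),
        "max_events": int(events_used.max()),
        "expected_patients": float(patients.mean()),
        "max_patients": int(patients.max()),
    }
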