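"""Sample size re-estimation with the inverse normal combination test.

The SSR designs here have a single interim at a pre-specified information
fraction of an initially (possibly under-) powered plan.  At the interim
the trial (1) stops for efficacy on the formal error-spending efficacy
boundary, (2) stops for futility if the observed hazard ratio favours the
control arm (HR >= 1), or (3) continues to a second stage whose event count
is recalculated from the observed hazard ratio so that the conditional
power of the combination test reaches the desired power, truncated at an
optimized total maximum number of events.  The total maximum is tuned by
simulation at a stated optimisation effect size and is capped at twice the
fixed-design event count under the assumed hazard ratio; when even the cap
cannot deliver the desired conditional power, the design forgoes the second
stage entirely and every non-efficacy trial stops at the interim for
futility.

Because the initial plan uses efficacy boundaries only (the futility rules
of SSR are the HR >= 1 check and the cap, not a beta-spending boundary),
its maximum-event inflation over the fixed design is small.

Stage-wise z-statistics are combined with fixed pre-specified weights
``(w1, w2) = (sqrt(t), sqrt(1 - t))``, which preserves the one-sided type-I
error for any data-dependent stage-2 size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .design import (GSDesign, _efficacy_bounds, _stagewise_exit_probs,
                     schoenfeld_events)

__all__ = [
    "SSRConfig",
    "SSRPlan",
    "SSROutcome",
    "inverse_normal_combination",
    "conditional_power",
    "required_stage2_events",
    "recalculate_stage2_events",
    "interim_decision",
    "plan_ssr",
    "optimize_total_max_events",
    "run_ssr_study",
]


@dataclass(frozen=True)
class SSRConfig:
    """Pre-specified choices of a sample size re-estimation design."""

    mode: str = "increase_only"          # 'increase_only' or 'both'
    ia_fraction: float = 0.64
    cap_multiplier: float = 2.0
    desired_power: float = 0.80
    alpha: float = 0.025
    alpha_spending: str = "obf"

    def __post_init__(self) -> None:
        if self.mode not in ("increase_only", "both"):
            raise ValueError(f"unknown SSR mode {self.mode!r}")
        if not 0.0 < self.ia_fraction < 1.0:
            raise ValueError("interim fraction must be in (0, 1)")
        if self.cap_multiplier < 1.0:
            raise ValueError("cap multiplier must be at least 1")

    @property
    def weights(self) -> tuple[float, float]:
        """Fixed combination-test weights ``(sqrt(t), sqrt(1 - t))``."""
        return (float(np.sqrt(self.ia_fraction)),
                float(np.sqrt(1.0 - self.ia_fraction)))


@dataclass(frozen=True)
class SSRPlan:
    """Initial (stage-1) plan derived from the assumed hazard ratio."""

    assumed_hr: float
    config: SSRConfig
    n1: int                  # events at the interim
    plan_max: int            # planned total events if no re-estimation
    cap: int                 # hard ceiling on the total (2 x fixed design)
    u1: float                # interim efficacy threshold
    u2: float                # final critical value of the combined test
    total_max: int | None = None  # optimized total; None = not yet optimized

    @property
    def plan_stage2(self) -> int:
        return self.plan_max - self.n1

    @property
    def degenerate(self) -> bool:
        """True when no second stage is allowed (optimisation infeasible)."""
        return self.total_max is not None and self.total_max <= self.n1


@dataclass(frozen=True)
class SSROutcome:
    """Result of one SSR trial path."""

    interim_decision: str                # 'efficacy', 'futility', 'continue'
    conditional_power_at_ia: float
    recalculated_stage2_events: int
    realized_max_events: int
    final_decision: str                  # 'reject' or 'accept'


# ---------------------------------------------------------------------------
# combination test machinery
# ---------------------------------------------------------------------------

def inverse_normal_combination(z1: float, z2: float, w1: float, w2: float):
    """Weighted inverse normal combination
    ``(w1*z1 + w2*z2) / sqrt(w1**2 + w2**2)``; invariant to rescaling the
    weights."""
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")
    denom = np.sqrt(w1 * w1 + w2 * w2)
    if denom == 0:
        raise ValueError("at least one weight must be positive")
    return (w1 * np.asarray(z1) + w2 * np.asarray(z2)) / denom


def _b_coefficient(z1, plan: SSRPlan):
    """Stage-2 z threshold for the combined statistic to cross ``u2``."""
    w1, w2 = plan.config.weights
    return (plan.u2 * np.sqrt(w1 * w1 + w2 * w2) - w1 * np.asarray(z1)) / w2


def conditional_power(z1, d2, hr, plan: SSRPlan):
    """Probability the combined test rejects, given the interim z and a
    stage-2 size of ``d2`` events, evaluated under hazard ratio ``hr``."""
    theta = -np.log(hr)
    return norm.cdf(theta * np.sqrt(np.asarray(d2, dtype=float) / 4.0)
                    - _b_coefficient(z1, plan))


def required_stage2_events(z1, observed_hr, plan: SSRPlan):
    """Smallest stage-2 event count whose conditional power under the
    observed hazard ratio reaches the desired power (uncapped, unfloored).

    Infinite when the observed hazard ratio does not favour the
    intervention.
    """
    z1 = np.asarray(z1, dtype=float)
    hr = np.asarray(observed_hr, dtype=float)
    theta = -np.log(hr)
    target = _b_coefficient(z1, plan) + norm.ppf(plan.config.desired_power)
    need = np.full(np.broadcast(z1, hr).shape, np.inf)
    ok = theta > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 4.0 * (np.maximum(target, 0.0) / theta) ** 2
    need = np.where(ok, np.ceil(np.maximum(raw, 1.0)), np.inf)
    return need if need.ndim else float(need)


def recalculate_stage2_events(observed_hr, z1, plan: SSRPlan,
                              total_max: int | None = None):
    """Stage-2 event count actually used when the trial continues.

    The conditional-power requirement is floored at the originally planned
    stage-2 count in ``increase_only`` mode (at one event in ``both`` mode)
    and truncated so the total never exceeds the optimized total maximum.
    """
    if total_max is None:
        total_max = plan.total_max if plan.total_max is not None else plan.cap
    need = required_stage2_events(z1, observed_hr, plan)
    floor = plan.plan_stage2 if plan.config.mode == "increase_only" else 1
    ceiling = max(total_max - plan.n1, 0)
    d2 = np.clip(np.nan_to_num(need, posinf=ceiling), floor, ceiling)
    d2 = np.asarray(d2, dtype=int)
    return d2 if d2.ndim else int(d2)


def interim_decision(z1: float, observed_hr: float, plan: SSRPlan,
                     total_max: int | None = None) -> str:
    """Three-way interim rule: efficacy on the spending boundary, futility
    when the observed hazard ratio favours the control arm (or when the
    design allows no second stage), otherwise continue."""
    if z1 >= plan.u1:
        return "efficacy"
    if observed_hr >= 1.0:
        return "futility"
    tm = total_max if total_max is not None else plan.total_max
    if tm is not None and tm <= plan.n1:
        return "futility"
    return "continue"


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def plan_ssr(assumed_hr: float, config: SSRConfig = SSRConfig()) -> SSRPlan:
    """Size the initial two-stage plan from the assumed hazard ratio.

    Efficacy boundaries come from the alpha-spending function at
    ``(t, 1)``; the plan's maximum events make the efficacy-only two-stage
    test attain the desired power at the assumed hazard ratio.  The cap is
    ``cap_multiplier`` times the fixed-design event count at the assumed
    hazard ratio.
    """
    if not 0 < assumed_hr < 1:
        raise ValueError("assumed hazard ratio must be in (0, 1)")
    t = np.array([config.ia_fraction, 1.0])
    design = GSDesign(info_fractions=tuple(t), alpha_spending=config.alpha_spending,
                      beta_spending=config.alpha_spending, alpha=config.alpha,
                      power=config.desired_power)
    u, _ = _efficacy_bounds(design)
    no_fut = np.full(2, -8.0)

    def power(drift):
        p_up, _ = _stagewise_exit_probs(t, drift, u, no_fut)
        return float(p_up.sum())

    d_fix = norm.ppf(1 - config.alpha) + norm.ppf(config.desired_power)
    drift = brentq(lambda d: power(d) - config.desired_power,
                   d_fix * 0.9, d_fix * 1.5, xtol=1e-8)
    theta = -np.log(assumed_hr)
    plan_max_cont = (drift / theta) ** 2 / 0.25
    n1 = int(np.ceil(config.ia_fraction * plan_max_cont - 1e-9))
    plan_max = int(np.ceil(plan_max_cont - 1e-9))
    n_fixed = schoenfeld_events(assumed_hr, config.alpha, config.desired_power)
    return SSRPlan(assumed_hr=assumed_hr, config=config, n1=n1,
                   plan_max=plan_max, cap=int(config.cap_multiplier * n_fixed),
                   u1=float(u[0]), u2=float(u[1]))


# ---------------------------------------------------------------------------
# vectorised trial paths on the z scale
# ---------------------------------------------------------------------------

def _draw_stage1(plan: SSRPlan, true_hr: float, n_sims: int,
                 rng: np.random.Generator):
    theta = -np.log(true_hr)
    z1 = theta * np.sqrt(plan.n1 / 4.0) + rng.standard_normal(n_sims)
    observed_hr = np.exp(-2.0 * z1 / np.sqrt(plan.n1))
    return z1, observed_hr


def _run_paths(plan: SSRPlan, true_hr: float, total_max: int | None,
               z1, observed_hr, eps2):
    """Evaluate every interim path given stage-1 draws and stage-2 noise.

    Returns (rejected, continued, totals) arrays; ``totals`` is the realized
    maximum event count of each path (n1 when the trial ends at the
    interim).
    """
    n = len(z1)
    eff = z1 >= plan.u1
    degenerate = total_max is None or total_max <= plan.n1
    if degenerate:
        cont = np.zeros(n, dtype=bool)
    else:
        cont = ~eff & (observed_hr < 1.0)
    totals = np.full(n, plan.n1, dtype=float)
    rejected = eff.copy()
    if cont.any():
        d2 = recalculate_stage2_events(observed_hr[cont], z1[cont], plan,
                                       total_max)
        theta = -np.log(true_hr)
        z2 = theta * np.sqrt(d2 / 4.0) + eps2[cont]
        w1, w2 = plan.config.weights
        combined = inverse_normal_combination(z1[cont], z2, w1, w2)
        rejected[cont] = combined >= plan.u2
        totals[cont] = plan.n1 + d2
    return rejected, cont, totals


def optimize_total_max_events(plan: SSRPlan, optimization_hr: float,
                              n_sims: int = 10_000, seed: int = 0) -> SSRPlan:
    """Tune the total maximum number of events by simulation.

    Simulating the design at the optimisation hazard ratio, the smallest
    total maximum for which the proportion of simulations rejecting the null
    (at the interim or the final analysis) reaches the desired power is
    selected, subject to the cap of twice the fixed design at the assumed
    hazard ratio.  Because the attained proportion is a Monte-Carlo
    estimate, equality with the desired power can only be asserted within
    sampling noise: when the cap falls short of the target by at most two
    binomial standard errors the cap itself is used.  If even that allowance
    cannot reach the desired power, the second stage is abandoned: the
    returned plan is degenerate and every non-efficacy trial stops at the
    interim for futility.
    """
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    rng = np.random.default_rng(seed)
    z1, observed_hr = _draw_stage1(plan, optimization_hr, n_sims, rng)
    eps2 = rng.standard_normal(n_sims)

    def attained(total):
        rejected, _, _ = _run_paths(plan, optimization_hr, total,
                                    z1, observed_hr, eps2)
        return float(rejected.mean())

    target = plan.config.desired_power
    mc_allowance = 2.0 * np.sqrt(target * (1.0 - target) / n_sims)
    lo, hi = plan.n1 + 1, plan.cap
    if hi <= plan.n1:
        return replace(plan, total_max=plan.n1)
    cap_power = attained(hi)
    if cap_power < target - mc_allowance:
        return replace(plan, total_max=plan.n1)  # degenerate: no second stage
    if cap_power < target:
        return replace(plan, total_max=int(hi))
    # attained power is non-decreasing in the total -> integer bisection
    while lo < hi:
        mid = (lo + hi) // 2
        if attained(mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    return replace(plan, total_max=int(lo))


def run_ssr_study(assumed_hr: float, true_hr: float,
                  config: SSRConfig = SSRConfig(),
                  optimization_hr: float | None = None,
                  n_sims: int = 10_000, seed: int = 0,
                  n_sims_optimize: int | None = None) -> dict:
    """Monte-Carlo operating characteristics of one SSR design.

    The initial plan is sized at ``assumed_hr``; the total maximum is
    optimized at ``optimization_hr`` (default: the true hazard ratio, unless
    the true value is 1, in which case the assumed one); trial paths are then
    simulated at ``true_hr``.  Reported "mean maximum" events average the
    re-calculated maximum among trials entering the second stage (the
    interim event count when none do).
    """
    plan = plan_ssr(assumed_hr, config)
    if optimization_hr is None:
        optimization_hr = true_hr if true_hr < 1.0 else assumed_hr
    rng = np.random.default_rng(seed)
    opt_seed = int(rng.integers(2**31 - 1))
    plan = optimize_total_max_events(plan, optimization_hr,
                                     n_sims_optimize or n_sims, opt_seed)
    z1, observed_hr = _draw_stage1(plan, true_hr, n_sims, rng)
    eps2 = rng.standard_normal(n_sims)
    rejected, cont, totals = _run_paths(plan, true_hr, plan.total_max,
                                        z1, observed_hr, eps2)
    eff_ia = (z1 >= plan.u1)
    power = float(rejected.mean())
    mean_max = float(totals[cont].mean()) if cont.any() else float(plan.n1)
    return {
        "plan": plan,
        "n_sims": n_sims,
        "power": power,
        "power_se": float(np.sqrt(power * (1 - power) / n_sims)),
        "p_eff_ia": float(eff_ia.mean()),
        "p_fut_ia": float((~eff_ia & ~cont).mean()),
        "p_continue": float(cont.mean()),
        "expected_events": float(totals.mean()),
        "expected_events_se": float(totals.std(ddof=1) / np.sqrt(n_sims)),
        "mean_max_events": mean_max,
        "total_max_events": int(totals.max()),
        "optimized_total_max": int(plan.total_max),
    }


def ssr_single(z1: float, observed_hr: float, z2_noise: float, true_hr: float,
               plan: SSRPlan, total_max: int | None = None) -> SSROutcome:
    """Evaluate a single SSR trial path (convenience wrapper used in tests
    and examples; the vectorised engine drives the studies)."""
    tm = total_max if total_max is not None else plan.total_max
    decision = interim_decision(z1, observed_hr, plan, tm)
    if decision == "efficacy":
        return SSROutcome(decision, 1.0, 0, plan.n1, "reject")
    if decision == "futility":
        return SSROutcome(decision, 0.0, 0, plan.n1, "accept")
    d2 = recalculate_stage2_events(observed_hr, z1, plan, tm)
    cp = float(conditional_power(z1, d2, observed_hr, plan))
    theta = -np.log(true_hr)
    z2 = theta * np.sqrt(d2 / 4.0) + z2_noise
    w1, w2 = plan.config.weights
    final = "reject" if inverse_normal_combination(z1, z2, w1, w2) >= plan.u2 \
        else "accept"
    return SSROutcome(decision, cp, int(d2), plan.n1 + int(d2), final)
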