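"""Error-spending group sequential design mathematics for time-to-event trials.

Everything in this module is closed-form or deterministic numerical
integration: fixed-design event counts (Schoenfeld), hazard ratios implied
by risk reductions under proportional hazards, Lan-DeMets error-spending
functions, efficacy/futility boundary computation, stage-wise crossing
probabilities, maximum and expected event counts, and the grid search for
the interim-analysis timing that minimises the expected number of events.

Conventions
-----------
* One-sided testing; a benefit (hazard ratio < 1) maps to a positive
  z-statistic.  The drift of the z-statistic at an analysis with ``n``
  cumulative events is ``-ln(hr) * sqrt(n * p_inv * p_soc)``.
* "Information fraction" means fraction of the maximum number of events.
* Futility boundaries are non-binding: efficacy boundaries are derived
  under the null ignoring futility, but sizing and operating
  characteristics always enforce futility stops, because the trial designs
  evaluated here always stop when a futility boundary is crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "TrialAssumptions",
    "GSDesign",
    "BoundarySet",
    "StopProbabilities",
    "DesignSummary",
    "schoenfeld_events",
    "hr_from_incidence",
    "spending_value",
    "compute_boundaries",
    "crossing_probabilities",
    "max_events",
    "expected_events",
    "optimal_ia_timing",
]

_SPENDING_KINDS = ("obf", "pocock")

# Integration nodes per stage for the sub-density recursion.  301 nodes on
# the continuation interval give boundary crossing probabilities accurate to
# well below 1e-6, enough to reproduce printed 2-dp probabilities robustly.
_N_NODES = 301
_Z_SPAN = 8.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialAssumptions:
    """Planning assumptions of a two-arm superiority trial with a
    time-to-event endpoint.

    Parameters
    ----------
    p_soc : float
        28-day cumulative incidence of the event in the control arm.
    reduction : float
        Relative reduction of the cumulative incidence in the
        investigational arm, as a fraction (0.30 for "30% reduction").
    alpha : float
        One-sided type-I error.
    power : float
        Target power, e.g. 0.80.
    alloc_inv, alloc_soc : float
        Allocation proportions; must sum to one.
    """

    p_soc: float
    reduction: float
    alpha: float = 0.025
    power: float = 0.80
    alloc_inv: float = 0.5
    alloc_soc: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_soc < 1.0:
            raise ValueError(f"p_soc must be in (0, 1), got {self.p_soc}")
        if not 0.0 <= self.reduction < 1.0:
            raise ValueError(f"reduction must be in [0, 1), got {self.reduction}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 0.5 < self.power < 1.0:
            raise ValueError(f"power must be in (0.5, 1), got {self.power}")
        if abs(self.alloc_inv + self.alloc_soc - 1.0) > 1e-12:
            raise ValueError("allocation proportions must sum to 1")

    @property
    def p_inv(self) -> float:
        """28-day cumulative incidence in the investigational arm."""
        return self.p_soc * (1.0 - self.reduction)

    @property
    def hr(self) -> float:
        """Hazard ratio implied by the risk reduction (proportional hazards)."""
        return hr_from_incidence(self.p_soc, self.reduction)

    def fixed_events(self) -> int:
        """Total number of events of the fixed (no-interim) design."""
        return schoenfeld_events(self.hr, self.alpha, self.power,
                                 self.alloc_inv, self.alloc_soc)


@dataclass(frozen=True)
class GSDesign:
    """Schedule and error-spending specification of a group sequential design.

    ``info_fractions`` are the event-information fractions of the analyses
    (interims plus final); they must be strictly increasing and end at 1.
    """

    info_fractions: tuple[float, ...]
    alpha_spending: str = "obf"
    beta_spending: str = "obf"
    alpha: float = 0.025
    power: float = 0.80
    futility_binding: bool = False

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.info_fractions)
        object.__setattr__(self, "info_fractions", t)
        if len(t) < 1:
            raise ValueError("need at least one analysis")
        if any(b - a <= 0 for a, b in zip((0.0,) + t, t)):
            raise ValueError(f"info_fractions must be strictly increasing in (0, 1]: {t}")
        if abs(t[-1] - 1.0) > 1e-12:
            raise ValueError("last information fraction must equal 1")
        for kind in (self.alpha_spending, self.beta_spending):
            if kind not in _SPENDING_KINDS:
                raise ValueError(f"unknown spending kind {kind!r}; use one of {_SPENDING_KINDS}")
        if self.futility_binding:
            raise ValueError("binding futility designs are out of scope")

    @property
    def n_analyses(self) -> int:
        return len(self.info_fractions)

    @classmethod
    def equally_spaced(cls, n_interim: int, **kwargs) -> "GSDesign":
        """Design with ``n_interim`` equally spaced interims plus the final."""
        k = n_interim + 1
        return cls(info_fractions=tuple((i + 1) / k for i in range(k)), **kwargs)


@dataclass(frozen=True)
class BoundarySet:
    """Per-analysis efficacy (upper) and futility (lower) z thresholds,
    with the cumulative error spent at each analysis."""

    efficacy_z: tuple[float, ...]
    futility_z: tuple[float, ...]
    cumulative_alpha_spent: tuple[float, ...]
    cumulative_beta_spent: tuple[float, ...]
    drift: float  # drift of the final-analysis z under the design alternative

    def __post_init__(self) -> None:
        u, l = self.efficacy_z, self.futility_z
        if len(u) != len(l):
            raise ValueError("efficacy and futility boundaries differ in length")
        if any(li > ui + 1e-9 for li, ui in zip(l, u)):
            raise ValueError("futility boundary exceeds efficacy boundary")


@dataclass(frozen=True)
class StopProbabilities:
    """Per-analysis exit probabilities of a group sequential trial."""

    p_eff: tuple[float, ...]
    p_fut: tuple[float, ...]
    p_final_accept: float

    def __post_init__(self) -> None:
        total = sum(self.p_eff) + sum(self.p_fut) + self.p_final_accept
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"exit probabilities sum to {total}, expected 1")

    @property
    def p_stop(self) -> tuple[float, ...]:
        """Probability of the trial ending at each analysis (any reason)."""
        k = len(self.p_eff)
        p = [self.p_eff[i] + self.p_fut[i] for i in range(k)]
        p[-1] += self.p_final_accept
        return tuple(p)

    @property
    def power(self) -> float:
        return float(sum(self.p_eff))


@dataclass(frozen=True)
class DesignSummary:
    """Event-count summary of a sized group sequential design."""

    n_fixed_events: int
    n_max_events: int
    n_events_per_stage: tuple[int, ...]
    expected_events: float
    stop_probabilities: StopProbabilities | None = field(default=None, compare=False)
    boundaries: BoundarySet | None = field(default=None, compare=False)


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------

def schoenfeld_events(hr: float, alpha: float = 0.025, power: float = 0.80,
                      alloc_inv: float = 0.5, alloc_soc: float = 0.5) -> int:
    """Total number of events required by a fixed design.

    Uses the Schoenfeld approximation
    ``n = (z_{1-alpha} + z_{1-beta})^2 / (P_inv * P_soc * ln(hr)^2)``,
    rounded up to an integer.  The count is the total across both arms.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    if abs(np.log(hr)) < 1e-12:
        raise ValueError("hazard ratio of 1 gives a divergent event count")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z = norm.ppf(1.0 - alpha) + norm.ppf(power)
    n = z * z / (alloc_inv * alloc_soc * np.log(hr) ** 2)
    return int(np.ceil(n - 1e-9))


def hr_from_incidence(p_soc: float, reduction: float) -> float:
    """Hazard ratio implied by a relative risk reduction at a fixed horizon.

    Under proportional hazards the survival functions satisfy
    ``S_inv = S_soc ** hr``, so
    ``hr = ln(1 - p_soc * (1 - reduction)) / ln(1 - p_soc)``.
    """
    if not 0.0 < p_soc < 1.0:
        raise ValueError(f"p_soc must be in (0, 1), got {p_soc}")
    if not 0.0 <= reduction <= 1.0:
        raise ValueError(f"reduction must be in [0, 1], got {reduction}")
    p_inv = p_soc * (1.0 - reduction)
    return float(np.log1p(-p_inv) / np.log1p(-p_soc))


def spending_value(kind: str, total_error: float, t):
    """Cumulative error spent at information fraction ``t``.

    ``kind='obf'`` is the Lan-DeMets O'Brien-Fleming-type function
    ``2 * (1 - Phi(z_{1 - e/2} / sqrt(t)))``; ``kind='pocock'`` is the
    Pocock-type function ``e * ln(1 + (exp(1) - 1) * t)``.  Both vanish as
    ``t -> 0`` and equal ``total_error`` at ``t = 1``.
    """
    if kind not in _SPENDING_KINDS:
        raise ValueError(f"unknown spending kind {kind!r}; use one of {_SPENDING_KINDS}")
    if not 0.0 < total_error < 1.0:
        raise ValueError(f"total_error must be in (0, 1), got {total_error}")
    tt = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
    if np.any(np.asarray(t, dtype=float) < 0):
        raise ValueError("information fraction must be non-negative")
    with np.errstate(divide="ignore"):
        if kind == "obf":
            out = 2.0 * norm.sf(norm.ppf(1.0 - total_error / 2.0) / np.sqrt(tt))
        else:
            out = total_error * np.log1p((np.e - 1.0) * tt)
    out = np.where(tt == 0.0, 0.0, out)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# sub-density recursion over the canonical joint distribution
# ---------------------------------------------------------------------------

class _SequentialRecursion:
    """Incremental Armitage sub-density recursion for sequential z-statistics.

    ``z_k ~ N(drift * sqrt(t_k), 1)`` with ``corr(z_j, z_k) = sqrt(t_j/t_k)``.
    Stages are committed one at a time with their continuation interval
    ``(lower_k, upper_k)``; ``peek`` evaluates the next stage's crossing
    probabilities against the committed state without advancing, which makes
    boundary root solves O(nodes) instead of O(stages * nodes**2).
    """

    def __init__(self, t, drift: float, n_nodes: int = _N_NODES):
        self.t = np.asarray(t, dtype=float)
        self.drift = float(drift)
        self.k = 0          # number of committed stages
        self.x = None       # nodes of the committed continuation interval
        self.f = None       # weighted sub-density at those nodes
        self.dead = False   # continuation region became empty
        self._gx, self._gw = np.polynomial.legendre.leggauss(n_nodes)

    def _conditional(self):
        """Mean and sd of z_{k+1} given z_k at the committed nodes."""
        k = self.k
        ratio = np.sqrt(self.t[k - 1] / self.t[k])
        mu = self.x * ratio + self.drift * (self.t[k] - self.t[k - 1]) / np.sqrt(self.t[k])
        s = np.sqrt((self.t[k] - self.t[k - 1]) / self.t[k])
        return mu, s

    def peek(self, upper: float, lower: float) -> tuple[float, float]:
        """Upper/lower first-crossing probabilities at the next stage."""
        if self.dead:
            return 0.0, 0.0
        if self.k == 0:
            m = self.drift * np.sqrt(self.t[0])
            return float(norm.sf(upper - m)), float(norm.cdf(lower - m))
        mu, s = self._conditional()
        return (float(self.f @ norm.sf((upper - mu) / s)),
                float(self.f @ norm.cdf((lower - mu) / s)))

    def commit(self, upper: float, lower: float) -> None:
        """Advance one stage, keeping the sub-density on (lower, upper)."""
        if self.dead:
            self.k += 1
            return
        m = self.drift * np.sqrt(self.t[self.k])
        lo, hi = max(lower, m - _Z_SPAN), min(upper, m + _Z_SPAN)
        if hi <= lo:
            self.dead = True
            self.k += 1
            return
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        xn = mid + half * self._gx
        wn = half * self._gw
        if self.k == 0:
            self.f = norm.pdf(xn - m) * wn
        else:
            mu, s = self._conditional()
            self.f = (norm.pdf((xn[:, None] - mu[None, :]) / s) / s) @ self.f * wn
        self.x = xn
        self.k += 1


def _stagewise_exit_probs(t, drift: float, upper, lower,
                          n_nodes: int = _N_NODES):
    """Per-stage first-crossing probabilities for fixed boundary vectors.

    The trial continues while ``lower_k < z_k < upper_k``; returns arrays of
    upper- and lower-crossing probabilities by stage.
    """
    t = np.asarray(t, dtype=float)
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    K = len(t)
    rec = _SequentialRecursion(t, drift, n_nodes)
    p_up = np.zeros(K)
    p_lo = np.zeros(K)
    for k in range(K):
        p_up[k], p_lo[k] = rec.peek(upper[k], lower[k])
        if k < K - 1:
            rec.commit(upper[k], lower[k])
    return p_up, p_lo


def _efficacy_bounds(design: GSDesign) -> tuple[np.ndarray, np.ndarray]:
    """Efficacy boundaries solving alpha-spending increments under the null.

    Futility is ignored (non-binding construction).  Returns the boundaries
    and the cumulative alpha spent at each analysis.
    """
    t = np.asarray(design.info_fractions)
    cum = np.atleast_1d(spending_value(design.alpha_spending, design.alpha, t))
    K = len(t)
    u = np.empty(K)
    rec = _SequentialRecursion(t, 0.0)
    for k in range(K):
        inc = max(cum[k] - (cum[k - 1] if k else 0.0), 1e-14)

        def shortfall(b):
            return rec.peek(b, -_Z_SPAN)[0] - inc

        try:
            u[k] = brentq(shortfall, 0.0, _Z_SPAN, xtol=1e-9)
        except ValueError as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"efficacy boundary root solve failed at analysis {k + 1} "
                f"(increment {inc:.3e})") from exc
        if k < K - 1:
            rec.commit(u[k], -_Z_SPAN)
    return u, cum


def _futility_pass(design: GSDesign, u: np.ndarray, drift: float):
    """One forward pass under ``drift``: solve the beta-spending futility
    boundaries with the efficacy boundaries in place, and accumulate the
    stage-wise exit probabilities.

    The final lower boundary is forced equal to the final efficacy boundary
    so the trial always terminates; interim lower boundaries are capped at
    the efficacy boundary when the requested increment cannot be spent.
    Returns ``(lower_bounds, cumulative_beta, p_up, p_lo)``.
    """
    t = np.asarray(design.info_fractions)
    beta = 1.0 - design.power
    cum = np.atleast_1d(spending_value(design.beta_spending, beta, t))
    K = len(t)
    low = np.full(K, -_Z_SPAN)
    p_up = np.zeros(K)
    p_lo = np.zeros(K)
    rec = _SequentialRecursion(t, drift)
    for k in range(K - 1):
        inc = max(cum[k] - (cum[k - 1] if k else 0.0), 1e-14)

        def excess(b):
            return rec.peek(u[k], b)[1] - inc

        hi = u[k] - 1e-9
        if excess(hi) < 0.0:
            low[k] = hi
        else:
            low[k] = brentq(excess, -_Z_SPAN, hi, xtol=1e-9)
        p_up[k], p_lo[k] = rec.peek(u[k], low[k])
        rec.commit(u[k], low[k])
    low[K - 1] = u[K - 1]
    p_up[K - 1], p_lo[K - 1] = rec.peek(u[K - 1], low[K - 1])
    return low, cum, p_up, p_lo


def _futility_bounds(design: GSDesign, u: np.ndarray, drift: float):
    low, cum, _, _ = _futility_pass(design, u, drift)
    return low, cum


def _power_at_drift(design: GSDesign, u: np.ndarray, drift: float) -> float:
    """Rejection probability under ``drift`` with futility stops enforced."""
    _, _, p_up, _ = _futility_pass(design, u, drift)
    return float(p_up.sum())


def _solve_design_drift(design: GSDesign, u: np.ndarray | None = None) -> float:
    """Final-analysis drift at which the design attains its target power."""
    if u is None:
        u, _ = _efficacy_bounds(design)
    lo = norm.ppf(1 - design.alpha) + norm.ppf(design.power)  # fixed-design drift
    hi = lo * 1.8
    return brentq(lambda d: _power_at_drift(design, u, d) - design.power,
                  lo * 0.8, hi, xtol=1e-8)


# ---------------------------------------------------------------------------
# public design operations
# ---------------------------------------------------------------------------

def compute_boundaries(design: GSDesign, drift: float | None = None) -> BoundarySet:
    """Efficacy and futility boundaries of an error-spending design.

    Efficacy thresholds spend the alpha increments under the null, ignoring
    futility (non-binding).  Futility thresholds spend the beta increments
    under the design alternative; if ``drift`` is not given, the drift is
    solved so that the design attains its target power with futility stops
    enforced (self-consistent sizing).
    """
    u, cum_a = _efficacy_bounds(design)
    if drift is None:
        drift = _solve_design_drift(design, u)
    low, cum_b = _futility_bounds(design, u, drift)
    return BoundarySet(
        efficacy_z=tuple(u),
        futility_z=tuple(low),
        cumulative_alpha_spent=tuple(np.atleast_1d(cum_a)),
        cumulative_beta_spent=tuple(np.atleast_1d(cum_b)),
        drift=float(drift),
    )


def crossing_probabilities(boundaries: BoundarySet, design: GSDesign, hr: float,
                           n_max_events: float, alloc_inv: float = 0.5,
                           alloc_soc: float = 0.5) -> StopProbabilities:
    """Per-analysis exit probabilities under a given true hazard ratio.

    The drift of the z-statistic at analysis ``k`` with ``n_k`` cumulative
    events is ``-ln(hr) * sqrt(n_k * alloc_inv * alloc_soc)``.  Futility
    crossings are treated as actual stops.
    """
    t = np.asarray(design.info_fractions)
    theta = -np.log(hr)
    drift = theta * np.sqrt(n_max_events * alloc_inv * alloc_soc)
    u = np.asarray(boundaries.efficacy_z)
    low = np.asarray(boundaries.futility_z)
    p_up, p_lo = _stagewise_exit_probs(t, drift, u, low)
    # At the final analysis the lower boundary equals the upper one, so the
    # "lower crossing" there is acceptance, not a futility stop.
    p_fut = p_lo.copy()
    p_final_accept = float(p_fut[-1])
    p_fut[-1] = 0.0
    # absorb integration residue (<1e-8) into the final acceptance mass
    p_final_accept = max(0.0, 1.0 - float(p_up.sum()) - float(p_fut.sum()))
    return StopProbabilities(p_eff=tuple(p_up), p_fut=tuple(p_fut),
                             p_final_accept=p_final_accept)


def max_events(design: GSDesign, hr: float, alloc_inv: float = 0.5,
               alloc_soc: float = 0.5, _round: bool = True) -> DesignSummary:
    """Size a group sequential design for a given hazard ratio.

    Finds the maximum number of events such that the rejection probability
    under ``hr`` — with non-binding futility boundaries enforced as actual
    stops — reaches the target power.  Also reports the fixed-design count,
    the per-stage cumulative event targets, and the expected number of
    events under the design alternative.
    """
    if hr <= 0 or abs(np.log(hr)) < 1e-12:
        raise ValueError("hazard ratio must be positive and different from 1")
    theta = abs(np.log(hr))
    u, _ = _efficacy_bounds(design)
    drift = _solve_design_drift(design, u)
    boundaries = compute_boundaries(design, drift=drift)
    i_max = (drift / theta) ** 2
    n_max_cont = i_max / (alloc_inv * alloc_soc)
    n_max = int(np.ceil(n_max_cont - 1e-9)) if _round else n_max_cont
    stops = crossing_probabilities(boundaries, design, hr, n_max_cont,
                                   alloc_inv, alloc_soc)
    t = np.asarray(design.info_fractions)
    if _round:
        stages = tuple(int(np.ceil(f * n_max - 1e-9)) for f in t)
    else:
        stages = tuple(f * n_max_cont for f in t)
    expected = expected_events_from(stages, stops)
    n_fixed = schoenfeld_events(hr, design.alpha, design.power, alloc_inv, alloc_soc)
    return DesignSummary(
        n_fixed_events=n_fixed,
        n_max_events=n_max if _round else int(np.ceil(n_max_cont)),
        n_events_per_stage=stages,
        expected_events=float(expected),
        stop_probabilities=stops,
        boundaries=boundaries,
    )


def expected_events_from(n_events_per_stage: Sequence[float],
                         stop_probs: StopProbabilities) -> float:
    """Expected number of events: ``sum_i p_i * n_i`` over all exit stages."""
    n = np.asarray(n_events_per_stage, dtype=float)
    p = np.asarray(stop_probs.p_stop, dtype=float)
    if len(n) != len(p):
        raise ValueError(f"stage count mismatch: {len(n)} event targets vs "
                         f"{len(p)} stop probabilities")
    return float(p @ n)


def expected_events(design_summary: DesignSummary,
                    stop_probs: StopProbabilities) -> float:
    """Expected number of events of a sized design under given exit
    probabilities (the stage-weighted average of cumulative event counts)."""
    return expected_events_from(design_summary.n_events_per_stage, stop_probs)


def optimal_ia_timing(spending: str, hr: float, grid: Sequence[float] | None = None,
                      alpha: float = 0.025, power: float = 0.80,
                      alloc_inv: float = 0.5, alloc_soc: float = 0.5) -> float:
    """Information fraction of a single interim minimising expected events.

    For each candidate fraction the one-interim design is fully re-sized
    (boundaries, drift, maximum events) and the expected number of events
    under the design alternative is evaluated on the continuous event scale;
    the grid point with the minimum wins, ties broken toward the earlier
    fraction.  Default grid: 1% steps on [0.05, 0.95].
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 0.951, 0.01), 10)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty timing grid")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid fractions must lie strictly inside (0, 1)")
    best_t, best_e = None, np.inf
    for frac in grid:
        design = GSDesign(info_fractions=(float(frac), 1.0),
                          alpha_spending=spending, beta_spending=spending,
                          alpha=alpha, power=power)
        summary = max_events(design, hr, alloc_inv, alloc_soc, _round=False)
        if summary.expected_events < best_e - 1e-12:
            best_e = summary.expected_events
            best_t = float(frac)
    return best_t
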