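"""Multi-dose treatment machinery.

Contains the auxiliary idealized saturation model (instantaneous binding,
receptors held saturated) used to reason about long-term curability and to
derive continuous dosing profiles; discretization of continuous profiles
into bolus schedules; capacity-tailored universal schedule families
stratified by the self-damage significance k_s; and their optimization and
evaluation on virtual populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp

from . import analytics
from .model import DoseSchedule
from .params import ModelParameters
from .trials import (FAST_SIM_KWARGS, Strategy, TrialOutcome,
                     VirtualPopulation, run_trial)

__all__ = [
    "KsGroup", "DEFAULT_KS_GROUPS", "ks_group_of",
    "idealized_saturation_dynamics", "discretize_schedule",
    "ScheduleFamily", "schedule_strategy",
    "optimize_universal_schedule", "evaluate_schedule",
]


# ---------------------------------------------------------------------------
# k_s stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KsGroup:
    """A stratum of the self-damage significance k_s."""

    label: str
    lo: float
    hi: float  # half-open [lo, hi); the top group includes k_s = 1

    def contains(self, k_s: float) -> bool:
        return self.lo <= k_s < self.hi or (self.hi >= 1.0 and k_s == 1.0)


#: default stratification: particle range / cell density determine whether
#: self-damage is negligible, comparable to, or dominant over cross-fire
DEFAULT_KS_GROUPS: tuple[KsGroup, ...] = (
    KsGroup("low", 0.0, 0.2),
    KsGroup("intermediate", 0.2, 0.6),
    KsGroup("high", 0.6, 1.0),
)


def ks_group_of(k_s: float,
                groups: Sequence[KsGroup] = DEFAULT_KS_GROUPS) -> KsGroup:
    for g in groups:
        if g.contains(k_s):
            return g
    raise ValueError(f"k_s={k_s!r} not covered by the group partition")


# ---------------------------------------------------------------------------
# idealized saturation model
# ---------------------------------------------------------------------------

def idealized_saturation_dynamics(params: ModelParameters,
                                  occupancy: Callable[[float], float] | float | None = None,
                                  horizon: float = 365.0,
                                  eta: float | None = None,
                                  rtol: float = 1e-8,
                                  atol: float = 1e-12) -> pd.DataFrame:
    """Reduced model with instantaneous binding and saturated receptors.

    All receptors are assumed occupied at all times; the dosing policy
    prescribes the *active* occupancy ``phi(t) <= 1/(eta+1)`` (the rest of
    the saturating antibodies are inert). With equal occupancy on viable and
    damaged cells the damage rate collapses to
    ``RD = alpha*lambda*gamma*phi/nu`` regardless of k_s, so the maximal
    sustainable kill rate is ``alpha*lambda*gamma/(nu*(eta+1))`` and
    long-term cure requires it to exceed rho.

    Returns a daily trajectory of N, D and the injection rate/cumulative
    activity needed to maintain the occupancy (decay replacement plus
    saturation of newborn-cell receptors, minus receptors lost with dying
    damaged cells).
    """
    eta = params.eta if eta is None else eta
    phi_max = 1.0 / (eta + 1.0)
    if occupancy is None:
        phi = lambda t: phi_max
    elif callable(occupancy):
        phi = occupancy
    else:
        level = float(occupancy)
        phi = lambda t: level

    alpha, lam, gam, nu = params.alpha, params.lambda_decay, params.gamma, params.nu

    def check(phival: float) -> float:
        if not -1e-12 <= phival <= phi_max * (1 + 1e-9):
            raise ValueError(
                f"occupancy {phival!r} outside [0, 1/(eta+1)] = [0, {phi_max:g}]")
        return min(max(phival, 0.0), phi_max)

    def rhs(t, y):
        N, D, _ = y
        p = check(phi(t))
        RD = alpha * lam * gam * p / nu
        # activity to keep occupancy: replace decays on all cells and claim
        # the receptors of newborn viable cells
        u = gam * p * (lam * (N + D) + params.rho * N)
        return [params.rho * N - RD * N, RD * N - params.omega * D, u]

    t_eval = np.arange(0.0, horizon + 1e-9, 1.0)
    sol = solve_ivp(rhs, (0.0, horizon), [params.N0, 0.0, 0.0],
                    t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"idealized model integration failed: {sol.message}")
    return pd.DataFrame({
        "time": sol.t, "N": sol.y[0], "D": sol.y[1],
        "cum_injected_activity": sol.y[2],
        "occupancy": [check(phi(t)) for t in sol.t],
    })


def discretize_schedule(profile: Callable[[float], float],
                        breakpoints: Sequence[float],
                        eta: float | None = None) -> DoseSchedule:
    """Turn a continuous dosing-rate profile (pmol of activity per day) into
    boluses over the intervals between ``breakpoints``.

    Each bolus, injected at the start of its interval, carries the profile's
    integral over that interval; total activity is conserved.
    """
    bp = [float(b) for b in breakpoints]
    if len(bp) < 2 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
        raise ValueError("breakpoints must be at least 2, strictly increasing")
    injections = []
    for t0, t1 in zip(bp[:-1], bp[1:]):
        amount, _ = quad(profile, t0, t1, limit=200)
        if amount < -1e-12:
            raise ValueError("profile integrates to a negative dose")
        injections.append((t0, max(amount, 0.0)))
    return DoseSchedule(tuple(injections), eta_override=eta)


# ---------------------------------------------------------------------------
# universal schedule families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleFamily:
    """Capacity-tailored multi-dose schedule.

    The first injected *antibody* amount is ``c1*capacity + c0`` pmol (the
    saturating level plus the slow-binding compensation), each of the K-1
    follow-up doses carries the fraction ``c2`` of the first, and doses are
    ``tau`` days apart. Every bolus is capped at the worst-case maximal safe
    dose for the mouse's capacity.
    """

    c1: float = 1.5
    c0: float = 3.0
    c2: float = 0.25
    tau: float = 7.0
    K: int = 4
    label: str = ""

    def __post_init__(self) -> None:
        if self.K < 1 or self.tau <= 0 or self.c2 < 0 or self.c1 < 0 or self.c0 < 0:
            raise ValueError("invalid schedule family constants")

    def build(self, capacity_pmol: float, params: ModelParameters,
              eta: float | None = None,
              ranges: analytics.SafeDoseRanges | None = None) -> DoseSchedule:
        eta = params.eta if eta is None else eta
        cap = analytics.max_safe_dose(capacity_pmol, params, ranges, eta=eta)
        first = min((self.c1 * capacity_pmol + self.c0) / (eta + 1.0), cap)
        injections = [(0.0, first)]
        for k in range(1, self.K):
            injections.append((k * self.tau, min(self.c2 * first, cap)))
        return DoseSchedule(tuple(injections), eta_override=eta)


def schedule_strategy(family: ScheduleFamily,
                      ranges: analytics.SafeDoseRanges | None = None) -> Strategy:
    """Trial strategy applying a schedule family tailored to each mouse's
    (known) binding capacity."""
    def strategy(mouse: ModelParameters) -> DoseSchedule:
        return family.build(mouse.binding_capacity, mouse, ranges=ranges)
    return strategy


#: default optimization grid: dose-fraction, interval and dose-count ranges
DEFAULT_FAMILY_GRID = dict(
    c1=(1.5,),
    c0=(3.0,),
    c2=(0.05, 0.15, 0.3, 0.5),
    tau=(3.0, 7.0, 14.0, 30.0),
    K=(1, 4, 8),
)


def optimize_universal_schedule(training_pop: VirtualPopulation,
                                group: KsGroup | None = None,
                                grid: dict | None = None,
                                horizon: float = 365.0,
                                sim_kwargs: dict | None = None
                                ) -> tuple[ScheduleFamily, pd.DataFrame]:
    """Grid-search a universal schedule family maximizing one-year survival
    on (the k_s stratum of) a training population.

    Returns the best family and the full search table (one row per candidate
    with its survival, cure and toxicity-death rates). Ties are broken
    toward fewer injections, then lower cumulative relative activity.
    """
    pop = training_pop if group is None else training_pop.stratify_ks(group.lo, group.hi)
    if len(pop) == 0:
        raise ValueError("no training mice in the requested k_s group")
    grid = {**DEFAULT_FAMILY_GRID, **(grid or {})}
    sim_kwargs = dict(FAST_SIM_KWARGS if sim_kwargs is None else sim_kwargs)

    rows = []
    best: tuple | None = None
    for c1, c0, c2, tau, K in itertools.product(
            grid["c1"], grid["c0"], grid["c2"], grid["tau"], grid["K"]):
        if K == 1 and (c2, tau) != (grid["c2"][0], grid["tau"][0]):
            continue  # follow-up constants are irrelevant for K=1
        fam = ScheduleFamily(c1, c0, c2, tau, K,
                             label=group.label if group else "all")
        out = run_trial(pop, schedule_strategy(fam), horizon,
                        sim_kwargs=sim_kwargs)
        score = (out.one_year_survival, -K, -(1 + c2 * (K - 1)))
        rows.append({"c1": c1, "c0": c0, "c2": c2, "tau": tau, "K": K,
                     "one_year_survival": out.one_year_survival,
                     "cure_rate": out.cure_rate,
                     "toxicity_death_rate": out.toxicity_death_rate})
        if best is None or score > best[0]:
            best = (score, fam)
    assert best is not None
    return best[1], pd.DataFrame(rows)


def evaluate_schedule(test_pop: VirtualPopulation, family: ScheduleFamily,
                      group: KsGroup | None = None,
                      horizon: float = 365.0,
                      sim_kwargs: dict | None = None) -> TrialOutcome:
    """Apply an optimized family to (the k_s stratum of) a test population."""
    pop = test_pop if group is None else test_pop.stratify_ks(group.lo, group.hi)
    return run_trial(pop, schedule_strategy(family), horizon,
                     label=family.label, sim_kwargs=sim_kwargs)
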