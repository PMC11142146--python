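"""Virtual-mouse populations and in-silico trials.

A virtual mouse is a :class:`~trtsim.params.ModelParameters` record sampled
from the physiologic parameter ranges; a trial runs a dosing strategy on
each mouse of a population and assembles survival and toxicity curves from
the per-mouse endpoints (cancer death at total burden C_d, toxicity death at
cumulative blood decays A_bl_cr, censoring of cured mice at the horizon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import analytics, dosing
from .fixtures import generate_pk_fixture
from .model import DoseSchedule, simulate
from .params import ModelParameters, SWEEP_RANGES, VARIED_PARAMETERS

__all__ = [
    "VirtualPopulation", "sample_population",
    "TrialOutcome", "run_trial",
    "fixed_dose_strategy", "personalized_strategy", "optimized_strategy",
    "find_max_tolerated_dose", "optimize_single_dose_per_mouse",
    "FAST_SIM_KWARGS",
]

#: solver settings used inside population loops: accuracy is traded for
#: speed where only endpoint times and cure flags are needed
FAST_SIM_KWARGS = dict(rtol=1e-6, atol=1e-10, grid_per_day=6,
                       refine_nmin=False)

#: a strategy maps one mouse to the schedule it receives
Strategy = Callable[[ModelParameters], DoseSchedule]


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualPopulation:
    """A seeded, reproducible sample of virtual mice."""

    mice: tuple[ModelParameters, ...]
    seed: int | None
    distribution: str = "log-uniform (k_s uniform)"
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(SWEEP_RANGES))

    def __len__(self) -> int:
        return len(self.mice)

    def __iter__(self):
        return iter(self.mice)

    def subset(self, indices: Sequence[int]) -> "VirtualPopulation":
        return VirtualPopulation(tuple(self.mice[i] for i in indices),
                                 self.seed, self.distribution, self.ranges)

    def stratify_ks(self, lo: float, hi: float) -> "VirtualPopulation":
        """Mice whose k_s falls in [lo, hi)."""
        idx = [i for i, m in enumerate(self.mice) if lo <= m.k_s < hi
               or (hi >= 1.0 and m.k_s == 1.0)]
        return self.subset(idx)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_dict() for m in self.mice])


def sample_population(n: int, seed: int | None = None,
                      ranges: dict[str, tuple[float, float]] | None = None,
                      base: ModelParameters | None = None,
                      eta: float | None = None) -> VirtualPopulation:
    """Draw ``n`` virtual mice from the physiologic ranges.

    Each varied parameter (kappa_c, kappa_p, gamma, V, rho, omega, alpha,
    k_f, N0, k_s) is drawn independently, log-uniformly over its range - the
    ranges span orders of magnitude - except k_s, whose range includes 0 and
    which is drawn uniformly. lambda, k_on and nu stay at their basic values.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    ranges = dict(SWEEP_RANGES if ranges is None else ranges)
    base = base or ModelParameters.basic()
    if eta is not None:
        base = base.replace(eta=eta)
    for name, (lo, hi) in ranges.items():
        if name not in VARIED_PARAMETERS or hi < lo:
            raise ValueError(f"invalid range for {name!r}")
    rng = np.random.default_rng(seed)
    mice = []
    for _ in range(n):
        draw = {}
        for name, (lo, hi) in ranges.items():
            if name == "k_s":
                draw[name] = float(rng.uniform(lo, hi))
            else:
                draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        mice.append(base.replace(**draw))
    return VirtualPopulation(tuple(mice), seed)


# ---------------------------------------------------------------------------
# trial execution
# ---------------------------------------------------------------------------

@dataclass
class TrialOutcome:
    """Per-mouse endpoints and population-level curves of one trial arm."""

    table: pd.DataFrame  #: per-mouse: dose_pmol, survival_time, cause, cured,
                         #: blood_decays_pmol, n_min
    horizon: float
    label: str = ""

    @property
    def one_year_survival(self) -> float:
        return float(np.mean(self.table["survival_time"] >= min(self.horizon, 365.0)))

    @property
    def cure_rate(self) -> float:
        return float(np.mean(self.table["cured"]))

    @property
    def toxicity_death_rate(self) -> float:
        return float(np.mean(self.table["cause"] == "toxicity"))

    def survival_curve(self, days: np.ndarray | None = None) -> pd.DataFrame:
        """Fraction of mice alive, and fraction dead of toxicity, per day."""
        days = np.arange(0.0, self.horizon + 1) if days is None else np.asarray(days)
        t = self.table["survival_time"].to_numpy()
        dead = self.table["cause"].isin(["cancer", "toxicity"]).to_numpy()
        tox = (self.table["cause"] == "toxicity").to_numpy()
        surv = [np.mean(~dead | (t > d)) for d in days]
        toxf = [np.mean(tox & (t <= d)) for d in days]
        return pd.DataFrame({"day": days, "surviving_fraction": surv,
                             "toxicity_fraction": toxf})


def _run_one(mouse: ModelParameters, schedule: DoseSchedule, horizon: float,
             sim_kwargs: dict) -> dict:
    res = simulate(mouse, schedule, horizon, stop_on_death=True,
                   stop_on_toxicity=True, **sim_kwargs)
    cured = res.cured
    cause = res.cause
    if cause == "toxicity":
        survival = res.toxicity_time
    elif cause == "cancer" and not cured:
        survival = res.death_time
    else:
        # cured mice are censored alive: regrowth past the cure threshold is
        # an artifact of the continuum cell count
        cause, survival = "censored", horizon
    return {
        "dose_pmol": schedule.total_activity,
        "n_doses": len(schedule.injections),
        "survival_time": float(survival),
        "cause": cause,
        "cured": bool(cured),
        "blood_decays_pmol": float(res.final_state.cum_blood_decays),
        "n_min": float(res.n_min),
    }


def run_trial(pop: VirtualPopulation, strategy: Strategy,
              horizon: float = 365.0, label: str = "",
              sim_kwargs: dict | None = None) -> TrialOutcome:
    """Treat every mouse of ``pop`` with ``strategy`` and collect endpoints."""
    sim_kwargs = dict(FAST_SIM_KWARGS if sim_kwargs is None else sim_kwargs)
    rows = []
    for i, mouse in enumerate(pop):
        row = {"mouse": i, "k_s": mouse.k_s,
               "capacity_pmol": mouse.binding_capacity}
        row.update(_run_one(mouse, strategy(mouse), horizon, sim_kwargs))
        rows.append(row)
    return TrialOutcome(pd.DataFrame(rows), horizon, label)


# ---------------------------------------------------------------------------
# dosing strategies
# ---------------------------------------------------------------------------

def fixed_dose_strategy(A_pmol: float) -> Strategy:
    """One-size-fits-all single dose at t = 0."""
    def strategy(mouse: ModelParameters) -> DoseSchedule:
        return DoseSchedule.single(A_pmol)
    return strategy


def personalized_strategy(noise_cv: float = 0.0, seed: int | None = None,
                          use_true_capacity: bool = False,
                          ranges: analytics.SafeDoseRanges | None = None) -> Strategy:
    """Capacity-personalized single dose.

    The binding capacity gamma*N0 is either taken as known
    (``use_true_capacity``) or estimated per mouse from a synthetic
    diagnostic PK curve with the given measurement noise; the dose follows
    the personalized rule with its worst-case safety cap.
    """
    rng = np.random.default_rng(seed)

    def strategy(mouse: ModelParameters) -> DoseSchedule:
        if use_true_capacity:
            capacity = mouse.binding_capacity
        else:
            pk = generate_pk_fixture(mouse, noise_cv=noise_cv,
                                     seed=int(rng.integers(2 ** 31)))
            capacity = dosing.estimate_binding_capacity(
                pk, mouse.k_on, mouse.V, mouse.lambda_decay, mouse.kappa_c)
        A = dosing.personalized_dose(capacity, mouse.eta, mouse, ranges)
        return DoseSchedule.single(A)
    return strategy


def optimized_strategy(horizon: float = 365.0, **kwargs) -> Strategy:
    """Per-mouse numerically optimized single dose (full parameter
    knowledge)."""
    def strategy(mouse: ModelParameters) -> DoseSchedule:
        A = optimize_single_dose_per_mouse(mouse, horizon=horizon, **kwargs)
        return DoseSchedule.single(A)
    return strategy


# ---------------------------------------------------------------------------
# maximum tolerated dose
# ---------------------------------------------------------------------------

def _toxicity_death(mouse: ModelParameters, A_pmol: float, horizon: float,
                    sim_kwargs: dict) -> tuple[bool, float]:
    """(died of toxicity, blood decays at end/death) for a single dose."""
    res = simulate(mouse, DoseSchedule.single(A_pmol), horizon,
                   stop_on_death=True, stop_on_toxicity=True, **sim_kwargs)
    return res.cause == "toxicity", float(res.final_state.cum_blood_decays)


def _certified_floor(pop: VirtualPopulation, params: ModelParameters) -> float:
    """A dose certainly tolerated by every sampled mouse: blood decays are
    bounded by A*(intact + fragment worst-case fractions) over the sampled
    parameter values."""
    lam = params.lambda_decay
    kc_min = min(m.kappa_c for m in pop)
    om_max = max(m.omega for m in pop)
    kp_min = min(m.kappa_p for m in pop)
    f_intact = lam / (lam + kc_min)
    f_frag = om_max * lam / ((lam + om_max) * (lam + kp_min))
    return params.A_bl_cr / (f_intact + f_frag)

_MTD_SIM_KWARGS = dict(rtol=1e-6, atol=1e-10, grid_per_day=1,
                       refine_nmin=False)


def find_max_tolerated_dose(pop: VirtualPopulation,
                            tol_nCi: float = 0.5,
                            horizon: float = 365.0,
                            top_k: int = 50,
                            sim_kwargs: dict | None = None) -> float:
    """Largest uniform single dose (pmol) causing no toxicity deaths in
    ``pop``.

    The population maximum of blood decays is monotone in the dose, so the
    MTD is located by bisection. To avoid simulating every mouse at every
    trial dose, mice are ranked by their blood-decay load at a certainly-safe
    probe dose and only the ``top_k`` most toxicity-prone mice drive the
    bisection; the result is then certified on the full population (and the
    search resumed with the offending mice included in the unlikely event
    the ranking missed one).
    """
    if len(pop) == 0:
        raise ValueError("population is empty")
    sim_kwargs = dict(_MTD_SIM_KWARGS if sim_kwargs is None else sim_kwargs)
    params = pop.mice[0]
    lam = params.lambda_decay
    tol_pmol = analytics.pmol_from_activity_nCi(tol_nCi, lam)

    lo = _certified_floor(pop, params)
    loads = np.array([_toxicity_death(m, lo, horizon, sim_kwargs)[1]
                      for m in pop])
    order = np.argsort(loads)[::-1]
    candidates = set(order[:top_k].tolist())

    def any_toxic(A: float, idx: set[int]) -> int | None:
        for i in sorted(idx, key=lambda j: -loads[j]):
            if _toxicity_death(pop.mice[i], A, horizon, sim_kwargs)[0]:
                return i
        return None

    hi = lo * 2.0
    while any_toxic(hi, candidates) is None:
        lo, hi = hi, hi * 2.0
        if hi > 1e3:
            raise RuntimeError("no toxic dose found; population degenerate")

    while True:
        a, b = lo, hi
        while b - a > tol_pmol:
            mid = 0.5 * (a + b)
            if any_toxic(mid, candidates) is None:
                a = mid
            else:
                b = mid
        offender = any_toxic(a, set(range(len(pop))) - candidates)
        if offender is None:
            return a
        candidates.add(offender)
        hi = a  # the certified interval shrinks below the failing dose


# ---------------------------------------------------------------------------
# per-mouse single-dose optimization
# ---------------------------------------------------------------------------

def optimize_single_dose_per_mouse(mouse: ModelParameters,
                                   horizon: float = 365.0,
                                   rel_tol: float = 1e-2,
                                   sim_kwargs: dict | None = None) -> float:
    """Optimal single dose for one mouse with full parameter knowledge.

    Returns the smallest curative dose below the mouse's individual toxicity
    limit if one exists, otherwise the dose maximizing survival time over
    the tolerated interval (golden-section search).
    """
    sim_kwargs = dict(FAST_SIM_KWARGS if sim_kwargs is None else sim_kwargs)

    # individual toxicity limit by bisection
    lam = mouse.lambda_decay
    f_intact = lam / (lam + mouse.kappa_c)
    f_frag = mouse.omega * lam / ((lam + mouse.omega) * (lam + mouse.kappa_p))
    lo = mouse.A_bl_cr / (f_intact + f_frag)
    hi = lo * 2.0
    while not _toxicity_death(mouse, hi, horizon, _MTD_SIM_KWARGS)[0]:
        lo, hi = hi, hi * 2.0
        if hi > 1e4:
            break
    while hi - lo > rel_tol * lo:
        mid = 0.5 * (lo + hi)
        if _toxicity_death(mouse, mid, horizon, _MTD_SIM_KWARGS)[0]:
            hi = mid
        else:
            lo = mid
    limit = lo

    cure_kwargs = dict(sim_kwargs, refine_nmin=True, grid_per_day=8)
    res_at_limit = simulate(mouse, DoseSchedule.single(limit), horizon,
                            stop_on_death=True, **cure_kwargs)
    if res_at_limit.cured:
        r = dosing.find_minimal_curative_dose(
            mouse, horizon=horizon, bracket=(limit / 1e3, limit),
            rel_tol=rel_tol, **cure_kwargs)
        # the root is knife-edge by construction; pad it by twice the search
        # tolerance so the cure is robust to evaluation resolution
        return min(r.A_cur_pmol * (1.0 + 2.0 * rel_tol), limit)

    def neg_survival(A: float) -> float:
        row = _run_one(mouse, DoseSchedule.single(float(A)), horizon, sim_kwargs)
        return -row["survival_time"]

    res = minimize_scalar(neg_survival, bounds=(0.0, limit), method="bounded",
                          options={"xatol": max(rel_tol * limit, 1e-6)})
    # compare against the endpoint: survival can be monotone up to the limit
    return float(res.x) if neg_survival(limit) > res.fun else limit
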