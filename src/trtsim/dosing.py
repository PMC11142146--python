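"""Single-dose design: curative-dose search, impurity sweeps, PK-based
capacity estimation and the capacity-based personalized dose rule."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import analytics
from .constants import AVOGADRO_PER_PMOL
from .model import DoseSchedule, SimulationResult, simulate
from .params import ModelParameters

log = logging.getLogger(__name__)

__all__ = [
    "CurativeDoseResult", "find_minimal_curative_dose",
    "radioconjugates_per_cell", "impurity_sweep",
    "PKObservation", "estimate_binding_capacity", "personalized_dose",
]


def radioconjugates_per_cell(A_pmol: float, n_cells: float) -> float:
    """Convert an injected activity (pmol) into radioconjugate molecules per
    cell, for ``n_cells`` absolute cells (not 1e7 units)."""
    if n_cells <= 0:
        raise ValueError("cell count must be > 0")
    if A_pmol < 0:
        raise ValueError("dose must be >= 0")
    return A_pmol * AVOGADRO_PER_PMOL / n_cells


@dataclass
class CurativeDoseResult:
    """Outcome of the minimal-curative-dose bisection."""

    A_cur_pmol: float
    A_cur_nCi: float
    n_min: float                 #: minimal viable count at A_cur (1e7 cells)
    per_cell: float              #: radioconjugate molecules per initial cell
    converged: bool
    bracket: tuple[float, float]
    eta: float
    result: SimulationResult | None = field(default=None, repr=False)


_EVALS = 0  # bisection bookkeeping for logging


def _nmin_log_gap(A: float, params: ModelParameters, eta: float,
                  injection_time: float, horizon: float,
                  sim_kwargs: dict) -> tuple[float, SimulationResult]:
    global _EVALS
    _EVALS += 1
    res = simulate(params, DoseSchedule.single(A, injection_time, eta=eta),
                   horizon, **sim_kwargs)
    n_min = max(res.n_min, 1e-300)
    return math.log(n_min / params.N_cur), res


def find_minimal_curative_dose(params: ModelParameters,
                               eta: float | None = None,
                               injection_time: float = 0.0,
                               horizon: float = 365.0,
                               bracket: tuple[float, float] = (1e-5, 1.0),
                               rel_tol: float = 1e-4,
                               max_expand: int = 12,
                               **sim_kwargs) -> CurativeDoseResult:
    """Find the minimal single curative dose A_cur by bisection.

    A_cur is the injected activity for which the minimum of viable cells over
    the horizon equals the cure threshold N_cur. The root of
    ``log(N_min(A)/N_cur)`` is located with Brent's method on a bracket that
    is expanded geometrically until it straddles the root; N_min(A) is
    monotone decreasing in the dose in the regimes of interest, and a
    post-hoc certificate (0.99*A_cur does not cure, A_cur does) guards
    against silent failure elsewhere.

    Raises
    ------
    RuntimeError
        If no curative dose exists within the expanded bracket (e.g. k_f = 0
        with injected antibodies exceeding the total receptor amount).
    """
    global _EVALS
    eta = params.eta if eta is None else eta
    sim_kwargs.setdefault("stop_on_death", True)
    lo, hi = bracket
    _EVALS = 0

    g_lo, _ = _nmin_log_gap(lo, params, eta, injection_time, horizon, sim_kwargs)
    while g_lo <= 0 and max_expand:
        hi, lo = lo, lo / 10.0
        g_lo, _ = _nmin_log_gap(lo, params, eta, injection_time, horizon, sim_kwargs)
        max_expand -= 1
    g_hi, res_hi = _nmin_log_gap(hi, params, eta, injection_time, horizon, sim_kwargs)
    while g_hi > 0 and max_expand:
        lo, hi = hi, hi * 10.0
        g_hi, res_hi = _nmin_log_gap(hi, params, eta, injection_time, horizon, sim_kwargs)
        max_expand -= 1
    if g_lo <= 0 or g_hi > 0:
        raise RuntimeError(
            f"no curative dose within bracket ({lo:g}, {hi:g}) pmol: "
            f"log-gaps ({g_lo:.3g}, {g_hi:.3g}); with k_f=0 cure is "
            "impossible once injected antibodies exceed the receptor amount")

    A_cur = brentq(
        lambda A: _nmin_log_gap(A, params, eta, injection_time, horizon,
                                sim_kwargs)[0],
        lo, hi, rtol=rel_tol, xtol=1e-30)

    _, res = _nmin_log_gap(A_cur, params, eta, injection_time, horizon, sim_kwargs)
    gap_below, _ = _nmin_log_gap(A_cur * 0.99, params, eta, injection_time,
                                 horizon, sim_kwargs)
    converged = gap_below > 0
    log.info("curative-dose bisection: A_cur=%.4g pmol after %d simulations "
             "(bracket %.3g-%.3g)", A_cur, _EVALS, lo, hi)
    if not converged:
        warnings.warn("N_min(A) not locally monotone at the root; "
                      "curative dose may not be minimal", stacklevel=2)
    return CurativeDoseResult(
        A_cur_pmol=A_cur,
        A_cur_nCi=analytics.activity_nCi_from_pmol(A_cur, params.lambda_decay),
        n_min=res.n_min,
        per_cell=radioconjugates_per_cell(A_cur, params.N0 * 1e7),
        converged=converged, bracket=(lo, hi), eta=eta, result=res,
    )


def impurity_sweep(params: ModelParameters, eta_grid: Sequence[float],
                   horizon: float = 365.0, rel_tol: float = 1e-4,
                   **sim_kwargs) -> pd.DataFrame:
    """Minimal curative dose and its toxicity accounting across impurity
    levels.

    Returns one row per eta with columns ``eta, A_cur_pmol, A_cur_nCi,
    per_cell, blood_decays_pmol, blood_over_lethal, viable_fraction, cured``.
    Where no finite dose cures (possible for k_f = 0 once antibodies exceed
    the receptor pool) the dose columns are NaN and ``cured`` is False.
    """
    rows = []
    for eta in eta_grid:
        if not math.isfinite(eta) or eta < 0:
            raise ValueError(f"invalid eta {eta!r}")
        try:
            r = find_minimal_curative_dose(params, eta=eta, horizon=horizon,
                                           rel_tol=rel_tol, **sim_kwargs)
            final = r.result.final_state
            rows.append({
                "eta": eta, "A_cur_pmol": r.A_cur_pmol,
                "A_cur_nCi": r.A_cur_nCi, "per_cell": r.per_cell,
                "blood_decays_pmol": final.cum_blood_decays,
                "blood_over_lethal": final.cum_blood_decays / params.A_bl_cr,
                "viable_fraction": final.cum_viable_decays / r.A_cur_pmol,
                "cured": True,
            })
        except RuntimeError:
            rows.append({
                "eta": eta, "A_cur_pmol": math.nan, "A_cur_nCi": math.nan,
                "per_cell": math.nan, "blood_decays_pmol": math.nan,
                "blood_over_lethal": math.nan, "viable_fraction": math.nan,
                "cured": False,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pharmacokinetic capacity estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKObservation:
    """Sampled plasma concentrations of a small diagnostic radioconjugate
    dose during the binding phase."""

    times: np.ndarray          #: days, strictly increasing
    concentrations: np.ndarray #: nM, > 0
    noise: str = "none"        #: descriptor of the noise model applied
    true_capacity: float | None = None  #: generating gamma*N0, if synthetic

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and concentrations must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def estimate_binding_capacity(pk: PKObservation, k_on: float, V: float,
                              lambda_decay: float, kappa_c: float) -> float:
    """Estimate the cancer binding capacity gamma*N0 (pmol) from a diagnostic
    pharmacokinetic curve.

    During the binding phase of a dose occupying a negligible receptor
    fraction, plasma concentration decays single-exponentially at
    ``k_obs = lambda + kappa_c + k_on*gamma*N0/V``. The slope is fitted by
    ordinary least squares on log-concentration and inverted for gamma*N0.
    Returns 0 (with a warning) when the fitted rate does not exceed
    lambda + kappa_c, i.e. no receptor sink is detectable.
    """
    if pk.times.size < 3:
        raise ValueError("need at least 3 observations in the binding phase")
    if np.any(pk.concentrations <= 0):
        raise ValueError("concentrations must be positive for log-linear fit")
    slope, _ = np.polyfit(pk.times, np.log(pk.concentrations), 1)
    k_obs = -slope
    capacity = (k_obs - lambda_decay - kappa_c) * V / k_on
    if capacity < 0:
        warnings.warn(
            f"fitted decay rate {k_obs:.3g}/day below lambda+kappa_c="
            f"{lambda_decay + kappa_c:.3g}/day; returning capacity 0",
            stacklevel=2)
        return 0.0
    return capacity


def personalized_dose(capacity_pmol: float, eta: float,
                      params: ModelParameters,
                      ranges: analytics.SafeDoseRanges | None = None,
                      slope: float = 1.5, intercept_pmol: float = 3.0) -> float:
    """Capacity-based personalized single dose (pmol of activity).

    The antibody amount is tailored to the binding capacity as
    ``slope*capacity + intercept`` (the intercept compensates for slow drug
    binding when few receptors are present), divided by eta+1 to get the
    active share, and capped at the worst-case maximal safe dose for that
    capacity. The rule is non-decreasing in capacity.
    """
    if capacity_pmol < 0:
        raise ValueError("capacity must be >= 0")
    uncapped = (slope * capacity_pmol + intercept_pmol) / (eta + 1.0)
    cap = analytics.max_safe_dose(capacity_pmol, params, ranges, eta=eta)
    return min(uncapped, cap)


def treatment_metrics(result: SimulationResult) -> dict[str, float]:
    """Efficiency measures of a single-dose treatment course.

    Evaluated at the time of the viable-cell minimum (the effective end of
    treatment; afterwards the integrals accumulate regrowth, not therapy):

    * ``born_fraction``: cells born during treatment over N0,
    * ``viable_fraction``: share of injected activity decaying on
      viable-cell receptors (bounded by 1/ln(N0/N_cur) for curative doses),
    * ``blood_over_lethal``: cumulative blood decays over A_bl_cr at the
      end of the simulated horizon.
    """
    injected = result.schedule.total_activity
    t_star = result.t_nmin
    born = float(np.interp(t_star, result.t, result.states[:, 12]))
    viable = float(np.interp(t_star, result.t, result.states[:, 10]))
    return {
        "t_nmin": t_star,
        "born_fraction": born / result.params.N0,
        "viable_fraction": viable / injected if injected > 0 else 0.0,
        "blood_over_lethal": result.final_state.cum_blood_decays
        / result.params.A_bl_cr,
    }
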