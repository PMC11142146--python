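"""Core dynamics: receptor-binding ODE system, bolus injections, integration.

The model tracks radiolabeled ("active") and unlabeled/decayed ("inert")
antibodies in plasma, their binding to receptors of viable and damaged cancer
cells, continuous radiation damage from three sources (self-damage, cross-fire
and unanchored nuclides), damaged-cell death with release of radioactive
antibody fragments, and cumulative bookkeeping of where decays occur.

State variables (normalized units: days, ml, pmol, nM, 1e7 cells)::

    a, b, p          plasma concentrations: active antibodies, inert
                     antibodies, active fragments (nM)
    N, D             viable / damaged cancer cells (1e7 cells)
    f_FN, f_AN       free / active receptor fractions on viable cells
    f_FD, f_AD       free / active receptor fractions on damaged cells

Internally the damaged-cell receptor *fractions* are replaced by the absolute
free/active receptor amounts per cell unit ``FD = D*f_FD`` and ``AD = D*f_AD``,
which removes the ``RD*N/D`` singularity of the fraction equations at D -> 0
exactly rather than through an epsilon guard.

Four auxiliary integrals are carried along: cumulative decays of unanchored
(plasma-resident) nuclides in pmol, cumulative decays on viable-cell and on
damaged-cell receptors in pmol, and cumulative newborn viable cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .params import ModelParameters

__all__ = [
    "ModelState",
    "DoseSchedule",
    "SimulationResult",
    "SolverFailure",
    "radiation_damage",
    "rhs",
    "apply_injection",
    "simulate",
    "STATE_COLUMNS",
]

#: column order used by trajectory tables
STATE_COLUMNS = (
    "a", "b", "p", "N", "D", "f_FN", "f_AN", "f_FD", "f_AD",
    "cum_blood_decays", "cum_viable_decays", "cum_damaged_decays",
    "cum_cells_born",
)

# damaged-cell count below which receptor fractions on damaged cells are
# reported as the fresh-damage limit (f_FD = f_FN, f_AD = f_AN)
_D_FLOOR = 1e-12


log = logging.getLogger(__name__)


class SolverFailure(RuntimeError):
    """Raised when the ODE solver fails on some integration interval."""


# ---------------------------------------------------------------------------
# right-hand side (internal representation)
# ---------------------------------------------------------------------------

def _rhs_internal(t: float, y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vector field in the internal (FD/AD product) representation.

    ``q`` packs [lambda, k_on, kappa_c, kappa_p, gamma, V, nu, k_s, rho,
    omega, alpha, k_f].
    """
    lam, kon, kc, kp, gam, V, nu, ks, rho, omega, alpha, kf = (
        q[0], q[1], q[2], q[3], q[4], q[5], q[6], q[7], q[8], q[9], q[10], q[11]
    )
    a, b, p, N, D = y[0], y[1], y[2], y[3], y[4]
    fFN, fAN, FD, AD = y[5], y[6], y[7], y[8]

    total = N + D
    if total > 0.0:
        crossfire = lam * gam * (fAN * N + AD) / (nu * total)
    else:
        crossfire = 0.0
    RD = alpha * (ks * lam * gam * fAN / nu
                  + (1.0 - ks) * crossfire
                  + kf * lam * (a + p))

    free_receptors = gam * (fFN * N + FD) / V  # nM-equivalent binding sink

    out = np.empty(13)
    out[0] = -lam * a - kon * a * free_receptors - kc * a
    out[1] = lam * a - kon * b * free_receptors - kc * b
    out[2] = omega * gam * AD / V - lam * p - kp * p
    out[3] = rho * N - RD * N
    out[4] = RD * N - omega * D
    out[5] = (1.0 - fFN) * rho - kon * (a + b) * fFN
    out[6] = kon * a * fFN - (lam + rho) * fAN
    out[7] = RD * N * fFN - kon * (a + b) * FD - omega * FD
    out[8] = RD * N * fAN + kon * a * FD - (lam + omega) * AD
    out[9] = lam * (a + p) * V
    out[10] = lam * gam * fAN * N
    out[11] = lam * gam * AD
    out[12] = rho * N
    return out


try:  # pragma: no cover - exercised implicitly whenever numba is present
    from numba import njit as _njit

    _rhs_internal = _njit("f8[:](f8, f8[:], f8[:])", cache=True)(_rhs_internal)
except Exception:  # pragma: no cover
    pass


def _pack_params(params: ModelParameters) -> np.ndarray:
    return np.array([
        params.lambda_decay, params.k_on, params.kappa_c, params.kappa_p,
        params.gamma, params.V, params.nu, params.k_s, params.rho,
        params.omega, params.alpha, params.k_f,
    ])


# ---------------------------------------------------------------------------
# public state container
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Model state in the natural (receptor-fraction) representation."""

    a: float = 0.0
    b: float = 0.0
    p: float = 0.0
    N: float = 0.0
    D: float = 0.0
    f_FN: float = 1.0
    f_AN: float = 0.0
    f_FD: float = 1.0
    f_AD: float = 0.0
    cum_blood_decays: float = 0.0
    cum_viable_decays: float = 0.0
    cum_damaged_decays: float = 0.0
    cum_cells_born: float = 0.0

    @classmethod
    def initial(cls, params: ModelParameters) -> "ModelState":
        """Pre-treatment state: N0 viable cells, all receptors free, no drug."""
        return cls(N=params.N0)

    def validate(self, tol: float = 1e-6) -> None:
        for name in STATE_COLUMNS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"non-finite state component {name}={value!r}")
            if value < -tol:
                raise ValueError(f"negative state component {name}={value!r}")
        if self.f_FN + self.f_AN > 1 + tol or self.f_FD + self.f_AD > 1 + tol:
            raise ValueError("receptor fractions exceed 1")

    def to_internal(self) -> np.ndarray:
        return np.array([
            self.a, self.b, self.p, self.N, self.D,
            self.f_FN, self.f_AN,
            self.D * self.f_FD, self.D * self.f_AD,
            self.cum_blood_decays, self.cum_viable_decays,
            self.cum_damaged_decays, self.cum_cells_born,
        ])

    @classmethod
    def from_internal(cls, y: Sequence[float]) -> "ModelState":
        a, b, p, N, D, fFN, fAN, FD, AD = y[:9]
        if D > _D_FLOOR:
            fFD, fAD = FD / D, AD / D
        else:
            # fresh-damage limit: newly damaged cells inherit viable-cell
            # occupancies
            fFD, fAD = fFN, fAN
        return cls(a, b, p, N, D, fFN, fAN, fFD, fAD, *y[9:13])

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_COLUMNS])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def radiation_damage(state: ModelState, params: ModelParameters) -> float:
    """Radiation damage rate RD (1/day) experienced by viable cells.

    Sums three sources: self-damage from decays on a cell's own receptors,
    cross-fire from decays on neighboring (viable and damaged) cells, and
    decays of unanchored nuclides in plasma. The cross-fire term is defined
    as 0 when no cells are present.
    """
    state.validate()
    lam, gam, nu = params.lambda_decay, params.gamma, params.nu
    total = state.N + state.D
    self_damage = lam * gam * state.f_AN / nu
    if total > 0:
        crossfire = lam * gam * (state.f_AN * state.N + state.f_AD * state.D) / (nu * total)
    else:
        crossfire = 0.0
    unanchored = params.k_f * lam * (state.a + state.p)
    return params.alpha * (params.k_s * self_damage
                           + (1.0 - params.k_s) * crossfire
                           + unanchored)


def rhs(state: ModelState, params: ModelParameters) -> ModelState:
    """Time derivative of the state between injections.

    Returns a :class:`ModelState` whose fields hold d(state)/dt. The
    damaged-cell fraction derivatives use the exact product formulation
    internally; at D=0 the damage-transfer terms are reported as 0.
    """
    state.validate()
    y = state.to_internal()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    dy = _rhs_internal(0.0, y, _pack_params(params))
    D = state.D
    out = ModelState(*dy[:5], dy[5], dy[6], 0.0, 0.0, *dy[9:13])
    if D > _D_FLOOR:
        # d(f)/dt = (d(D f)/dt - f dD/dt) / D
        out.f_FD = (dy[7] - state.f_FD * dy[4]) / D
        out.f_AD = (dy[8] - state.f_AD * dy[4]) / D
    return out


def apply_injection(state: ModelState, amount_pmol: float, eta: float,
                    V: float) -> ModelState:
    """Instantaneous bolus: active concentration rises by amount/V, inert by
    eta*amount/V; everything else is unchanged."""
    if amount_pmol < 0:
        raise ValueError(f"injection amount must be >= 0, got {amount_pmol!r}")
    if eta < 0 or V <= 0:
        raise ValueError("eta must be >= 0 and V > 0")
    new = ModelState(**{k: getattr(state, k) for k in STATE_COLUMNS})
    new.a += amount_pmol / V
    new.b += eta * amount_pmol / V
    return new


# ---------------------------------------------------------------------------
# schedules and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseSchedule:
    """Ordered bolus injections of (time in days, active amount in pmol)."""

    injections: tuple[tuple[float, float], ...]
    eta_override: float | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.injections]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("injection times must be strictly increasing")
        if any(a < 0 for _, a in self.injections):
            raise ValueError("injection amounts must be >= 0")
        object.__setattr__(self, "injections", tuple(
            (float(t), float(a)) for t, a in self.injections))

    @classmethod
    def single(cls, amount_pmol: float, time: float = 0.0,
               eta: float | None = None) -> "DoseSchedule":
        return cls(((time, amount_pmol),), eta_override=eta)

    @classmethod
    def empty(cls) -> "DoseSchedule":
        return cls(())

    def eta(self, params: ModelParameters) -> float:
        return params.eta if self.eta_override is None else self.eta_override

    @property
    def total_activity(self) -> float:
        """Cumulative injected active amount, pmol."""
        return sum(a for _, a in self.injections)


@dataclass
class SimulationResult:
    """Trajectory plus treatment endpoints of one simulated course."""

    t: np.ndarray
    states: np.ndarray                   # (len(t), 13) in STATE_COLUMNS order
    n_min: float
    t_nmin: float
    cured: bool
    death_time: float | None
    toxicity_time: float | None
    horizon: float
    params: ModelParameters
    schedule: DoseSchedule

    @property
    def survival_time(self) -> float:
        candidates = [self.horizon]
        if self.death_time is not None:
            candidates.append(self.death_time)
        if self.toxicity_time is not None:
            candidates.append(self.toxicity_time)
        return min(candidates)

    @property
    def cause(self) -> str:
        """'cancer' | 'toxicity' | 'censored' - earliest endpoint wins."""
        d = math.inf if self.death_time is None else self.death_time
        x = math.inf if self.toxicity_time is None else self.toxicity_time
        if d == x == math.inf:
            return "censored"
        return "toxicity" if x <= d else "cancer"

    @property
    def final_state(self) -> ModelState:
        return ModelState(*self.states[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=list(STATE_COLUMNS)).assign(
            time=self.t)[["time", *STATE_COLUMNS]]


# ---------------------------------------------------------------------------
# piecewise integration with events
# ---------------------------------------------------------------------------

def _fractions_from_internal(Y: np.ndarray) -> np.ndarray:
    """Convert (n, 13) internal trajectory rows to the public representation."""
    out = Y.copy()
    D = Y[:, 4]
    fFD = np.where(D > _D_FLOOR, Y[:, 7] / np.maximum(D, _D_FLOOR), Y[:, 5])
    fAD = np.where(D > _D_FLOOR, Y[:, 8] / np.maximum(D, _D_FLOOR), Y[:, 6])
    out[:, 7] = fFD
    out[:, 8] = fAD
    return out


def simulate(params: ModelParameters,
             schedule: DoseSchedule | None = None,
             horizon: float = 365.0,
             *,
             initial_state: ModelState | None = None,
             rtol: float = 1e-8,
             atol: float = 1e-12,
             grid_per_day: float = 20.0,
             refine_nmin: bool = True,
             stop_on_death: bool = True,
             stop_on_toxicity: bool = False,
             n_floor_factor: float = 1e-3,
             method: str = "LSODA") -> SimulationResult:
    """Integrate the model over ``[0, horizon]`` under a dose schedule.

    Injections are events: the system is integrated on the open intervals
    between injection times and the plasma concentrations jump at each bolus;
    delta functions never enter the vector field. Crossings of the lethal
    burden ``C_d`` (total cells N+D) and of the lethal blood-decay amount
    ``A_bl_cr`` are located by the solver's event machinery. The global
    minimum of viable cells N is taken over a dense output grid
    (``grid_per_day`` points per day) and refined on the solver's dense
    output around the grid argmin.

    Parameters
    ----------
    stop_on_death, stop_on_toxicity:
        Whether the corresponding endpoint terminates the integration. Death
        is terminal by default; toxicity is recorded but, unless requested,
        the dynamics continue (a dose can be curative and lethally toxic at
        the same time).
    n_floor_factor:
        Strongly supra-curative doses drive N far below any meaningful
        count; once N < n_floor_factor * N_cur the cure outcome is decided
        and the integration stops. Set to 0 to disable.
    """
    schedule = schedule if schedule is not None else DoseSchedule.empty()
    if schedule.injections and horizon <= schedule.injections[-1][0]:
        raise ValueError("horizon must exceed the last injection time")
    eta = schedule.eta(params)
    state = initial_state if initial_state is not None else ModelState.initial(params)
    q = _pack_params(params)

    def death_event(t, y, *_):
        return y[3] + y[4] - params.C_d

    def toxicity_event(t, y, *_):
        return y[9] - params.A_bl_cr

    death_event.terminal = stop_on_death
    death_event.direction = 1.0
    toxicity_event.terminal = stop_on_toxicity
    toxicity_event.direction = 1.0

    n_floor = n_floor_factor * params.N_cur

    def eradication_event(t, y, *_):
        return y[3] - n_floor

    eradication_event.terminal = True
    eradication_event.direction = -1.0
    event_funcs = (death_event, toxicity_event) + (
        (eradication_event,) if n_floor > 0 else ())

    # integration breakpoints: injection times, then the horizon. Injections
    # closer than ~0.1 s to each other (or to t=0 / the horizon) are merged
    # onto one breakpoint: they are physically simultaneous and micro-segments
    # stall the step-size selection.
    min_gap = 1e-6
    merged: list[list[float]] = []
    for t, a in schedule.injections:
        te = 0.0 if t < min_gap else min(t, horizon - min_gap)
        if merged and te - merged[-1][0] < min_gap:
            merged[-1][1] += a
        else:
            merged.append([te, a])
    injections_at = {t: a for t, a in merged}
    breaks: list[float] = sorted(t for t in injections_at if 0.0 < t < horizon)
    segments = [0.0, *breaks, horizon]

    y = state.to_internal()
    if 0.0 in injections_at:
        log.info("injection at t=0: %.4g pmol active (eta=%g)",
                 injections_at[0.0], eta)
        s = apply_injection(ModelState.from_internal(y), injections_at[0.0], eta, params.V)
        y = s.to_internal()

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    death_time: float | None = None
    toxicity_time: float | None = None
    n_min, t_nmin = math.inf, 0.0

    for t0, t1 in zip(segments[:-1], segments[1:]):
        n_pts = max(int(math.ceil((t1 - t0) * grid_per_day)), 2)
        t_eval = np.linspace(t0, t1, n_pts + 1)
        sol = solve_ivp(
            _rhs_internal, (t0, t1), y, method=method, t_eval=t_eval,
            dense_output=refine_nmin, rtol=rtol, atol=atol, args=(q,),
            events=event_funcs,
        )
        if not sol.success:
            raise SolverFailure(
                f"solver failed on [{t0}, {t1}]: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y.T)

        if sol.t_events[0].size and death_time is None:
            death_time = float(sol.t_events[0][0])
            log.info("lethal burden C_d crossed at t=%.3f d", death_time)
        if sol.t_events[1].size and toxicity_time is None:
            toxicity_time = float(sol.t_events[1][0])
            log.info("lethal blood decays A_bl_cr crossed at t=%.3f d",
                     toxicity_time)

        # track / refine global minimum of N on this segment
        seg_N = sol.y[3]
        i = int(np.argmin(seg_N))
        if seg_N[i] < n_min:
            n_min, t_nmin = float(seg_N[i]), float(sol.t[i])
        if refine_nmin and sol.sol is not None and 0 < i < len(sol.t) - 1:
            bracket = (sol.t[i - 1], sol.t[i + 1])
            res = minimize_scalar(
                lambda tt: float(sol.sol(tt)[3]), bounds=bracket,
                method="bounded", options={"xatol": 1e-6})
            if res.fun < n_min:
                n_min, t_nmin = float(res.fun), float(res.x)

        y = sol.y[:, -1].copy()
        if sol.status == 1:  # terminated by an event: append the event state
            for k, te in enumerate(sol.t_events):
                if te.size and sol.y_events[k].size:
                    ts.append(te[:1])
                    ys.append(sol.y_events[k][:1])
                    if k == 2:  # eradication: N at the floor is the minimum
                        n_min = min(n_min, float(sol.y_events[k][0][3]))
                        t_nmin = float(te[0])
            break
        if t1 in injections_at:
            log.info("injection at t=%.3f d: %.4g pmol active (eta=%g)",
                     t1, injections_at[t1], eta)
            s = apply_injection(ModelState.from_internal(y), injections_at[t1], eta, params.V)
            y = s.to_internal()
            if death_time is None:
                # drop the duplicated breakpoint row; the post-jump state opens
                # the next segment
                ts[-1] = ts[-1][:-1]
                ys[-1] = ys[-1][:-1]

    t_arr = np.concatenate(ts) if ts else np.array([0.0])
    y_arr = np.vstack(ys) if ys else state.to_internal()[None, :]
    # deduplicate identical consecutive times (event-terminated edges)
    keep = np.concatenate(([True], np.diff(t_arr) > 0))
    t_arr, y_arr = t_arr[keep], y_arr[keep]

    n_min = min(n_min, float(np.min(y_arr[:, 3])))
    cured = n_min < params.N_cur
    return SimulationResult(
        t=t_arr, states=_fractions_from_internal(y_arr), n_min=n_min,
        t_nmin=t_nmin, cured=cured, death_time=death_time,
        toxicity_time=toxicity_time, horizon=horizon, params=params,
        schedule=schedule,
    )
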