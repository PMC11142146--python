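"""Closed-form results and unit conversions.

Everything here is algebra on the model parameters - no ODE integration:
activity/amount conversions, the impurity coefficient implied by a labeling
ratio, minimal-surviving-fraction estimates for the self-damage-only and
cross-fire-only regimes, the decays-in-blood decomposition, worst-case safe
dose bounds, and the long-term curability condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .constants import (AVOGADRO_PER_PMOL, BQ_PER_NCI,
                        IGG_MOLAR_MASS_G_PER_MOL, SECONDS_PER_DAY)
from .params import ModelParameters, SWEEP_RANGES

__all__ = [
    "activity_nCi_from_pmol", "pmol_from_activity_nCi",
    "eta_from_labeling_ratio", "receptors_per_cell",
    "surviving_fraction_selfdamage", "surviving_fraction_crossfire",
    "BloodDecayFractions", "blood_decay_fraction",
    "viable_fraction_bound", "SafeDoseRanges", "max_safe_dose",
    "CurabilityCheck", "curability_condition",
]


# ---------------------------------------------------------------------------
# activity conversions
# ---------------------------------------------------------------------------

def activity_nCi_from_pmol(n_pmol: float, lambda_decay: float) -> float:
    """Instantaneous activity (nCi) of ``n_pmol`` of a nuclide decaying at
    ``lambda_decay`` per day. 0.0175 pmol of ^225^Ac (lambda = 0.07/day) is
    ~230 nCi."""
    if n_pmol < 0:
        raise ValueError("amount must be >= 0")
    decays_per_second = n_pmol * AVOGADRO_PER_PMOL * lambda_decay / SECONDS_PER_DAY
    return decays_per_second / BQ_PER_NCI


def pmol_from_activity_nCi(activity_nCi: float, lambda_decay: float) -> float:
    """Inverse of :func:`activity_nCi_from_pmol`."""
    if activity_nCi < 0:
        raise ValueError("activity must be >= 0")
    return activity_nCi * BQ_PER_NCI * SECONDS_PER_DAY / (
        AVOGADRO_PER_PMOL * lambda_decay)


def eta_from_labeling_ratio(ratio_kBq_per_ug: float,
                            antibody_molar_mass: float = IGG_MOLAR_MASS_G_PER_MOL,
                            lambda_decay: float = 0.07) -> float:
    """Impurity coefficient eta implied by a labeling (specific) activity.

    Per ug of antibody product: the total antibody amount follows from the
    molar mass; the labeled amount follows from the activity via the decay
    constant. eta is the ratio of unlabeled to labeled antibodies; a labeling
    ratio of 1.85 kBq/ug with a 148 kDa antibody gives eta ~ 1780.
    """
    if ratio_kBq_per_ug <= 0:
        raise ValueError("labeling ratio must be > 0")
    antibodies_pmol = 1e-6 / antibody_molar_mass * 1e12  # pmol per ug
    decays_per_second = ratio_kBq_per_ug * 1000.0
    nuclides_pmol = decays_per_second * SECONDS_PER_DAY / (
        lambda_decay * AVOGADRO_PER_PMOL)
    if nuclides_pmol > antibodies_pmol:
        raise ValueError(
            "labeling ratio implies more than one nuclide per antibody")
    return (antibodies_pmol - nuclides_pmol) / nuclides_pmol


def receptors_per_cell(gamma: float) -> float:
    """Receptor copies per cell from the receptor amount per 1e7 cells (pmol).

    gamma = 2.1 pmol corresponds to ~126,000 CD38 copies per MM.1S cell.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return gamma * AVOGADRO_PER_PMOL / 1e7


# ---------------------------------------------------------------------------
# minimal surviving fraction closed forms
# ---------------------------------------------------------------------------

def _xr(A_pmol: float, params: ModelParameters) -> tuple[float, float]:
    x = params.alpha * A_pmol / (params.nu * params.N0)
    r = params.rho / params.lambda_decay
    return x, r


def surviving_fraction_selfdamage(A_pmol: float, params: ModelParameters,
                                  *, log: bool = False) -> float:
    """Estimated minimal surviving fraction Nm/N0 for a pure single dose in
    the self-damage-only regime (k_s = 1).

    With x = alpha*A/(nu*N0) and r = rho/lambda the estimate is
    ``[(x/r)^r * exp(r - x)]^(1/(1+r))``; it tends to exp(-x) as rho -> 0,
    the classical instantaneous-irradiation survival formula.
    """
    if A_pmol < 0:
        raise ValueError("dose must be >= 0")
    if A_pmol == 0:
        return 0.0 if log else 1.0
    x, r = _xr(A_pmol, params)
    log_sf = (r * math.log(x / r) + r - x) / (1.0 + r) if r > 0 else -x
    return log_sf if log else math.exp(log_sf)


def surviving_fraction_crossfire(A_pmol: float, params: ModelParameters,
                                 *, log: bool = False) -> float:
    """Estimated minimal surviving fraction Nm/N0 for a pure single dose in
    the cross-fire-only regime (k_s = 0).

    With x = alpha*A/(nu*N0) and r = rho/lambda the estimate is
    ``(x/r)^r * exp(2r - x)``; it tends to exp(-x) as rho -> 0.
    """
    if A_pmol < 0:
        raise ValueError("dose must be >= 0")
    if A_pmol == 0:
        return 0.0 if log else 1.0
    x, r = _xr(A_pmol, params)
    log_sf = r * math.log(x / r) + 2.0 * r - x if r > 0 else -x
    return log_sf if log else math.exp(log_sf)


# ---------------------------------------------------------------------------
# decays in blood
# ---------------------------------------------------------------------------

class BloodDecayFractions(NamedTuple):
    """Fractions of injected activity decaying in blood, by carrier."""

    intact: float    #: decays on intact radioconjugates before binding/clearance
    fragment: float  #: decays on antibody fragments released from dead cells
    total: float     #: intact + fragment, the Abl/Acur estimate


def blood_decay_fraction(params: ModelParameters) -> BloodDecayFractions:
    """Estimated decays-in-blood fraction Abl/Acur for a curative single dose.

    Intact branch: lambda/(lambda + kappa_c + k_on*gamma*N0/V) - the share of
    nuclides decaying before anchoring or clearance. Fragment branch:
    omega*lambda/((lambda+omega)(lambda+kappa_p)) - anchored nuclides whose
    host cell dies, returning them to plasma on fragments. At basic
    parameters ~97% of blood decays come from fragments.
    """
    lam = params.lambda_decay
    intact = lam / (lam + params.kappa_c + params.k_on * params.gamma * params.N0 / params.V)
    fragment = params.omega * lam / ((lam + params.omega) * (lam + params.kappa_p))
    return BloodDecayFractions(intact, fragment, intact + fragment)


def viable_fraction_bound(N0: float, N_cur: float) -> float:
    """Upper bound 1/ln(N0/N_cur) on the fraction of injected activity that
    can be spent on viable cells by a curative single dose.

    Units cancel; pass N0 and N_cur on any common scale. For N0 = 1e7 cells
    and N_cur = 0.01 cell the bound is 1/ln(1e9) < 5%.
    """
    if not (N0 > N_cur > 0):
        raise ValueError("require N0 > N_cur > 0")
    return 1.0 / math.log(N0 / N_cur)


# ---------------------------------------------------------------------------
# safe doses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SafeDoseRanges:
    """Physiologic ranges over which the safe-dose worst case is taken."""

    kappa_c: tuple[float, float] = SWEEP_RANGES["kappa_c"]
    kappa_p: tuple[float, float] = SWEEP_RANGES["kappa_p"]
    omega: tuple[float, float] = SWEEP_RANGES["omega"]

    def __post_init__(self) -> None:
        for name in ("kappa_c", "kappa_p", "omega"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def worst_case_blood_fractions(params: ModelParameters,
                               ranges: SafeDoseRanges | None = None
                               ) -> tuple[float, float]:
    """Worst-case (largest) blood-decay fractions over the ranges.

    Returns ``(intact, fragment)``: the intact branch lambda/(lambda+kappa_c)
    at minimal clearance and zero binding, and the fragment branch at maximal
    omega / minimal kappa_p. Both branch expressions are monotone in each
    parameter, so the corners are the worst cases.
    """
    ranges = ranges or SafeDoseRanges()
    lam = params.lambda_decay
    intact = lam / (lam + ranges.kappa_c[0])
    omega_max, kappa_p_min = ranges.omega[1], ranges.kappa_p[0]
    fragment = omega_max * lam / ((lam + omega_max) * (lam + kappa_p_min))
    return intact, fragment


def max_safe_dose(binding_capacity_pmol: float, params: ModelParameters,
                  ranges: SafeDoseRanges | None = None,
                  eta: float | None = None) -> float:
    """Largest injected activity (pmol) that cannot breach the blood-decay
    limit for any parameter set within the physiologic ranges.

    The active amount guaranteed to anchor is capped by the receptor share of
    the injected antibody mix, ``min(A, B/(eta+1))`` for binding capacity B;
    anchored nuclides expose blood only through the fragment branch, the
    remainder through the intact branch. With B = 0 the bound is ~362 nCi
    (0.0175*(lambda+kappa_c_min)/lambda pmol); as B grows it tends to
    ~1763 nCi, set by fragment decays alone. Both limits are independent of
    eta; eta shapes only the transition between them.
    """
    if binding_capacity_pmol < 0:
        raise ValueError("binding capacity must be >= 0")
    eta = params.eta if eta is None else eta
    f_intact, f_fragment = worst_case_blood_fractions(params, ranges)
    bound_cap = binding_capacity_pmol / (eta + 1.0)
    # blood decays: f_fragment on the anchored part, f_intact on the excess
    if f_fragment * bound_cap >= params.A_bl_cr:
        return params.A_bl_cr / f_fragment
    return bound_cap + (params.A_bl_cr - f_fragment * bound_cap) / f_intact


# ---------------------------------------------------------------------------
# curability
# ---------------------------------------------------------------------------

class CurabilityCheck(NamedTuple):
    max_kill_rate: float  #: alpha*lambda*gamma/(nu*(eta+1)), 1/day
    rho: float            #: proliferation rate, 1/day
    curable: bool         #: max_kill_rate > rho
    margin: float         #: max_kill_rate - rho


def curability_condition(params: ModelParameters,
                         eta: float | None = None) -> CurabilityCheck:
    """Necessary long-term curability condition for saturated multi-dosing.

    Under permanently saturated receptors the active occupancy cannot exceed
    1/(eta+1), so the maximal anchored-decay kill rate is
    alpha*lambda*gamma/(nu*(eta+1)); cure requires it to exceed the
    proliferation rate rho.
    """
    eta = params.eta if eta is None else eta
    rate = params.alpha * params.lambda_decay * params.gamma / (
        params.nu * (eta + 1.0))
    return CurabilityCheck(rate, params.rho, rate > params.rho, rate - params.rho)
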