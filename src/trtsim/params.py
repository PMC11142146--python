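"""Model parameters for targeted radionuclide therapy of disseminated blood cancer.

The parameter record collects every rate constant, volume, receptor density and
radiobiology coefficient of the mechanistic model, in the normalized unit system
of :mod:`trtsim.constants` (days, ml, pmol, nM, 1e7 cells).

``ModelParameters.basic()`` returns the reference parameterization of the
^225^Ac-DOTA-daratumumab / disseminated MM.1S xenograft system; ``SWEEP_RANGES``
holds the physiologic ranges used for parameter sweeps and virtual populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict

__all__ = ["ModelParameters", "SWEEP_RANGES", "VARIED_PARAMETERS", "FIXED_PARAMETERS"]


#: physiologic ranges ("Range" column) for the swept parameters
SWEEP_RANGES: dict[str, tuple[float, float]] = {
    "kappa_c": (0.04, 0.28),
    "kappa_p": (0.4, 4.0),
    "gamma": (0.13, 10.0),
    "V": (0.75, 1.5),
    "rho": (0.15, 0.7),
    "omega": (0.005, 0.5),
    "alpha": (50.0, 5000.0),
    "k_f": (0.01, 0.25),
    "N0": (1.0, 10.0),
    "k_s": (0.0, 1.0),
}

#: parameters varied in sweeps / virtual populations
VARIED_PARAMETERS: tuple[str, ...] = tuple(SWEEP_RANGES)

#: parameters held fixed in sweeps
FIXED_PARAMETERS: tuple[str, ...] = ("lambda_decay", "k_on", "nu")


@dataclass(frozen=True)
class ModelParameters:
    """All model parameters.

    Attributes
    ----------
    lambda_decay : float
        Radionuclide decay rate, 1/day (0.07 for ^225^Ac, half-life ~9.9 d).
    k_on : float
        Antibody-receptor binding rate, 1/(nM day).
    kappa_c : float
        Intact-antibody clearance rate, 1/day.
    kappa_p : float
        Antibody-fragment clearance rate, 1/day.
    gamma : float
        Receptor amount per 1e7 cancer cells, pmol.
    V : float
        Volume of drug distribution, ml.
    nu : float
        Lesion volume per 1e7 cancer cells, ml.
    k_s : float
        Relative significance of self-damage irradiation, in [0, 1].
    rho : float
        Viable-cell proliferation rate, 1/day.
    omega : float
        Damaged-cell death rate, 1/day.
    alpha : float
        Cancer-cell radiosensitivity (damage per unit decay concentration).
    k_f : float
        Significance of unanchored-nuclide decays for cancer damage.
    eta : float
        Coefficient of drug impurity: inert antibodies co-injected per active
        radioconjugate.
    N0 : float
        Initial viable-cell count, units of 1e7 cells.
    N_cur : float
        Cure threshold, units of 1e7 cells (1e-9 = 0.01 cell).
    C_d : float
        Lethal cancer burden, units of 1e7 cells (1e4 = 1e11 cells).
    A_bl_cr : float
        Lethal cumulative decays of plasma-resident nuclides, pmol
        (0.0175 pmol, the activity equivalent of ~230 nCi of ^225^Ac).
    """

    lambda_decay: float = 0.07
    k_on: float = 11.15
    kappa_c: float = 0.1
    kappa_p: float = 1.0
    gamma: float = 2.1
    V: float = 1.0
    nu: float = 0.015
    k_s: float = 0.3
    rho: float = 0.34
    omega: float = 0.05
    alpha: float = 500.0
    k_f: float = 0.05
    eta: float = 1780.0
    N0: float = 3.0
    N_cur: float = 1e-9
    C_d: float = 1e4
    A_bl_cr: float = 0.0175

    def __post_init__(self) -> None:
        strictly_positive = (
            "lambda_decay", "k_on", "kappa_c", "kappa_p", "gamma", "V", "nu",
            "rho", "omega", "alpha", "N0", "N_cur", "C_d", "A_bl_cr",
        )
        for name in strictly_positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        for name in ("k_s", "k_f", "eta"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if self.k_s > 1:
            raise ValueError(f"k_s must be <= 1, got {self.k_s!r}")
        if not (self.N_cur < self.N0 < self.C_d):
            raise ValueError(
                f"require N_cur < N0 < C_d, got {self.N_cur!r}, {self.N0!r}, {self.C_d!r}"
            )

    @classmethod
    def basic(cls, **overrides: float) -> "ModelParameters":
        """The reference ('basic') parameter set, with optional field overrides."""
        return cls(**overrides)

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @property
    def binding_capacity(self) -> float:
        """Cancer binding capacity gamma*N0 at t=0, pmol of receptors."""
        return self.gamma * self.N0
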