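"""Transition-state energetics of channel water permeation.

The single-file water column advances by thermally activated hops.  With
a hopping rate r = p_f/v_w and an Arrhenius-type rate law
r = nu0*exp(-dG/(R*T)) (nu0 ~ 1e13 1/s, the universal transition-state
attempt frequency), the unitary permeability follows directly from the
Gibbs activation barrier:

    p_f = nu0 * v_w * exp(-dG / (R*T))

This one-liner is a powerful consistency check: a claimed (p_f, dG)
pair must satisfy it.  A reported barrier of 24.1 kcal/mol, for
instance, caps p_f at ~1e-28 cm^3/s — fourteen orders of magnitude
below a simultaneously claimed 6.8e-13 cm^3/s, an impossible
combination.  Physically plausible barriers for a water-filled pore lie
between the self-diffusion activation energy of bulk water
(~4.6 kcal/mol) and that value plus the vaporization enthalpy
(~10.5 kcal/mol), i.e. ~15 kcal/mol.

Temperature series are analyzed the standard way: ln(P_f) regressed on
1/T, with the activation energy E_a = -slope*R.  Note the slope of such
a plot is strictly an Arrhenius activation energy; treating it as the
Gibbs barrier dG ignores the activation entropy, a simplification this
module documents but does not attempt to refine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import statsmodels.api as sm

from . import units
from .errors import DesignError, DomainError

__all__ = [
    "BarrierModel",
    "ArrheniusSeries",
    "ArrheniusFit",
    "SELF_DIFFUSION_EA",
    "VAPORIZATION_DH",
    "barrier_upper_limit",
    "hopping_rate",
    "pf_from_barrier",
    "barrier_from_pf",
    "fit_activation_energy",
]

SELF_DIFFUSION_EA = 4.6
"""Activation energy of bulk-water self-diffusion, kcal/mol (lower barrier limit)."""

VAPORIZATION_DH = 10.5
"""Enthalpy of vaporization of water, kcal/mol."""


def barrier_upper_limit() -> float:
    """Upper barrier bound for pore water transport, kcal/mol.

    Water that loses its bulk hydrogen-bond network on entering the pore
    pays, at most, the self-diffusion activation energy plus the full
    vaporization enthalpy: ~15 kcal/mol.
    """
    return SELF_DIFFUSION_EA + VAPORIZATION_DH


@dataclass
class BarrierModel:
    """Transition-state link between p_f and the activation barrier.

    dG: Gibbs activation energy, kcal/mol; nu0: attempt frequency, 1/s;
    T: temperature, K; v_w: molecular water volume, cm^3.
    """

    dG: float
    nu0: float = units.NU0_TST
    T: float = units.T_DEFAULT
    v_w: float = units.V_W_MOLECULE
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.nu0 <= 0 or self.T <= 0 or self.v_w <= 0:
            raise DomainError("nu0, T and v_w must be > 0")
        if self.T == units.T_DEFAULT:
            self.provenance.setdefault("T", "default 298.15 K")
        if self.v_w == units.V_W_MOLECULE:
            self.provenance.setdefault("v_w", "default 3.0e-23 cm^3")

    @property
    def r(self) -> float:
        """Hopping rate nu0*exp(-dG/RT), 1/s (never exceeds nu0)."""
        return self.nu0 * math.exp(-self.dG / (units.R_KCAL * self.T))


@dataclass
class ArrheniusSeries:
    """Temperature-permeability series for activation-energy analysis.

    P_f may be membrane (cm/s) or unitary (cm^3/s) permeability as long
    as units are consistent across the series.
    """

    T: np.ndarray
    P_f: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.P_f = np.asarray(self.P_f, dtype=float)
        if self.T.shape != self.P_f.shape:
            raise DomainError("T and P_f must have equal length")
        if np.any(self.T <= 0):
            raise DomainError("temperatures must be > 0 K")
        if np.any(self.P_f <= 0):
            raise DomainError("permeabilities must be > 0")


@dataclass
class ArrheniusFit:
    E_a: float
    intercept: float
    E_a_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]


def hopping_rate(p_f: float, v_w: float = units.V_W_MOLECULE) -> float:
    """Column hopping rate r = p_f/v_w, 1/s."""
    if v_w <= 0:
        raise DomainError(f"v_w must be > 0, got {v_w}")
    return p_f / v_w


def pf_from_barrier(model: BarrierModel) -> float:
    """Unitary permeability p_f = nu0*v_w*exp(-dG/RT), cm^3/s."""
    return model.nu0 * model.v_w * math.exp(
        -model.dG / (units.R_KCAL * model.T))


def barrier_from_pf(p_f: float,
                    T: float = units.T_DEFAULT,
                    nu0: float = units.NU0_TST,
                    v_w: float = units.V_W_MOLECULE) -> float:
    """Invert the transition-state relation: dG = -R*T*ln(p_f/(nu0*v_w)), kcal/mol."""
    if p_f <= 0:
        raise DomainError(f"p_f must be > 0, got {p_f}")
    ceiling = nu0 * v_w
    if p_f > ceiling * (1 + 1e-12):
        raise DomainError(
            f"p_f={p_f} exceeds the attempt-frequency ceiling nu0*v_w={ceiling}"
        )
    return -units.R_KCAL * T * math.log(p_f / ceiling)


def consistency_gap(p_f_claimed: float, dG_claimed: float,
                    T: float = units.T_DEFAULT,
                    nu0: float = units.NU0_TST,
                    v_w: float = units.V_W_MOLECULE) -> dict:
    """Check a claimed (p_f, dG) pair against transition-state theory.

    Returns the barrier implied by the claimed p_f, the p_f implied by
    the claimed barrier, and flags the pair inconsistent when the
    implied and claimed barriers differ by more than ~1 kcal/mol
    (corresponding to a factor ~5 in rate at room temperature).
    """
    dG_implied = barrier_from_pf(p_f_claimed, T=T, nu0=nu0, v_w=v_w)
    pf_implied = pf_from_barrier(BarrierModel(dG=dG_claimed, nu0=nu0, T=T, v_w=v_w))
    gap = dG_claimed - dG_implied
    return {
        "dG_implied_kcal_mol": dG_implied,
        "pf_implied_cm3_s": pf_implied,
        "gap_kcal_mol": gap,
        "consistent": abs(gap) < 1.0,
    }


def fit_activation_energy(series: ArrheniusSeries,
                          ci_level: float = 0.95) -> ArrheniusFit:
    """OLS of ln(P_f) on 1/T; E_a = -slope*R in kcal/mol."""
    if np.unique(series.T).size < 2:
        raise DesignError("need >= 2 distinct temperatures")
    x = 1.0 / series.T
    y = np.log(series.P_f)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    if len(series.T) == 2:
        # two points determine the line exactly; no residual dof for a CI
        slope = float(res.params[1])
        E_a = -slope * units.R_KCAL
        return ArrheniusFit(E_a=E_a, intercept=float(res.params[0]),
                            E_a_ci=(E_a, E_a),
                            intercept_ci=(float(res.params[0]),) * 2)
    ci = res.conf_int(alpha=1.0 - ci_level)
    slope = float(res.params[1])
    E_a = -slope * units.R_KCAL
    E_a_ci = (float(-ci[1][1] * units.R_KCAL), float(-ci[1][0] * units.R_KCAL))
    return ArrheniusFit(E_a=E_a, intercept=float(res.params[0]),
                        E_a_ci=E_a_ci,
                        intercept_ci=(float(ci[0][0]), float(ci[0][1])))
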