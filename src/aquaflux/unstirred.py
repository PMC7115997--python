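"""Unstirred-layer concentration profiles and P_f from volume flow.

Water crossing a planar membrane dilutes the impermeant osmolyte in the
stagnant layer it enters (and concentrates the one it leaves).  A
scanning ion-selective microelectrode records the steady-state osmolyte
concentration as a function of the distance x to the membrane:

    C(x) = C_s * exp(-v_t*x/D + a*x**3/(3*D))

with C_s the near-membrane concentration, v_t the transmembrane volume
flow velocity, D the osmolyte diffusion coefficient and ``a`` an
empirical stirring parameter describing how convection re-mixes the
layer far from the membrane.  The model is linear in its parameters
after taking logs, so the fit is an ordinary least-squares regression of
ln C on {1, x, x**3}.

The fitted velocity converts to the membrane osmotic permeability via

    P_f = v_t / (chi * C_osm * V_w)

where chi is the osmotic coefficient and C_osm the *near-membrane*
osmolyte concentration (the fitted C_s, not the bulk value — the driving
force the membrane actually sees is the diluted one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import statsmodels.api as sm

from . import units
from .errors import DesignError, DomainError

__all__ = [
    "ConcentrationProfile",
    "OsmoticContext",
    "ProfileFit",
    "ul_profile",
    "fit_ul_profile",
    "pf_from_velocity",
]


@dataclass
class ConcentrationProfile:
    """Distance-concentration data from a microelectrode scan.

    x in cm (>= 0, increasing, measured into the hyperosmotic
    compartment), C in mol/cm^3, D the solute diffusion coefficient in
    cm^2/s.  Optional model parameters (C_s, v_t, a_stir) are attached
    when known (synthetic data) or after fitting.
    """

    x: np.ndarray
    C: np.ndarray
    D: float
    C_s: Optional[float] = None
    v_t: Optional[float] = None
    a_stir: Optional[float] = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.x.shape != self.C.shape:
            raise DomainError("x and C must have equal length")
        if np.any(self.x < 0):
            raise DomainError("distances must be >= 0")
        if np.any(np.diff(self.x) < 0):
            raise DomainError("x must be non-decreasing")
        if np.any(self.C <= 0):
            raise DomainError("concentrations must be > 0")
        if self.D <= 0:
            raise DomainError(f"D must be > 0, got {self.D}")


@dataclass
class OsmoticContext:
    """Osmotic parameters converting velocity to permeability.

    chi: osmotic coefficient (ideal solution: 1); C_osm: near-membrane
    osmolyte concentration, mol/cm^3; V_w_molar: partial molar volume of
    water, cm^3/mol.
    """

    C_osm: float
    chi: float = 1.0
    V_w_molar: float = units.V_W_MOLAR

    def __post_init__(self):
        if not (0.0 < self.chi <= 2.0):
            raise DomainError(f"chi must be in (0, 2], got {self.chi}")
        if self.C_osm <= 0:
            raise DomainError(f"C_osm must be > 0, got {self.C_osm}")


@dataclass
class ProfileFit:
    """Fitted unstirred-layer parameters with 95% confidence intervals."""

    C_s: float
    v_t: float
    a_stir: float
    C_s_ci: Tuple[float, float]
    v_t_ci: Tuple[float, float]
    a_stir_ci: Tuple[float, float]
    rss: float


def ul_profile(x: Union[float, np.ndarray], C_s: float, v_t: float,
               D: float, a_stir: float = 0.0) -> Union[float, np.ndarray]:
    """Steady-state unstirred-layer concentration C_s*exp(-v_t*x/D + a*x**3/(3D))."""
    if D <= 0:
        raise DomainError(f"D must be > 0, got {D}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("x must be >= 0")
    C = C_s * np.exp(-v_t * x / D + a_stir * x**3 / (3.0 * D))
    return C if C.ndim else float(C)


def fit_ul_profile(profile: ConcentrationProfile,
                   fit_stirring: bool = True,
                   a_stir_fixed: Optional[float] = None,
                   ci_level: float = 0.95) -> ProfileFit:
    """Fit (C_s, v_t, a_stir) to a measured profile by log-space OLS.

    ln C = ln C_s - (v_t/D)*x + (a_stir/(3D))*x**3 is linear in the
    parameters; confidence intervals come from the OLS residual
    covariance, propagated through the reparameterization (C_s by the
    delta method on ln C_s).  ``a_stir_fixed`` freezes the stirring term
    at a value obtained from a control (no-gradient) scan.
    """
    x, C, D = profile.x, profile.C, profile.D
    if x.size < 5:
        raise DesignError(f"need >= 5 points, got {x.size}")
    if np.unique(x).size < 2:
        raise DesignError("all x equal: design is collinear")

    y = np.log(C)
    if a_stir_fixed is not None:
        y = y - a_stir_fixed * x**3 / (3.0 * D)
        fit_stirring = False

    cols = [np.ones_like(x), x]
    if fit_stirring:
        cols.append(x**3)
    X = np.column_stack(cols)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1.0 - ci_level)

    lnCs, beta_x = res.params[0], res.params[1]
    C_s = float(np.exp(lnCs))
    v_t = float(-beta_x * D)
    C_s_ci = (float(np.exp(ci[0][0])), float(np.exp(ci[0][1])))
    # beta_x = -v_t/D: negate and swap the interval endpoints
    v_t_ci = (float(-ci[1][1] * D), float(-ci[1][0] * D))
    if fit_stirring:
        a_stir = float(res.params[2] * 3.0 * D)
        a_ci = (float(ci[2][0] * 3.0 * D), float(ci[2][1] * 3.0 * D))
    else:
        a_stir = float(a_stir_fixed if a_stir_fixed is not None else 0.0)
        a_ci = (a_stir, a_stir)
    return ProfileFit(C_s=C_s, v_t=v_t, a_stir=a_stir,
                      C_s_ci=C_s_ci, v_t_ci=v_t_ci, a_stir_ci=a_ci,
                      rss=float(res.ssr))


def pf_from_velocity(v_t: float, ctx: OsmoticContext) -> float:
    """Membrane permeability from flow velocity, P_f = v_t/(chi*C_osm*V_w), cm/s."""
    return v_t / (ctx.chi * ctx.C_osm * ctx.V_w_molar)
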