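"""Classical single-file (hard-sphere chain) transport theory.

The model treats the water column in a narrow pore as N hard spheres
pushed by the osmotic force and retarded by wall friction.  Its core
results are the unitary osmotic permeability

    p_f = v_w * D_1 / (z * L)          (per-molecule diffusivity form)
    p_f = D_w * v_w / z**2             (column-diffusivity form)

which are algebraically identical under D_w = D_1/N, L = N*z.  The model
also predicts p_f/p_d = N, a ratio that experiments have never confirmed
(measured ~5 for gramicidin A where N = 7, ~13 for AQP1 where N ~ 8);
see :func:`pf_pd_ratio_prediction`.

The chain derivation assumes the work of moving the column grows
linearly with pore length L — the "hard-sphere limit".  Real channels
with constriction zones or unevenly distributed hydrogen-bonding
residues concentrate their resistance in one spot, and experimentally
p_f falls off *exponentially* with N (see :mod:`aquaflux.determinants`),
so the closed forms here are the classical reference model, not a
validated law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import units
from .errors import ConfigurationError, DomainError

__all__ = [
    "ChannelGeometry",
    "TransportCoefficients",
    "ChainDerivation",
    "osmotic_work",
    "finkelstein_chain",
    "pf_finkelstein",
    "pf_from_mobility",
    "pf_pd_ratio_prediction",
]

_REL_TOL = 1e-9


@dataclass
class ChannelGeometry:
    """Single-file pore descriptor.

    Parameters
    ----------
    N : number of water molecules in the single-file column (>= 1).
    L : pore length, cm.  Derived from N*z when omitted.
    z : water-water spacing, cm; defaults to one water diameter.
    N_H : count of hydrogen-bond donating/accepting pore-lining residues.
    """

    N: int
    L: Optional[float] = None
    z: float = units.Z_WATER
    N_H: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.N < 1:
            raise DomainError(f"N must be >= 1, got {self.N}")
        if self.z <= 0:
            raise DomainError(f"z must be > 0, got {self.z}")
        if self.N_H is not None and self.N_H < 0:
            raise DomainError(f"N_H must be >= 0, got {self.N_H}")
        if self.L is None:
            self.L = self.N * self.z
            self.provenance.setdefault("L", "derived from N*z")
            if self.z == units.Z_WATER:
                self.provenance.setdefault("z", "default 2.8e-8 cm")
        else:
            if self.L <= 0:
                raise DomainError(f"L must be > 0, got {self.L}")
            if abs(self.L - self.N * self.z) > _REL_TOL * self.L:
                raise ConfigurationError(
                    f"inconsistent geometry: L={self.L} but N*z={self.N * self.z}"
                )


@dataclass
class TransportCoefficients:
    """Diffusivities and permeabilities of a single-file column.

    D_1 is the (theoretical) pore diffusion coefficient of an isolated
    water molecule; the full column moves N times slower, D_w = D_1/N.
    """

    D_1: Optional[float] = None
    D_w: Optional[float] = None
    v_w: float = units.V_W_MOLECULE
    p_f: Optional[float] = None
    p_d: Optional[float] = None

    def __post_init__(self):
        for name in ("D_1", "D_w", "v_w", "p_f", "p_d"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise DomainError(f"{name} must be > 0 when set, got {val}")

    def check_column_consistency(self, N: int, rtol: float = 1e-9) -> bool:
        """D_w == D_1/N for the given column length."""
        if self.D_1 is None or self.D_w is None:
            raise ConfigurationError("both D_1 and D_w must be set")
        return abs(self.D_w - self.D_1 / N) <= rtol * self.D_w


@dataclass
class ChainDerivation:
    """All intermediates of the hard-sphere chain derivation.

    Attributes (CGS): W osmotic work (erg); F_Pi osmotic force (dyn);
    F_gamma frictional force (dyn); gamma friction coefficient kT/D_1
    (g/s); v column velocity (cm/s); Phi flux (molecules/s); delta_Pi
    osmotic pressure difference (dyn/cm^2); delta_n_s osmolyte number
    density difference (molecules/cm^3).
    """

    W: float
    F_Pi: float
    F_gamma: float
    gamma: float
    v: float
    Phi: float
    delta_Pi: float
    delta_n_s: float

    @property
    def p_f(self) -> float:
        """Unitary permeability Phi/delta_n_s, cm^3/s (0/0 -> defined via limit elsewhere)."""
        if self.delta_n_s == 0:
            raise DomainError("p_f undefined at zero osmolyte gradient; use pf_finkelstein")
        return self.Phi / self.delta_n_s


def osmotic_work(N: int, delta_Pi: float, v_w: float = units.V_W_MOLECULE) -> float:
    """Work to move N column waters across the pore, W = v_w*N*delta_Pi (erg).

    delta_Pi is the osmotic pressure difference in dyn/cm^2.
    """
    if N < 0:
        raise DomainError(f"N must be >= 0, got {N}")
    if v_w <= 0:
        raise DomainError(f"v_w must be > 0, got {v_w}")
    return v_w * N * delta_Pi


def finkelstein_chain(
    geometry: ChannelGeometry,
    delta_Pi: float,
    D_1: float,
    v_w: float = units.V_W_MOLECULE,
    T: float = units.T_DEFAULT,
) -> ChainDerivation:
    """Run the chain derivation end to end, returning every intermediate.

    Steady state balances the osmotic force F_Pi = W/L against the total
    friction F_gamma = N*gamma*v with gamma = kT/D_1, giving the column
    velocity v = v_w*delta_Pi/(L*gamma), flux Phi = N*v/L per unit
    osmolyte number-density difference delta_n_s = delta_Pi/kT.
    """
    if geometry is None or geometry.L is None:
        raise ConfigurationError("complete ChannelGeometry required")
    if T <= 0:
        raise DomainError(f"T must be > 0, got {T}")
    if D_1 <= 0:
        raise DomainError(f"D_1 must be > 0, got {D_1}")
    kT = units.K_BOLTZMANN * T
    gamma = kT / D_1
    W = osmotic_work(geometry.N, delta_Pi, v_w)
    F_Pi = W / geometry.L
    v = v_w * delta_Pi / (geometry.L * gamma)
    F_gamma = geometry.N * gamma * v
    Phi = geometry.N * v / geometry.L
    delta_n_s = delta_Pi / kT
    return ChainDerivation(
        W=W, F_Pi=F_Pi, F_gamma=F_gamma, gamma=gamma, v=v, Phi=Phi,
        delta_Pi=delta_Pi, delta_n_s=delta_n_s,
    )


def pf_finkelstein(
    v_w: float = units.V_W_MOLECULE,
    D_1: float = 1e-5,
    z: float = units.Z_WATER,
    L: float = None,
) -> float:
    """Unitary permeability from the per-molecule diffusivity, p_f = v_w*D_1/(z*L).

    Inversely proportional to pore length — the hallmark (and weakness)
    of the hard-sphere chain model.
    """
    if L is None:
        raise DomainError("pore length L is required")
    for name, val in (("v_w", v_w), ("D_1", D_1), ("z", z), ("L", L)):
        if val <= 0:
            raise DomainError(f"{name} must be > 0, got {val}")
    return v_w * D_1 / (z * L)


def pf_from_mobility(
    D_w: float,
    v_w: float = units.V_W_MOLECULE,
    z: float = units.Z_WATER,
) -> float:
    """Unitary permeability from the column diffusivity, p_f = D_w*v_w/z**2.

    This form is length-free: the two questionable L-dependencies of the
    chain model (work ~ L and mobility ~ 1/N) cancel.  It is the standard
    route for extracting p_f from molecular-dynamics D_w values, and
    conversely D_w from measured p_f.
    """
    if D_w < 0:
        raise DomainError(f"D_w must be >= 0, got {D_w}")
    for name, val in (("v_w", v_w), ("z", z)):
        if val <= 0:
            raise DomainError(f"{name} must be > 0, got {val}")
    return D_w * v_w / z**2


def pf_pd_ratio_prediction(N: int) -> float:
    """Chain-model prediction p_f/p_d = N.

    .. warning::
       Never confirmed experimentally: measured ratios are ~5 for
       gramicidin A (N = 7 waters) and ~13 for AQP1 (N ~ 8).  Both p_f
       and p_d derivations rest on the work-proportional-to-length
       assumption, so the ratio cannot be used to infer N.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    return float(N)
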