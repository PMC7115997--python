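"""Channel counting and conversion of ensemble P_f to unitary p_f.

A membrane's osmotic permeability is the sum of the lipid background and
the channel contribution, P_f = P_f,lipid + n*p_f/A.  Extracting p_f
therefore requires counting n, which is hard for water channels (no
unitary conductance steps to count).  Two counting routes are covered:

* electrical: for ion-conducting pores (gramicidin, KcsA) the channel
  count follows from the macroscopic conductance, n = G/g.  Plotting
  P_f against G across reconstitutions gives p_f = slope*A*g.  Beware
  electrically silent channels: if a fraction s of channels conducts no
  current but still passes water, the electrical count misses them and
  the slope-derived p_f is inflated exactly 1/(1-s)-fold (s = 0.9 has
  been reported for KcsA, a 10x error).
* fluorescence (FCS) two-step counting for vesicles too small to
  resolve individual channels: count labeled proteoliposomes, dissolve
  with detergent, count labeled micelles; the count ratio gives labeled
  protomers per vesicle, corrected for labeling efficiency and oligomer
  stoichiometry (:func:`channels_per_vesicle`).  With channel densities
  in hand, P_f regressed on density gives p_f directly as the slope
  (:func:`pf_from_density_slope`).

All counts are returned as real numbers: they are ensemble averages,
never forced to integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import statsmodels.api as sm

from .errors import DesignError, DomainError

__all__ = [
    "ElectricalCensus",
    "FcsCensus",
    "SlopeCensus",
    "SlopeFit",
    "VesicleOccupancy",
    "channels_from_conductance",
    "pf_from_conductance_slope",
    "channels_per_vesicle",
    "pf_from_density_slope",
]

LOW_LABELING_THRESHOLD = 0.8


@dataclass
class ElectricalCensus:
    """Electrical channel count: G macroscopic and g unitary conductance (S)."""

    G: float
    g: float
    A: Optional[float] = None

    def __post_init__(self):
        if self.g <= 0:
            raise DomainError(f"g must be > 0, got {self.g}")
        if self.G < 0:
            raise DomainError(f"G must be >= 0, got {self.G}")

    @property
    def n(self) -> float:
        return self.G / self.g


@dataclass
class FcsCensus:
    """Two-step FCS particle counts before/after detergent solubilization.

    vesicle_count / micelle_count: particle concentrations (any common
    unit) in the protein fluorescence channel; protomers_per_oligomer:
    stoichiometry after harsh detergent (monomer micelles);
    labeling_efficiency: fraction of protomers carrying a label;
    bare_fraction: fraction of counted vesicles carrying no protein.
    """

    vesicle_count: float
    micelle_count: float
    protomers_per_oligomer: int = 1
    labeling_efficiency: float = 1.0
    bare_fraction: float = 0.0

    def __post_init__(self):
        if self.vesicle_count < 0 or self.micelle_count < 0:
            raise DomainError("counts must be >= 0")
        if self.protomers_per_oligomer < 1:
            raise DomainError("protomers_per_oligomer must be >= 1")
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise DomainError(
                f"labeling_efficiency must be in (0, 1], got {self.labeling_efficiency}")
        if not (0.0 <= self.bare_fraction < 1.0):
            raise DomainError(
                f"bare_fraction must be in [0, 1), got {self.bare_fraction}")


@dataclass
class SlopeCensus:
    """Paired predictor (conductance or channel density) and P_f series."""

    x: np.ndarray
    P_f: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.P_f = np.asarray(self.P_f, dtype=float)
        if self.x.shape != self.P_f.shape:
            raise DomainError("x and P_f must have equal length")
        if self.x.size < 3:
            raise DesignError(f"need >= 3 points, got {self.x.size}")
        if np.unique(self.x).size < 2:
            raise DesignError("all predictor values equal: design is collinear")


@dataclass
class SlopeFit:
    """p_f from a regression slope; intercept is the lipid background P_f."""

    p_f: float
    lipid_background: float
    slope: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    warnings: List[str] = field(default_factory=list)


@dataclass
class VesicleOccupancy:
    """Average channel content per vesicle from two-step counting."""

    oligomers_per_vesicle: float
    protomers_per_vesicle: float
    oligomers_per_proteoliposome: float
    warnings: List[str] = field(default_factory=list)


def channels_from_conductance(G: float, g: float) -> float:
    """Channel count n = G/g (real-valued ensemble average)."""
    if g <= 0:
        raise DomainError(f"g must be > 0, got {g}")
    if G < 0:
        raise DomainError(f"G must be >= 0, got {G}")
    return G / g


def _slope_fit(census: SlopeCensus, ci_level: float):
    X = sm.add_constant(census.x)
    res = sm.OLS(census.P_f, X).fit()
    ci = res.conf_int(alpha=1.0 - ci_level)
    return (float(res.params[1]), float(res.params[0]),
            (float(ci[1][0]), float(ci[1][1])),
            (float(ci[0][0]), float(ci[0][1])))


def pf_from_conductance_slope(census: SlopeCensus, A: float, g: float,
                              silent_fraction: float = 0.0,
                              ci_level: float = 0.95) -> SlopeFit:
    """Unitary permeability from the P_f-vs-G regression, p_f = slope*A*g.

    ``silent_fraction`` corrects for channels that conduct water but not
    current (the electrical count underestimates n by 1-s, inflating
    p_f by 1/(1-s)); default 0 because the silent fraction is
    channel-specific and must be measured independently.
    """
    if g <= 0 or A <= 0:
        raise DomainError("A and g must be > 0")
    if not (0.0 <= silent_fraction < 1.0):
        raise DomainError(f"silent_fraction must be in [0, 1), got {silent_fraction}")
    slope, intercept, slope_ci, int_ci = _slope_fit(census, ci_level)
    warnings = []
    if slope_ci[0] <= 0.0 <= slope_ci[1]:
        warnings.append("slope not significant: CI spans 0")
    p_f = slope * A * g * (1.0 - silent_fraction)
    return SlopeFit(p_f=p_f, lipid_background=intercept, slope=slope,
                    slope_ci=slope_ci, intercept_ci=int_ci, warnings=warnings)


def channels_per_vesicle(census: FcsCensus) -> VesicleOccupancy:
    """Average oligomer/protomer count per vesicle from FCS two-step counting.

    Assumes harsh-detergent micelles carry one labeled protomer each, so
    micelle_count/vesicle_count = labeled protomers per counted vesicle;
    dividing by the labeling efficiency gives true protomers, and by the
    oligomer stoichiometry gives channels.  When a bare (protein-free)
    vesicle fraction is known, the per-proteoliposome count is
    value/(1 - bare_fraction).
    """
    if census.vesicle_count <= 0:
        raise DomainError("vesicle_count must be > 0")
    warnings = []
    if census.micelle_count == 0:
        warnings.append("no reconstitution: micelle count is zero")
        return VesicleOccupancy(0.0, 0.0, 0.0, warnings)
    if census.labeling_efficiency < LOW_LABELING_THRESHOLD:
        warnings.append(
            f"labeling efficiency {census.labeling_efficiency:.2f} below "
            f"{LOW_LABELING_THRESHOLD}: protomer counts unreliable"
        )
    protomers = (census.micelle_count / census.vesicle_count) / census.labeling_efficiency
    oligomers = protomers / census.protomers_per_oligomer
    per_pl = oligomers / (1.0 - census.bare_fraction)
    return VesicleOccupancy(
        oligomers_per_vesicle=oligomers,
        protomers_per_vesicle=protomers,
        oligomers_per_proteoliposome=per_pl,
        warnings=warnings,
    )


def pf_from_density_slope(census: SlopeCensus,
                          ci_level: float = 0.95) -> SlopeFit:
    """Unitary permeability from the P_f-vs-channel-density regression.

    With density in channels/cm^2 the slope is directly p_f in cm^3/s;
    the intercept is the lipid background permeability in cm/s.
    """
    slope, intercept, slope_ci, int_ci = _slope_fit(census, ci_level)
    warnings = []
    if slope_ci[0] <= 0.0 <= slope_ci[1]:
        warnings.append("slope not significant: CI spans 0")
    return SlopeFit(p_f=slope, lipid_background=intercept, slope=slope,
                    slope_ci=slope_ci, intercept_ci=int_ci, warnings=warnings)
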