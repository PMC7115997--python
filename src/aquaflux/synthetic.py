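"""Seeded synthetic-data generators for every fitter in the package.

Each generator produces (data, truth) pairs: the data object the
corresponding fitter consumes plus a plain-dict ground-truth record, so
recovery tests never rely on hand-edited fixtures.  All randomness comes
from an explicit integer seed through numpy's Generator; the same seed
always yields the same output, and there is no hidden global state.

Default scenario values mirror a typical stopped-flow / microelectrode
bench setup: 100 nm vesicles, a small 290 -> 300 mM osmotic step (small
gradients are the regime where the classical tau -> P_f conversions go
wrong), P_f = 0.01 cm/s, 500-point traces; 30-point electrode scans over
0-200 um; 6-point temperature series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import units
from .determinants import CatalogEntry
from .energetics import ArrheniusSeries
from .errors import DomainError
from .unstirred import ConcentrationProfile, ul_profile
from .vesicle import (
    IntensityTrace,
    MixtureSpec,
    ScatterCalibration,
    VesicleSpec,
    deflate_analytic,
    mixture_trace,
    intensity_from_volume,
)

__all__ = [
    "NoiseSpec",
    "default_vesicle_spec",
    "gen_deflation",
    "gen_profile",
    "gen_arrhenius",
    "gen_catalog",
]


@dataclass
class NoiseSpec:
    """Noise model: multiplicative or additive Gaussian with explicit seed."""

    kind: str = "multiplicative_gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("multiplicative_gaussian", "additive_gaussian"):
            raise DomainError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise DomainError(f"sigma must be >= 0, got {self.sigma}")

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(y, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.standard_normal(np.shape(y))
        if self.kind == "multiplicative_gaussian":
            return y * (1.0 + self.sigma * eps)
        return y + self.sigma * eps


def default_vesicle_spec(P_f: float = 0.01) -> VesicleSpec:
    """Reference stopped-flow scenario: 100 nm LUV, 290 -> 300 mM challenge."""
    return VesicleSpec(
        r0=units.nm_to_cm(100.0),
        c_in0=units.mM_to_mol_cm3(290.0),
        c_out=units.mM_to_mol_cm3(300.0),
        P_f=P_f,
    )


def gen_deflation(
    spec: Union[VesicleSpec, MixtureSpec],
    noise: NoiseSpec,
    calib: Optional[ScatterCalibration] = None,
    t_grid: Optional[Sequence[float]] = None,
    n_points: int = 500,
) -> Tuple[IntensityTrace, dict]:
    """Simulate a stopped-flow scattering trace, normalized to I(0) = 1.

    For a single population the default time grid spans ~6 linearized
    relaxation times so the trace visibly reaches its plateau.
    """
    if isinstance(spec, VesicleSpec):
        populations = [(spec, 1.0)]
    else:
        populations = spec.populations
    if calib is None:
        calib = ScatterCalibration(a=0.0, b=1.0, d=0.0)
    if t_grid is None:
        t_end = 6.0 * max(p.tau_linear for p, _ in populations)
        t_grid = np.linspace(0.0, t_end, n_points)
    t_grid = np.asarray(t_grid, dtype=float)

    mix = MixtureSpec(populations=list(populations))
    clean = mixture_trace(mix, calib, t_grid)
    I0 = clean.I[0]
    I = noise.apply(clean.I / I0)
    truth = {
        "populations": [
            {"P_f_cm_s": p.P_f, "r0_cm": p.r0,
             "c_in0_mol_cm3": p.c_in0, "c_out_mol_cm3": p.c_out,
             "weight": w}
            for p, w in populations
        ],
        "calibration": {"a": calib.a, "b": calib.b, "d": calib.d,
                        "I0_norm": float(I0)},
        "noise": {"kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed},
    }
    return IntensityTrace(t=t_grid, I=I), truth


def gen_volume_trace(spec: VesicleSpec, noise: NoiseSpec,
                     t_grid: Optional[Sequence[float]] = None,
                     n_points: int = 500) -> Tuple["VolumeTrace", dict]:
    """Simulate a volume trace directly (no scattering observable)."""
    from .vesicle import VolumeTrace

    if t_grid is None:
        t_grid = np.linspace(0.0, 6.0 * spec.tau_linear, n_points)
    t_grid = np.asarray(t_grid, dtype=float)
    V = np.asarray(deflate_analytic(spec, t_grid))
    Vn = noise.apply(V)
    Vn[0] = spec.V0  # trace invariant: V[0] = V0
    truth = {"P_f_cm_s": spec.P_f, "r0_cm": spec.r0,
             "c_in0_mol_cm3": spec.c_in0, "c_out_mol_cm3": spec.c_out,
             "noise": {"kind": noise.kind, "sigma": noise.sigma,
                       "seed": noise.seed}}
    return VolumeTrace(t=t_grid, V=Vn), truth


def gen_profile(C_s: float, v_t: float, D: float, noise: NoiseSpec,
                a_stir: float = 0.0,
                x_grid: Optional[Sequence[float]] = None,
                n_points: int = 30,
                x_max: float = 200e-4) -> Tuple[ConcentrationProfile, dict]:
    """Simulate a microelectrode concentration scan (default 0-200 um)."""
    if x_grid is None:
        x_grid = np.linspace(0.0, x_max, n_points)
    x_grid = np.asarray(x_grid, dtype=float)
    C = ul_profile(x_grid, C_s=C_s, v_t=v_t, D=D, a_stir=a_stir)
    Cn = noise.apply(np.asarray(C))
    profile = ConcentrationProfile(x=x_grid, C=Cn, D=D)
    truth = {"C_s_mol_cm3": C_s, "v_t_cm_s": v_t, "D_cm2_s": D,
             "a_stir": a_stir,
             "noise": {"kind": noise.kind, "sigma": noise.sigma,
                       "seed": noise.seed}}
    return profile, truth


def gen_arrhenius(E_a: float, prefactor: float, noise: NoiseSpec,
                  T_grid: Optional[Sequence[float]] = None
                  ) -> Tuple[ArrheniusSeries, dict]:
    """Simulate a temperature series P_f = prefactor*exp(-E_a/(R*T)).

    E_a in kcal/mol; default 6 temperatures from 5 to 40 C.
    """
    if T_grid is None:
        T_grid = np.linspace(278.15, 313.15, 6)
    T_grid = np.asarray(T_grid, dtype=float)
    P = prefactor * np.exp(-E_a / (units.R_KCAL * T_grid))
    Pn = noise.apply(P)
    series = ArrheniusSeries(T=T_grid, P_f=Pn)
    truth = {"E_a_kcal_mol": E_a, "prefactor": prefactor,
             "noise": {"kind": noise.kind, "sigma": noise.sigma,
                       "seed": noise.seed}}
    return series, truth


def gen_catalog(slope: float, intercept: float,
                N_H_values: Sequence[int],
                sigma_ln: float, seed: int) -> Tuple[List[CatalogEntry], dict]:
    """Simulate a structure-function catalog with lognormal p_f scatter.

    ln p_f = intercept + slope*N_H + N(0, sigma_ln); names are synthetic
    ("ch00", "ch01", ...), never real channel identities.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i, nh in enumerate(N_H_values):
        ln_pf = intercept + slope * nh + sigma_ln * rng.standard_normal()
        entries.append(CatalogEntry(name=f"ch{i:02d}", N_H=int(nh),
                                    p_f=float(np.exp(ln_pf))))
    truth = {"slope": slope, "intercept": intercept,
             "sigma_ln": sigma_ln, "seed": seed,
             "N_H_values": list(int(v) for v in N_H_values)}
    return entries, truth
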