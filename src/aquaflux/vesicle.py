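"""Osmotic vesicle deflation kinetics and inverse P_f fitting.

A vesicle of initial volume V0 exposed at t = 0 to a hyperosmotic bath
(impermeant osmolyte at c_out > c_in0) shrinks as water leaves through
the membrane:

    dV/dt = A * P_f * V_w * (c_in(t) - c_out),   c_in(t) = c_in0 * V0 / V(t)

with A the (time-invariant) surface area, V_w the partial molar volume
of water and P_f the membrane osmotic permeability in cm/s.  The ODE has
a closed-form solution in terms of the principal branch of the Lambert W
function (:func:`deflate_analytic`); the ODE integrator
(:func:`deflate_ode`) is kept as an independent cross-check and for the
grid fitting strategy.

Stopped-flow instruments record scattered-light intensity, not volume.
The scattering observable is a quadratic function of volume,
I = a + b*V + d*V**2 (:class:`ScatterCalibration`).

Inverse routes implemented:

* monoexponential time constant + one of the classical tau -> P_f
  conversions (:func:`pf_from_tau`).  The historical divisors disagree
  by large factors at small osmotic gradients — variant "b" (divide by
  c_out - c_in0) overestimates P_f by c_out**2/(c_in0*(c_out - c_in0)),
  more than an order of magnitude for a 290 -> 300 mM challenge;
* full nonlinear fit of the closed form, or the grid-of-simulations
  strategy matching monoexponential time constants
  (:func:`fit_deflation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit
from scipy.special import lambertw

from . import units
from .errors import (
    DomainError,
    FitError,
    InversionError,
    NumericalError,
    RangeError,
)

__all__ = [
    "VesicleSpec",
    "VolumeTrace",
    "IntensityTrace",
    "ScatterCalibration",
    "MonoExpFit",
    "MixtureSpec",
    "DeflationFit",
    "deflate_ode",
    "deflate_analytic",
    "fit_monoexponential",
    "pf_from_tau",
    "fit_deflation",
    "intensity_from_volume",
    "volume_from_intensity",
    "mixture_trace",
]

_GEOM_RTOL = 1e-9


@dataclass
class VesicleSpec:
    """One vesicle population: geometry, osmolytes and permeability.

    Parameters (CGS): r0 initial radius in cm; c_in0/c_out internal and
    external osmolyte concentrations in mol/cm^3; P_f membrane osmotic
    permeability in cm/s; V_w_molar partial molar volume of water in
    cm^3/mol.  V0 and A are derived from r0 unless supplied, in which
    case they must be consistent with the sphere of radius r0.
    """

    r0: float
    c_in0: float
    c_out: float
    P_f: float
    V0: Optional[float] = None
    A: Optional[float] = None
    V_w_molar: float = units.V_W_MOLAR

    def __post_init__(self):
        if self.r0 <= 0:
            raise DomainError(f"r0 must be > 0, got {self.r0}")
        if self.c_in0 <= 0 or self.c_out <= 0:
            raise DomainError("concentrations must be > 0")
        if self.P_f <= 0:
            raise DomainError(f"P_f must be > 0, got {self.P_f}")
        V0_sphere = (4.0 / 3.0) * math.pi * self.r0**3
        A_sphere = 4.0 * math.pi * self.r0**2
        if self.V0 is None:
            self.V0 = V0_sphere
        elif abs(self.V0 - V0_sphere) > _GEOM_RTOL * V0_sphere:
            raise DomainError(f"V0={self.V0} inconsistent with r0 (expect {V0_sphere})")
        if self.A is None:
            self.A = A_sphere
        elif abs(self.A - A_sphere) > _GEOM_RTOL * A_sphere:
            raise DomainError(f"A={self.A} inconsistent with r0 (expect {A_sphere})")

    @property
    def c_delta(self) -> float:
        """Osmotic step c_out - c_in0, mol/cm^3 (> 0 means shrinking)."""
        return self.c_out - self.c_in0

    @property
    def V_eq(self) -> float:
        """Equilibrium volume V0*c_in0/c_out."""
        return self.V0 * self.c_in0 / self.c_out

    @property
    def tau_linear(self) -> float:
        """Small-gradient relaxation time r0*c_in0/(3*P_f*V_w*c_out**2), s."""
        return self.r0 * self.c_in0 / (3.0 * self.P_f * self.V_w_molar * self.c_out**2)

    def replace(self, **kw) -> "VesicleSpec":
        params = dict(r0=self.r0, c_in0=self.c_in0, c_out=self.c_out,
                      P_f=self.P_f, V_w_molar=self.V_w_molar)
        params.update(kw)
        return VesicleSpec(**params)


@dataclass
class VolumeTrace:
    """Time series of vesicle volume (t in s, strictly increasing, t[0]=0)."""

    t: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.t.shape != self.V.shape:
            raise DomainError("t and V must have equal length")
        if self.t.size and self.t[0] != 0:
            raise DomainError(f"t[0] must be 0, got {self.t[0]}")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("t must be strictly increasing")

    def __len__(self):
        return self.t.size


@dataclass
class IntensityTrace:
    """Time series of (normalized) scattered-light intensity."""

    t: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise DomainError("t and I must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("t must be strictly increasing")

    def __len__(self):
        return self.t.size


@dataclass
class ScatterCalibration:
    """Quadratic intensity-volume relation I = a + b*V + d*V**2.

    A second-order reduction of Rayleigh-Gans-Debye scattering that
    captures both the size and refractive-index change of a deflating
    vesicle.  Coefficients are empirical per dataset.
    """

    a: float = 0.0
    b: float = 1.0
    d: float = 0.0

    def is_monotone(self, V_lo: float, V_hi: float) -> bool:
        """Strict monotonicity of I(V) on [V_lo, V_hi] (no stationary point inside)."""
        if self.d == 0:
            return self.b != 0
        v_star = -self.b / (2.0 * self.d)
        return not (V_lo < v_star < V_hi)


@dataclass
class MonoExpFit:
    """Result of a monoexponential fit y = y_inf + amp*exp(-t/tau)."""

    V_inf: float
    amp: float
    tau: float
    rss: float

    def __post_init__(self):
        if self.tau <= 0:
            raise DomainError(f"tau must be > 0, got {self.tau}")


@dataclass
class MixtureSpec:
    """Weighted mixture of vesicle populations (e.g. bare liposomes + proteoliposomes)."""

    populations: List[Tuple[VesicleSpec, float]]

    def __post_init__(self):
        weights = [w for _, w in self.populations]
        if not weights:
            raise DomainError("at least one population required")
        if any(w <= 0 or w > 1 for w in weights):
            raise DomainError("weights must lie in (0, 1]")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise DomainError(f"weights must sum to 1, got {sum(weights)}")


@dataclass
class DeflationFit:
    """P_f estimate with optional bootstrap confidence interval."""

    P_f: float
    strategy: str
    ci: Optional[Tuple[float, float]] = None
    rss: Optional[float] = None
    n_boot: int = 0
    provenance: dict = field(default_factory=dict)


# --- forward models ----------------------------------------------------------

def _rate_constant(spec: VesicleSpec) -> float:
    """Exponent rate k = A*P_f*V_w*c_out**2/(V0*c_in0), 1/s."""
    return (spec.A * spec.P_f * spec.V_w_molar * spec.c_out**2
            / (spec.V0 * spec.c_in0))


def deflate_ode(spec: VesicleSpec, t_grid: Sequence[float],
                rtol: float = 1e-10) -> VolumeTrace:
    """Integrate the deflation ODE dV/dt = A*P_f*V_w*(c_in - c_out) numerically.

    Osmolyte mass is conserved inside the vesicle, c_in(t)*V(t) = c_in0*V0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or t_grid[0] != 0:
        raise DomainError("t_grid must start at 0")

    n_in = spec.c_in0 * spec.V0  # conserved osmolyte amount

    def rhs(t, y):
        V = y[0]
        return [spec.A * spec.P_f * spec.V_w_molar * (n_in / V - spec.c_out)]

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [spec.V0], t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=spec.V0 * rtol,
    )
    if not sol.success:
        raise NumericalError(f"deflation ODE integration failed: {sol.message}")
    return VolumeTrace(t=t_grid, V=sol.y[0])


def deflate_analytic(spec: VesicleSpec,
                     t: Union[float, Sequence[float]]) -> Union[float, np.ndarray]:
    """Closed-form deflation volume via the principal-branch Lambert W.

    V(t) = V0*(c_in0/c_out)*[1 + W(xi*exp(xi - k*t))] with
    xi = c_delta/c_in0 and k = A*P_f*V_w*c_out**2/(V0*c_in0).  At t = 0
    the Lambert identity W(x*e^x) = x gives V = V0; as t -> inf the
    argument tends to 0 and V -> V0*c_in0/c_out.
    """
    xi = spec.c_delta / spec.c_in0
    if xi <= -1.0:
        raise DomainError(
            "Lambert W principal-branch condition violated: "
            f"c_delta/c_in0 = {xi} <= -1 (extreme swelling)"
        )
    t = np.asarray(t, dtype=float)
    arg = xi * np.exp(xi - _rate_constant(spec) * t)
    if np.any(arg < -1.0 / math.e):
        raise DomainError(
            "Lambert W argument below -1/e: outside the principal branch W0"
        )
    w = lambertw(arg, k=0)
    if np.any(np.abs(w.imag) > 1e-12 * np.maximum(1.0, np.abs(w.real))):
        raise NumericalError("Lambert W returned a complex value")
    V = spec.V0 * (spec.c_in0 / spec.c_out) * (1.0 + w.real)
    return V if V.ndim else float(V)


def intensity_from_volume(V: Union[float, np.ndarray],
                          calib: ScatterCalibration) -> Union[float, np.ndarray]:
    """Scattered intensity I = a + b*V + d*V**2."""
    V = np.asarray(V, dtype=float)
    I = calib.a + calib.b * V + calib.d * V**2
    return I if I.ndim else float(I)


def volume_from_intensity(I: Union[float, np.ndarray],
                          calib: ScatterCalibration,
                          bounds: Tuple[float, float]) -> Union[float, np.ndarray]:
    """Invert the quadratic calibration on a physical volume interval.

    Exactly one root of a + b*V + d*V**2 = I must lie inside ``bounds``;
    anything else raises :class:`InversionError` naming both roots.
    """
    lo, hi = min(bounds), max(bounds)
    I_arr = np.atleast_1d(np.asarray(I, dtype=float))
    out = np.empty_like(I_arr)
    if calib.d == 0.0:
        if calib.b == 0.0:
            raise InversionError("calibration is constant: cannot invert")
        out = (I_arr - calib.a) / calib.b
    else:
        disc = calib.b**2 - 4.0 * calib.d * (calib.a - I_arr)
        if np.any(disc < 0):
            raise InversionError("no real root: discriminant < 0")
        sq = np.sqrt(disc)
        r1 = (-calib.b + sq) / (2.0 * calib.d)
        r2 = (-calib.b - sq) / (2.0 * calib.d)
        tol = 1e-12 * max(abs(hi), 1.0)
        in1 = (r1 >= lo - tol) & (r1 <= hi + tol)
        in2 = (r2 >= lo - tol) & (r2 <= hi + tol)
        both = in1 & in2 & (np.abs(r1 - r2) > tol)
        neither = ~in1 & ~in2
        if np.any(both):
            i = int(np.argmax(both))
            raise InversionError(
                f"both roots inside bounds [{lo}, {hi}]: {r1[i]} and {r2[i]}",
                roots=(r1[i], r2[i]),
            )
        if np.any(neither):
            i = int(np.argmax(neither))
            raise InversionError(
                f"no root inside bounds [{lo}, {hi}]: roots {r1[i]} and {r2[i]}",
                roots=(r1[i], r2[i]),
            )
        out = np.where(in1, r1, r2)
    if np.ndim(I) == 0:
        return float(out[0])
    return out


def mixture_trace(mix: MixtureSpec,
                  calib: Union[ScatterCalibration, Sequence[ScatterCalibration]],
                  t_grid: Sequence[float]) -> IntensityTrace:
    """Weighted-sum intensity of a vesicle mixture.

    Protein reconstitution typically yields two populations — bare lipid
    vesicles and proteoliposomes — each deflating with its own P_f; the
    detector sees the weighted sum of their scattering, producing a
    multi-exponential signal.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if isinstance(calib, ScatterCalibration):
        calibs = [calib] * len(mix.populations)
    else:
        calibs = list(calib)
        if len(calibs) != len(mix.populations):
            raise DomainError("one calibration per population required")
    I = np.zeros_like(t_grid)
    for (spec, w), cal in zip(mix.populations, calibs):
        I += w * intensity_from_volume(deflate_analytic(spec, t_grid), cal)
    return IntensityTrace(t=t_grid, I=I)


# --- inverse routes ----------------------------------------------------------

def fit_monoexponential(trace: Union[VolumeTrace, IntensityTrace],
                        t_start: float = 0.0) -> MonoExpFit:
    """Least-squares monoexponential fit y(t) = y_inf + amp*exp(-t/tau).

    Initialized from a log-linear regression of (y - y_last) on t.
    ``t_start`` crops the leading points to mimic stopped-flow dead time.
    """
    t = trace.t
    y = trace.V if isinstance(trace, VolumeTrace) else trace.I
    mask = t >= t_start
    t, y = t[mask], y[mask]
    if t.size < 4:
        raise FitError(f"need >= 4 points, got {t.size}")
    if np.ptp(y) == 0:
        raise FitError("signal is constant: monoexponential fit is degenerate")

    # asymptote guess from the trailing plateau, decay rate from a
    # log-linear regression on the early (clean-signed) part
    n_tail = max(3, t.size // 10)
    y_inf0 = float(np.mean(y[-n_tail:]))
    amp0 = y[0] - y_inf0
    if amp0 == 0:
        amp0 = y[0] - y[-1]
    s = (y - y_inf0) / amp0 if amp0 != 0 else np.zeros_like(y)
    valid = s > 1e-3
    if valid.sum() >= 2:
        slope = np.polyfit(t[valid], np.log(s[valid]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    # fit in normalized units: volumes can be ~1e-15 cm^3, far below the
    # optimizer's absolute tolerance floor
    scale = float(np.ptp(y))
    yn = (y - y_inf0) / scale
    p0 = (0.0, amp0 / scale, float(np.clip(tau0, 1e-12, 100 * (t[-1] - t[0]))))

    def model_n(tt, y_inf, amp, tau):
        return y_inf + amp * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model_n, t, yn, p0=p0, maxfev=10000, method="trf",
            bounds=([-np.inf, -np.inf, 1e-15],
                    [np.inf, np.inf, np.inf]))
    except RuntimeError as exc:
        raise FitError(f"monoexponential fit did not converge: {exc}",
                       last_iterate=p0) from exc
    y_inf = popt[0] * scale + y_inf0
    amp = popt[1] * scale
    tau = popt[2]
    rss = float(np.sum((y_inf + amp * np.exp(-t / tau) - y) ** 2))
    return MonoExpFit(V_inf=float(y_inf), amp=float(amp), tau=float(tau), rss=rss)


_TAU_VARIANTS = ("a", "b", "c", "improved")


def pf_from_tau(tau: float, r0: float, c_in0: float, c_out: float,
                variant: str = "improved",
                V_w_molar: float = units.V_W_MOLAR) -> float:
    """Convert a deflation time constant to P_f, cm/s.

    P_f = r0 / (3*V_w*tau*dPi_eff) with the historical choices of the
    effective osmotic divisor dPi_eff:

    * ``a``: c_out
    * ``b``: c_out - c_in0  (badly biased at small gradients)
    * ``c``: c_out**2/c_in0 (the correct small-gradient linearization)
    * ``improved``: P_f = r0/(3*V_w*tau) * (c_in0 + c_out)/(2*c_out**2)

    Variants a and b are retained because much of the literature used
    them; at a 290 -> 300 mM challenge variant b overestimates P_f
    ~31-fold.  ``improved`` keeps the error within a few percent.
    """
    if tau <= 0 or r0 <= 0:
        raise DomainError("tau and r0 must be > 0")
    if variant not in _TAU_VARIANTS:
        raise DomainError(f"variant must be one of {_TAU_VARIANTS}, got {variant!r}")
    if variant == "improved":
        return r0 / (3.0 * V_w_molar * tau) * (c_in0 + c_out) / (2.0 * c_out**2)
    if variant == "a":
        dPi = c_out
    elif variant == "b":
        dPi = c_out - c_in0
        if dPi == 0:
            raise DomainError("variant b undefined at c_out == c_in0")
    else:  # "c"
        dPi = c_out**2 / c_in0
    return r0 / (3.0 * V_w_molar * tau * dPi)


def _as_volume_trace(trace, calib, spec_like) -> VolumeTrace:
    if isinstance(trace, VolumeTrace):
        return trace
    if calib is None:
        raise DomainError("intensity trace requires a ScatterCalibration")
    bounds = (spec_like.V_eq, spec_like.V0)
    V = volume_from_intensity(trace.I, calib, bounds=bounds)
    return VolumeTrace(t=trace.t, V=V)


def fit_deflation(trace: Union[VolumeTrace, IntensityTrace],
                  spec_known: VesicleSpec,
                  strategy: str = "analytic",
                  grid: Optional[Sequence[float]] = None,
                  calib: Optional[ScatterCalibration] = None,
                  n_boot: int = 0,
                  seed: Optional[int] = None,
                  ci_level: float = 0.95) -> DeflationFit:
    """Estimate P_f from a deflation trace with known geometry and osmolytes.

    ``spec_known`` carries r0, c_in0, c_out (its P_f field is only an
    initial guess / placeholder).  Strategies:

    * ``analytic``: nonlinear least squares of the closed-form solution
      with P_f free;
    * ``grid``: simulate the ODE for each candidate P_f, fit each curve
      monoexponentially to get tau_c, and match the experimental tau to
      the nearest tau_c.

    A residual-resampling bootstrap (``n_boot`` resamples, seeded) gives
    the confidence interval; n_boot=0 skips it.
    """
    vol = _as_volume_trace(trace, calib, spec_known)
    if strategy == "analytic":
        est, rss = _fit_analytic(vol, spec_known)
    elif strategy == "grid":
        if grid is None:
            grid = np.logspace(-4, 0, 200)
        est = _fit_grid(vol, spec_known, np.asarray(grid, dtype=float))
        rss = None
    else:
        raise DomainError(f"unknown strategy {strategy!r}")

    ci = None
    if n_boot > 0:
        if seed is None:
            raise DomainError("bootstrap requires an explicit seed")
        ci = _bootstrap_ci(vol, spec_known, est, strategy, grid,
                           n_boot, seed, ci_level)
    return DeflationFit(
        P_f=est, strategy=strategy, ci=ci, rss=rss, n_boot=n_boot,
        provenance={"r0_cm": spec_known.r0,
                    "c_in0_mol_cm3": spec_known.c_in0,
                    "c_out_mol_cm3": spec_known.c_out,
                    "V_w_molar_cm3_mol": spec_known.V_w_molar,
                    "seed": seed},
    )


def _fit_analytic(vol: VolumeTrace, spec_known: VesicleSpec) -> Tuple[float, float]:
    mono = fit_monoexponential(vol)
    p0 = pf_from_tau(mono.tau, spec_known.r0, spec_known.c_in0,
                     spec_known.c_out, variant="improved",
                     V_w_molar=spec_known.V_w_molar)

    def model(t, log_pf):
        return deflate_analytic(spec_known.replace(P_f=math.exp(log_pf)), t)

    try:
        popt, _ = curve_fit(model, vol.t, vol.V, p0=[math.log(p0)], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"analytic deflation fit did not converge: {exc}",
                       last_iterate=p0) from exc
    pf = math.exp(popt[0])
    rss = float(np.sum((model(vol.t, popt[0]) - vol.V) ** 2))
    return pf, rss


def _fit_grid(vol: VolumeTrace, spec_known: VesicleSpec,
              grid: np.ndarray) -> float:
    tau_exp = fit_monoexponential(vol).tau
    tau_c = np.empty(grid.size)
    for i, pf in enumerate(grid):
        sim = deflate_ode(spec_known.replace(P_f=float(pf)), vol.t, rtol=1e-8)
        tau_c[i] = fit_monoexponential(sim).tau
    lo, hi = tau_c.min(), tau_c.max()
    if not (lo <= tau_exp <= hi):
        raise RangeError(
            f"experimental tau={tau_exp:.4g} s outside simulated range "
            f"[{lo:.4g}, {hi:.4g}]; extend the P_f grid"
        )
    return float(grid[np.argmin(np.abs(tau_c - tau_exp))])


def _bootstrap_ci(vol, spec_known, est, strategy, grid,
                  n_boot, seed, ci_level):
    rng = np.random.default_rng(seed)
    fitted = np.asarray(deflate_analytic(spec_known.replace(P_f=est), vol.t))
    resid = vol.V - fitted
    boot = []
    for _ in range(n_boot):
        Vb = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            vb = VolumeTrace(t=vol.t, V=Vb)
            if strategy == "analytic":
                boot.append(_fit_analytic(vb, spec_known)[0])
            else:
                boot.append(_fit_grid(vb, spec_known, np.asarray(grid)))
        except (FitError, RangeError):
            continue
    if len(boot) < max(10, n_boot // 4):
        raise FitError("bootstrap failed on too many resamples")
    alpha = (1.0 - ci_level) / 2.0
    return (float(np.quantile(boot, alpha)), float(np.quantile(boot, 1 - alpha)))
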