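"""Structure-function regressions for single-file water channels.

Across channels — gramicidin derivatives, KcsA, the aquaporins — the
unitary permeability p_f falls off *exponentially* with the number N of
single-file waters and, more fundamentally, with the number N_H of
pore-lining residues able to donate or accept hydrogen bonds to the
water column.  A span of ~10 hydrogen-bonding residues accounts for a
more-than-hundredfold change in p_f.  The natural model is log-linear:

    ln p_f = intercept + slope * predictor        (predictor: N or N_H)

fitted by unweighted OLS in ln space.  The intercept at N_H = 0 is the
hydrogen-bond-free ceiling — the (in silico) carbon-nanotube limit,
predicted to be length-invariant because N_H stays 0 as the tube grows.

Channels that fall far below the regression line (:func:`outlier_report`)
are candidates for gating: AQP0, for example, offers 16 hydrogen-bonding
residues yet conducts orders of magnitude less water than the trend
predicts, consistent with a mostly-closed channel.

The underlying experimental catalogs are not shipped: the module is a
fit-it-yourself tool, and the example catalog in the docs is synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .errors import DesignError, DomainError

__all__ = [
    "CatalogEntry",
    "LogLinearFit",
    "OutlierFlag",
    "fit_log_linear",
    "predict_pf",
    "outlier_report",
]

QUALITY_CLASSES = ("direct_count", "estimated")


@dataclass
class CatalogEntry:
    """One channel in a structure-function catalog.

    quality distinguishes p_f values backed by a direct channel count
    (and unstirred-layer correction) from biochemical estimates.
    """

    name: str
    N: Optional[int] = None
    N_H: Optional[int] = None
    p_f: Optional[float] = None
    dG: Optional[float] = None
    quality: str = "direct_count"

    def __post_init__(self):
        if self.p_f is not None and self.p_f <= 0:
            raise DomainError(f"{self.name}: p_f must be > 0, got {self.p_f}")
        if self.N is None and self.N_H is None:
            raise DomainError(f"{self.name}: at least one predictor (N, N_H) required")
        if self.quality not in QUALITY_CLASSES:
            raise DomainError(
                f"{self.name}: quality must be one of {QUALITY_CLASSES}")


@dataclass
class LogLinearFit:
    """OLS fit of ln p_f on a structural predictor."""

    predictor: str
    intercept: float
    slope: float
    intercept_ci: Tuple[float, float]
    slope_ci: Tuple[float, float]
    n_points: int
    resid_sd: float
    excluded: List[str] = field(default_factory=list)
    # retained for prediction intervals
    _x: np.ndarray = field(default=None, repr=False)
    _results: object = field(default=None, repr=False)


@dataclass
class OutlierFlag:
    name: str
    predictor_value: float
    p_f: float
    ln_residual: float
    n_sd: float
    annotation: str = "candidate gating / closed state"


def _usable(catalog: Sequence[CatalogEntry], predictor: str,
            quality_filter: Optional[str]):
    usable, excluded = [], []
    for e in catalog:
        x = getattr(e, predictor)
        if x is None or e.p_f is None:
            excluded.append(e.name)
            continue
        if quality_filter is not None and e.quality != quality_filter:
            excluded.append(e.name)
            continue
        usable.append((e, float(x)))
    return usable, excluded


def fit_log_linear(catalog: Sequence[CatalogEntry],
                   predictor: str = "N_H",
                   quality_filter: Optional[str] = None,
                   ci_level: float = 0.95) -> LogLinearFit:
    """Fit ln p_f = intercept + slope*predictor by unweighted OLS.

    ``quality_filter`` restricts the fit to one quality class; excluded
    entries are recorded on the returned fit.  A negative slope around
    -0.4 per hydrogen-bonding residue is typical for N_H.
    """
    if predictor not in ("N", "N_H"):
        raise DomainError(f"predictor must be 'N' or 'N_H', got {predictor!r}")
    usable, excluded = _usable(catalog, predictor, quality_filter)
    if len(usable) < 2:
        raise DesignError(f"need >= 2 usable entries, got {len(usable)}")
    x = np.array([v for _, v in usable])
    if np.unique(x).size < 2:
        raise DesignError("all predictor values equal: cannot fit a slope")
    y = np.array([math.log(e.p_f) for e, _ in usable])
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    if len(usable) == 2:
        ci = np.array([[res.params[0]] * 2, [res.params[1]] * 2])
    else:
        ci = res.conf_int(alpha=1.0 - ci_level)
    dof = max(len(usable) - 2, 1)
    return LogLinearFit(
        predictor=predictor,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n_points=len(usable),
        resid_sd=float(np.sqrt(res.ssr / dof)),
        excluded=excluded,
        _x=x,
        _results=res,
    )


def predict_pf(fit: LogLinearFit, predictor_value: float,
               ci_level: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """Predict p_f at a predictor value, with a delta-method interval.

    The point estimate is exp(intercept + slope*value); the interval is
    the OLS mean-prediction interval in ln space, exponentiated.  At
    N_H = 0 this returns the fitted hydrogen-bond-free ceiling (the
    nanotube limit).
    """
    ln_pred = fit.intercept + fit.slope * predictor_value
    point = math.exp(ln_pred)
    if fit._results is not None and fit.n_points > 2:
        pred = fit._results.get_prediction([1.0, predictor_value])
        lo, hi = pred.conf_int(alpha=1.0 - ci_level)[0]
        return point, (math.exp(lo), math.exp(hi))
    return point, (point, point)


def outlier_report(catalog: Sequence[CatalogEntry],
                   fit: LogLinearFit,
                   k: float = 3.0) -> List[OutlierFlag]:
    """Flag catalog entries whose ln residual exceeds k residual-SDs.

    Large negative residuals (p_f far below the line) suggest the
    channel spends time in a closed state; the flag carries that
    candidate explanation as an annotation slot, not a conclusion.
    """
    usable, _ = _usable(catalog, fit.predictor, None)
    flags: List[OutlierFlag] = []
    sd = fit.resid_sd
    if sd == 0:
        sd = np.finfo(float).tiny
    for e, x in usable:
        resid = math.log(e.p_f) - (fit.intercept + fit.slope * x)
        if abs(resid) > k * sd:
            flags.append(OutlierFlag(
                name=e.name, predictor_value=x, p_f=e.p_f,
                ln_residual=resid, n_sd=abs(resid) / sd,
            ))
    return flags
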