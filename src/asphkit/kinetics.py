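"""SPE-MS turnover assays: % conversion, integrated Michaelis-Menten progress
curves, initial rates, nonlinear Michaelis-Menten fitting, and active-fraction
corrected turnover numbers.

The turnover readout is label-free: % conversion is computed from the
extracted-ion-chromatogram integrals of the product (hydroxylated) and
substrate peptides.  Noiseless progress curves follow the integrated
Michaelis-Menten relation

    Km * ln(S0 / S) + (S0 - S) = kcat * E_active * t

with E_active = E_total * active_fraction: an active-site titration of the
enzyme preparation determines the catalytically active fraction, and kcat is
reported per active enzyme (kcat = vmax / (E_total * active_fraction)).
Catalytic efficiency is kcat/Km in mM^-1 s^-1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from lmfit import Model
from scipy.optimize import brentq


class ConversionUndefinedError(ValueError):
    """Both chromatogram integrals are zero."""


class InsufficientDataError(ValueError):
    """Too few qualifying points for the requested estimate."""


class FitFailureError(RuntimeError):
    """Nonlinear regression did not converge or returned an invalid fit."""


@dataclasses.dataclass(frozen=True)
class EnzymePrep:
    """An enzyme preparation: total concentration and active-site-titrated
    active fraction (dimensionless; the study preparation is 0.951 +/- 0.143)."""

    total_concentration: float  # uM
    active_fraction: float = 0.951
    active_fraction_sd: float = 0.143

    def __post_init__(self) -> None:
        if self.total_concentration <= 0:
            raise ValueError("total_concentration must be positive")
        if not (0 < self.active_fraction <= 1.2):
            raise ValueError("active_fraction outside (0, 1.2]")

    @property
    def active_concentration(self) -> float:
        return self.total_concentration * self.active_fraction


@dataclasses.dataclass(frozen=True)
class TimeCourse:
    times: tuple[float, ...]  # s, strictly increasing, >= 0
    conversion: tuple[float, ...]  # percent, in [0, 100]
    substrate_initial: float  # uM
    enzyme_total: float  # uM

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        c = np.asarray(self.conversion)
        if t.size != c.size:
            raise ValueError("times and conversion differ in length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if c.size and (np.any(c < 0) or np.any(c > 100)):
            raise ValueError("conversion values outside [0, 100]")

    @property
    def product_concentration(self) -> np.ndarray:
        """Product concentration in uM at each time point."""
        return np.asarray(self.conversion) / 100.0 * self.substrate_initial


@dataclasses.dataclass(frozen=True)
class RatePoint:
    substrate: float  # uM
    rate: float  # uM/s


@dataclasses.dataclass(frozen=True)
class MMFit:
    vmax: float  # uM/s
    km: float  # uM
    vmax_se: float
    km_se: float
    n_points: int
    kcat: float | None = None  # 1/s
    kcat_se: float | None = None
    efficiency: float | None = None  # mM^-1 s^-1
    efficiency_se: float | None = None


def percent_conversion(integral_product: float, integral_substrate: float) -> float:
    """% conversion = 100 * product / (substrate + product) from XIC integrals."""
    if integral_product < 0 or integral_substrate < 0:
        raise ValueError("integrals must be >= 0")
    total = integral_product + integral_substrate
    if total == 0:
        raise ConversionUndefinedError("both integrals are zero")
    return 100.0 * integral_product / total


def substrate_at_time(
    kcat: float, km: float, e_active: float, s0: float, t: float,
    rtol: float = 1e-10,
) -> float:
    """Solve Km ln(S0/S) + (S0 - S) = kcat * E_active * t for S.

    The left side is strictly decreasing in S, so the root is bracketed in
    (0, S0] and found by Brent's method to a relative tolerance of
    ``rtol * S0``.
    """
    if min(kcat, km, e_active, s0) <= 0:
        raise ValueError("kcat, km, e_active and s0 must all be positive")
    if t < 0:
        raise ValueError("time must be >= 0")
    if t == 0:
        return s0
    rhs = kcat * e_active * t

    def f(s: float) -> float:
        return km * math.log(s0 / s) + (s0 - s) - rhs

    lower = s0 * 1e-15
    while f(lower) < 0:  # extreme conversion: push the bracket further down
        lower *= 1e-3
        if lower < 1e-300:
            raise FitFailureError(
                f"no bracket for S(t): kcat={kcat}, km={km}, t={t}"
            )
    return brentq(f, lower, s0, xtol=rtol * s0)


def simulate_progress(
    kcat: float,
    km: float,
    prep: EnzymePrep,
    substrate_initial: float,
    times: Sequence[float],
) -> TimeCourse:
    """Noiseless integrated-Michaelis-Menten progress curve.

    Conversion(t) = 100 * (S0 - S(t)) / S0, with S(t) from
    :func:`substrate_at_time`.
    """
    s0 = substrate_initial
    conv = tuple(
        100.0 * (s0 - substrate_at_time(kcat, km, prep.active_concentration, s0, t)) / s0
        for t in times
    )
    return TimeCourse(tuple(float(t) for t in times), conv, s0, prep.total_concentration)


def initial_rate(
    tc: TimeCourse, max_conversion_pct: float = 15.0, min_points: int = 3
) -> float:
    """Initial slope (uM/s) of product vs time over the low-conversion window.

    Uses the points with conversion <= ``max_conversion_pct`` and fits a
    least-squares line forced through the first point, so early-curve
    curvature does not bias the intercept.
    """
    t = np.asarray(tc.times)
    p = tc.product_concentration
    mask = np.asarray(tc.conversion) <= max_conversion_pct
    if mask.sum() < min_points:
        raise InsufficientDataError(
            f"{int(mask.sum())} point(s) below {max_conversion_pct}% conversion, "
            f"need >= {min_points}"
        )
    t_w, p_w = t[mask], p[mask]
    dt = t_w - t_w[0]
    dp = p_w - p_w[0]
    denom = float(np.dot(dt, dt))
    if denom == 0:
        raise InsufficientDataError("no time spread in the initial window")
    return float(np.dot(dt, dp) / denom)


def _mm_rate(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(points: Sequence[RatePoint]) -> MMFit:
    """Nonlinear least-squares fit of v = vmax * S / (Km + S).

    Starting values: vmax0 = 1.5 x the largest observed rate; Km0 = the
    substrate concentration whose rate is closest to half the largest rate.
    Levenberg-Marquardt iterations run to a relative-change tolerance of
    1e-10; a negative parameter estimate is flagged as an invalid fit.
    """
    s = np.array([p.substrate for p in points], dtype=float)
    v = np.array([p.rate for p in points], dtype=float)
    if len(np.unique(s)) < 3:
        raise InsufficientDataError("need >= 3 distinct substrate concentrations")
    vmax0 = 1.5 * float(v.max())
    km0 = float(s[np.argmin(np.abs(v - v.max() / 2.0))])
    km0 = max(km0, 1e-6)

    model = Model(_mm_rate)
    try:
        result = model.fit(
            v, s=s, vmax=vmax0, km=km0,
            method="leastsq", fit_kws={"xtol": 1e-10, "ftol": 1e-12},
        )
    except Exception as exc:  # lmfit wraps MINPACK failures
        raise FitFailureError(f"Michaelis-Menten fit failed: {exc}") from exc
    if not result.success:
        raise FitFailureError(f"fit did not converge: {result.message}")
    vmax = float(result.params["vmax"].value)
    km = float(result.params["km"].value)
    if vmax <= 0 or km <= 0:
        raise FitFailureError(
            f"invalid fit: vmax={vmax:.4g}, km={km:.4g} (negative parameter)"
        )
    vmax_se = float(result.params["vmax"].stderr or np.nan)
    km_se = float(result.params["km"].stderr or np.nan)
    return MMFit(vmax=vmax, km=km, vmax_se=vmax_se, km_se=km_se, n_points=len(points))


def compute_kcat(vmax: float, prep: EnzymePrep) -> float:
    """Turnover number per active enzyme: kcat = vmax / (E_total * f_active)."""
    denom = prep.active_concentration
    if denom <= 0:
        raise ValueError("active enzyme concentration must be positive")
    return vmax / denom


def kcat_reported(vmax: float, prep: EnzymePrep) -> float:
    """kcat rounded to 2 decimal places, the convention of the kinetics table."""
    return round(compute_kcat(vmax, prep), 2)


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/Km in mM^-1 s^-1 (Km supplied in uM, hence the factor 1000)."""
    if km <= 0:
        raise ValueError("km must be positive")
    return 1000.0 * kcat / km


def propagate_kcat_se(vmax: float, vmax_se: float, prep: EnzymePrep) -> float:
    """SE of kcat by quadrature over the vmax SE and the active-fraction SD."""
    kcat = compute_kcat(vmax, prep)
    rel = math.hypot(vmax_se / vmax, prep.active_fraction_sd / prep.active_fraction)
    return kcat * rel


def propagate_efficiency_se(
    kcat: float, kcat_se: float, km: float, km_se: float
) -> float:
    eff = catalytic_efficiency(kcat, km)
    return eff * math.hypot(kcat_se / kcat, km_se / km)


def finalize_fit(fit: MMFit, prep: EnzymePrep) -> MMFit:
    """Attach active-fraction-corrected kcat and kcat/Km (with quadrature SEs)
    to a raw vmax/Km fit."""
    kcat = compute_kcat(fit.vmax, prep)
    kcat_se = (
        propagate_kcat_se(fit.vmax, fit.vmax_se, prep)
        if np.isfinite(fit.vmax_se)
        else float("nan")
    )
    eff = catalytic_efficiency(kcat, fit.km)
    eff_se = (
        propagate_efficiency_se(kcat, kcat_se, fit.km, fit.km_se)
        if np.isfinite(fit.km_se) and np.isfinite(kcat_se)
        else float("nan")
    )
    return dataclasses.replace(
        fit, kcat=kcat, kcat_se=kcat_se, efficiency=eff, efficiency_se=eff_se
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (table reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
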