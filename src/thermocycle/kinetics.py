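"""Steady-state and pre-steady-state (burst) kinetic fits.

Active-site titration of an aminoacyl-tRNA synthetase shows a rapid
exponential burst of product — one turnover of the active enzyme at the
first-order rate of the chemical step, k_chem — followed by linear
steady-state turnover limited by product release.  The burst time course
is fitted as

    P(t) = A·(1 − exp(−k_chem·t)) + v_ss·t + C

with amplitude A (active-enzyme concentration in product units),
steady-state velocity v_ss, and baseline C.  k_cat = v_ss / (active
enzyme) and the ratio k_chem/k_cat measures how much faster chemistry is
than turnover.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "TimeCourse",
    "BurstFit",
    "MichaelisFit",
    "fit_michaelis_menten",
    "fit_burst",
    "burst_model",
    "michaelis_menten",
    "chem_step_time",
]


@dataclass
class TimeCourse:
    """Product time course from an active-site titration experiment."""

    times: np.ndarray
    product: np.ndarray
    enzyme_total: float
    active_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.product.shape:
            raise ValueError("times and product must be matching 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size < 5:
            raise ValueError("a burst fit needs at least 5 points")
        if self.enzyme_total <= 0:
            raise ValueError("enzyme_total must be positive")
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in (0, 1]")

    @property
    def active_enzyme(self) -> float:
        return self.enzyme_total * self.active_fraction


@dataclass(frozen=True)
class BurstFit:
    """Fitted burst parameters plus the derived turnover quantities."""

    amplitude: float
    k_chem: float
    v_ss: float
    offset: float
    k_cat: float
    ratio: float | None  # k_chem / k_cat; None when no burst is resolvable

    @property
    def chem_step_time(self) -> float:
        return chem_step_time(self.k_chem)


@dataclass(frozen=True)
class MichaelisFit:
    kcat: float
    km: float
    kcat_se: float
    km_se: float
    km_identifiable: bool = True


def michaelis_menten(
    s: np.ndarray, kcat: float, km: float, enzyme: float
) -> np.ndarray:
    """v = kcat·E·S / (K_M + S)."""
    s = np.asarray(s, dtype=float)
    return kcat * enzyme * s / (km + s)


def burst_model(
    t: np.ndarray, amplitude: float, k_chem: float, v_ss: float, offset: float
) -> np.ndarray:
    """P(t) = A·(1 − e^(−k_chem·t)) + v_ss·t + C."""
    t = np.asarray(t, dtype=float)
    return amplitude * (1.0 - np.exp(-k_chem * t)) + v_ss * t + offset


def fit_michaelis_menten(
    substrate: np.ndarray, rates: np.ndarray, enzyme: float
) -> MichaelisFit:
    """Nonlinear least squares of the Michaelis–Menten rate law.

    Initialized from the Hanes linearization S/v vs S, so the fit is
    deterministic for identical inputs.  K_M is flagged unidentifiable
    when the data are effectively all-saturating (the rates barely vary
    and the fitted K_M falls below the sampled substrate range).
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rates, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("substrate and rates must be matching 1-D arrays")
    if s.size < 4:
        raise ValueError("need at least 4 substrate points")
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("substrate concentrations and rates must be positive")
    if enzyme <= 0:
        raise ValueError("enzyme concentration must be positive")

    # Hanes: S/v = KM/(kcat·E) + S/(kcat·E)
    slope, intercept = np.polyfit(s, s / v, 1)
    slope = max(slope, 1e-30)
    kcat0 = 1.0 / (slope * enzyme)
    km0 = max(intercept / slope, 1e-12 * s.max())
    try:
        popt, pcov = curve_fit(
            lambda ss, kcat, km: michaelis_menten(ss, kcat, km, enzyme),
            s,
            v,
            p0=[kcat0, km0],
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"Michaelis–Menten fit failed to converge (start kcat={kcat0:.3g}, "
            f"KM={km0:.3g}): {exc}"
        ) from exc
    kcat, km = (float(x) for x in popt)
    kcat_se, km_se = (float(x) for x in np.sqrt(np.diag(pcov)))
    saturating = (v.max() - v.min()) < 0.05 * v.max() or km < 0.02 * s.min()
    return MichaelisFit(kcat, km, kcat_se, km_se, km_identifiable=not saturating)


def _burst_start(tc: TimeCourse) -> tuple[float, float, float, float]:
    """Deterministic starting values (A, k_chem, v_ss, C)."""
    t, p = tc.times, tc.product
    n_tail = max(2, t.size // 3)
    v0, b0 = np.polyfit(t[-n_tail:], p[-n_tail:], 1)  # tail: v_ss·t + (A + C)
    c0 = p[0] - (b0 - p[0]) * 0.0  # product at t≈0 is offset + tiny burst
    if t[0] == 0:
        c0 = p[0]
    a0 = b0 - c0
    if a0 <= 0:
        return 0.0, 1.0 / max(t[1], 1e-12), max(v0, 0.0), c0
    # residual of the tail line decays as A·e^(−k t); log-slope of the
    # first two points seeds k_chem
    r = b0 + v0 * t - p
    k0 = None
    pairs = [(i, j) for i, j in zip(range(t.size), range(1, t.size))]
    for i, j in pairs:
        if r[i] > 0 and r[j] > 0 and r[j] < r[i]:
            dt = t[j] - t[i]
            k0 = math.log(r[i] / r[j]) / dt
            break
    if k0 is None or k0 <= 0:
        k0 = 1.0 / max(t[1] - t[0], 1e-12)
    return a0, k0, max(v0, 0.0), c0


def fit_burst(tc: TimeCourse, amplitude_rtol: float = 1e-3) -> BurstFit:
    """Fit the burst equation to an active-site-titration time course.

    Returns the four model parameters plus k_cat = v_ss/(active enzyme)
    and the dimensionless ratio k_chem/k_cat.  When the fitted burst
    amplitude is indistinguishable from zero (relative to the product
    range) the time course carries no information about k_chem and the
    ratio is reported as None.
    """
    t, p = tc.times, tc.product
    a0, k0, v0, c0 = _burst_start(tc)
    scale = max(p.max() - p.min(), abs(p.max()), 1e-30)

    if a0 <= amplitude_rtol * scale:
        # degenerate: straight line, no resolvable burst
        v_ss, c = np.polyfit(t, p, 1)
        k_cat = float(v_ss) / tc.active_enzyme
        return BurstFit(0.0, math.nan, float(v_ss), float(c), k_cat, None)

    with warnings.catch_warnings():
        # parameter covariance is not used; degenerate courses (v_ss = 0)
        # legitimately produce a singular covariance estimate
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(
            burst_model,
            t,
            p,
            p0=[a0, k0, v0, c0],
            maxfev=20000,
        )
    amplitude, k_chem, v_ss, offset = (float(x) for x in popt)
    k_chem = abs(k_chem)
    k_cat = v_ss / tc.active_enzyme
    if abs(amplitude) <= amplitude_rtol * scale or k_cat <= 0:
        ratio = None
    else:
        ratio = k_chem / k_cat
    return BurstFit(amplitude, k_chem, v_ss, offset, k_cat, ratio)


def chem_step_time(k_chem: float) -> float:
    """Characteristic time of the chemical step, 1/k_chem, in seconds."""
    if not (k_chem > 0):
        raise ValueError(f"k_chem must be positive, got {k_chem}")
    return 1.0 / k_chem
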