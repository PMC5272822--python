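"""Mg²⁺ speciation equilibria and the metal-depletion activity model.

An EDTA titration of a metal-dependent enzyme assay works by pulling
free Mg²⁺ out of solution: Mg²⁺ partitions among ATP, EDTA and the free
pool according to the coupled 1:1 binding equilibria, and the enzyme's
activity follows the free-metal concentration through a single saturable
transition-state metal site on top of a metal-free floor:

    v(m) = v_max · ( f + (1 − f) · m / (m + K_D‡) )

where m is free [Mg²⁺], f is the residual fraction of activity with no
metal at all, and K_D‡ is the dissociation constant of Mg²⁺ from the
transition-state complex.  Fitting log-activity against EDTA total (with
speciation solved at every point) recovers f and K_D‡.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "KD_MG_ATP_DEFAULT",
    "KD_MG_EDTA_DEFAULT",
    "Ligand",
    "EquilibriumSystem",
    "Speciation",
    "DepletionModel",
    "solve_speciation",
    "predicted_activity",
    "fit_depletion",
]

#: Default conditional dissociation constants (M) at assay pH.  The Mg·ATP
#: constant sits on the 10^−4.5 M scale and Mg·EDTA on the sub-nM scale;
#: both are configuration, not fitted quantities, and the same values must
#: be used for generating and fitting a titration.
KD_MG_ATP_DEFAULT = 10**-4.5
KD_MG_EDTA_DEFAULT = 10**-9.5


@dataclass(frozen=True)
class Ligand:
    name: str
    total: float  # M
    kd: float  # M, 1:1 dissociation constant for the Mg complex

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"total {self.name} concentration must be ≥ 0")
        if self.kd <= 0:
            raise ValueError(f"Kd for {self.name} must be > 0")


@dataclass
class EquilibriumSystem:
    """Total Mg²⁺ plus competing 1:1 ligands (at minimum ATP and EDTA)."""

    mg_total: float
    ligands: list[Ligand] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mg_total < 0:
            raise ValueError("mg_total must be ≥ 0")
        names = [lig.name for lig in self.ligands]
        if len(set(names)) != len(names):
            raise ValueError("ligand names must be unique")

    def with_ligand_total(self, name: str, total: float) -> "EquilibriumSystem":
        """Copy of the system with one ligand's total replaced."""
        new = [
            Ligand(l.name, total, l.kd) if l.name == name else l
            for l in self.ligands
        ]
        if name not in [l.name for l in self.ligands]:
            raise KeyError(f"no ligand named {name!r}")
        return EquilibriumSystem(self.mg_total, new)


@dataclass(frozen=True)
class Speciation:
    """Solved species concentrations (M) for one equilibrium system."""

    mg_free: float
    ligand_free: dict[str, float]
    complexes: dict[str, float]

    def conservation_residual(self, system: EquilibriumSystem) -> float:
        """Largest relative conservation error over Mg and all ligands."""
        worst = 0.0
        mg_sum = self.mg_free + sum(self.complexes.values())
        if system.mg_total > 0:
            worst = abs(mg_sum - system.mg_total) / system.mg_total
        for lig in system.ligands:
            if lig.total > 0:
                tot = self.ligand_free[lig.name] + self.complexes[lig.name]
                worst = max(worst, abs(tot - lig.total) / lig.total)
        return worst


def _bound_mg(m: float, system: EquilibriumSystem) -> float:
    # Σ_j complexes with free ligand closed-form in m: MgL_j = L_tot·m/(Kd_j+m)
    return sum(lig.total * m / (lig.kd + m) for lig in system.ligands)


def solve_speciation(system: EquilibriumSystem, rtol: float = 1e-12) -> Speciation:
    """Free Mg²⁺ and all complex concentrations for the coupled equilibria.

    The conservation equation mg_total = m + Σ_j L_j,tot·m/(Kd_j + m) is
    strictly increasing in m, so its root is unique; it is bracketed and
    solved on log m to the requested relative tolerance.
    """
    active = [lig for lig in system.ligands if lig.total > 0]
    if system.mg_total == 0:
        m = 0.0
    elif not active:
        m = system.mg_total
    else:
        def f(log_m: float) -> float:
            m = math.exp(log_m)
            return m + _bound_mg(m, system) - system.mg_total

        hi = math.log(system.mg_total)
        lo = hi - 80.0  # ≥ 34 decades below total: always brackets the root
        if f(lo) >= 0:  # pragma: no cover - unreachable for valid inputs
            raise RuntimeError("speciation bracket failed at the lower bound")
        m = math.exp(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16))
        # polish on the linear scale via one round of Newton for conservation
        for _ in range(3):
            g = m + _bound_mg(m, system) - system.mg_total
            dg = 1.0 + sum(
                lig.total * lig.kd / (lig.kd + m) ** 2 for lig in system.ligands
            )
            step = g / dg
            if abs(step) <= rtol * m:
                break
            m = max(m - step, 0.0)
    ligand_free = {
        lig.name: lig.total * lig.kd / (lig.kd + m) for lig in system.ligands
    }
    complexes = {
        lig.name: lig.total * m / (lig.kd + m) for lig in system.ligands
    }
    return Speciation(m, ligand_free, complexes)


@dataclass(frozen=True)
class DepletionModel:
    """Two-parameter metal-depletion activity model.

    ``f`` is the metal-free rate fraction (activity with no Mg²⁺ relative
    to saturating Mg²⁺), ``kd_ts`` the transition-state Mg²⁺ dissociation
    constant (M), ``v_max`` the saturating-metal rate.
    """

    f: float
    kd_ts: float
    v_max: float = 1.0
    f_se: float = math.nan
    kd_ts_se: float = math.nan
    kd_ts_identifiable: bool = True
    plateau_reached: bool = True

    @property
    def weakly_identified(self) -> bool:
        """True when the series never modulates activity or never plateaus."""
        return (not self.kd_ts_identifiable) or (not self.plateau_reached)

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError(f"f must lie in (0, 1], got {self.f}")
        if self.kd_ts <= 0:
            raise ValueError(f"kd_ts must be > 0, got {self.kd_ts}")


def predicted_activity(mg_free: float, model: DepletionModel) -> float:
    """v_max·(f + (1−f)·m/(m + K_D‡)); → f·v_max as m→0, → v_max as m→∞."""
    if mg_free < 0:
        raise ValueError("mg_free must be ≥ 0")
    m = mg_free
    return model.v_max * (model.f + (1.0 - model.f) * m / (m + model.kd_ts))


def _mg_free_series(
    edta_totals: np.ndarray, system: EquilibriumSystem
) -> np.ndarray:
    return np.array(
        [
            solve_speciation(system.with_ligand_total("EDTA", e)).mg_free
            for e in edta_totals
        ]
    )


def fit_depletion(
    edta_totals: np.ndarray,
    activities: np.ndarray,
    system: EquilibriumSystem,
    enzyme_concs: np.ndarray | None = None,
    v_max: float | None = None,
) -> DepletionModel:
    """Fit (f, K_D‡) to an EDTA titration by least squares on log-activity.

    Every predicted point goes through :func:`solve_speciation` for free
    Mg²⁺ at that EDTA total, then :func:`predicted_activity`.  When
    ``enzyme_concs`` labels the points with more than one enzyme
    concentration the fit is joint, with one v_max per series and shared
    (f, K_D‡).  ``v_max`` fixes the saturating rate instead of fitting
    it (single-series only).  The fit is on log activity, matching the
    multi-decade dynamic range of depletion data.

    K_D‡ is flagged unidentifiable when the titration never modulates
    the predicted activity (flat series, e.g. f ≈ 1 or all points on the
    plateau).
    """
    edta = np.asarray(edta_totals, dtype=float)
    act = np.asarray(activities, dtype=float)
    if edta.shape != act.shape or edta.ndim != 1:
        raise ValueError("edta_totals and activities must be matching 1-D arrays")
    if edta.size < 6:
        raise ValueError("need at least 6 EDTA points")
    if np.any(act <= 0):
        raise ValueError("activities must be strictly positive")
    if "EDTA" not in [l.name for l in system.ligands]:
        raise ValueError("the equilibrium system must declare an 'EDTA' ligand")

    if enzyme_concs is None:
        series_ids = np.zeros(edta.size, dtype=int)
        series_levels = [None]
    else:
        enzyme_concs = np.asarray(enzyme_concs, dtype=float)
        if enzyme_concs.shape != edta.shape:
            raise ValueError("enzyme_concs must align with edta_totals")
        series_levels, series_ids = np.unique(enzyme_concs, return_inverse=True)
        series_levels = list(series_levels)
    n_series = len(series_levels)
    if v_max is not None and n_series > 1:
        raise ValueError("fixed v_max is only supported for a single series")

    # speciation depends only on the EDTA grid, not on the parameters:
    # solve once per unique total
    uniq, inv = np.unique(edta, return_inverse=True)
    mg_free = _mg_free_series(uniq, system)[inv]

    log_act = np.log(act)
    # starting values from a deterministic coarse grid over (f, kd): for a
    # candidate pair the optimal per-series v_max has a closed form in the
    # log-residual objective, so the grid scan is cheap and the subsequent
    # local fit starts near the global optimum of this very nonconvex surface
    ratios = [
        act[series_ids == i].min() / act[series_ids == i].max()
        for i in range(n_series)
    ]
    f_ratio = float(np.clip(np.mean(ratios), 1e-12, 1.0))
    positive = mg_free[mg_free > 0]
    m_lo = positive.min() if positive.size else 1e-12
    m_hi = positive.max() if positive.size else 1e-6
    f_grid = np.geomspace(max(f_ratio / 30, 1e-14), 1.0, 30)
    kd_grid = np.geomspace(m_lo / 30, m_hi * 30, 30)
    best = (np.inf, f_ratio, math.sqrt(m_lo * m_hi))
    for f_c in f_grid:
        frac_c = f_c + (1.0 - f_c) * mg_free[None, :] / (mg_free[None, :] + kd_grid[:, None])
        log_frac = np.log(frac_c)
        resid = log_act[None, :] - log_frac
        for i in range(n_series):
            sel = series_ids == i
            resid[:, sel] -= resid[:, sel].mean(axis=1, keepdims=True)
        sse = (resid**2).sum(axis=1)
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), float(f_c), float(kd_grid[j]))
    _, f0, kd0 = best
    f0 = min(f0, 1 - 1e-9)
    frac0 = f0 + (1.0 - f0) * mg_free / (mg_free + kd0)
    vmax0 = np.array(
        [
            float(np.exp(np.mean(log_act[series_ids == i] - np.log(frac0[series_ids == i]))))
            for i in range(n_series)
        ]
    )

    def unpack(theta: np.ndarray):
        f = 1.0 / (1.0 + math.exp(-theta[0]))  # logistic keeps f in (0,1)
        kd = math.exp(theta[1])
        if v_max is not None:
            vmaxes = np.array([v_max])
        else:
            vmaxes = np.exp(theta[2:])
        return f, kd, vmaxes

    def residuals(theta: np.ndarray) -> np.ndarray:
        f, kd, vmaxes = unpack(theta)
        frac = f + (1.0 - f) * mg_free / (mg_free + kd)
        return np.log(vmaxes[series_ids] * frac) - log_act

    theta0 = [math.log(f0 / (1.0 - f0)), math.log(kd0)]
    if v_max is None:
        theta0 += list(np.log(vmax0))
    sol = least_squares(residuals, np.asarray(theta0), method="lm", xtol=1e-15,
                        ftol=1e-15, gtol=1e-15, max_nfev=20000)
    if not sol.success:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"depletion fit did not converge: {sol.message}")
    f_hat, kd_hat, vmaxes = unpack(sol.x)

    # identifiability: the fitted curve must actually move over the series,
    # and the metal-free floor must dominate somewhere for f to be measured
    # rather than extrapolated
    frac = f_hat + (1.0 - f_hat) * mg_free / (mg_free + kd_hat)
    span = np.log(frac.max() / frac.min()) if frac.min() > 0 else np.inf
    identifiable = bool(span > 0.05)
    plateau = bool(frac.min() < 2.0 * f_hat)
    if not identifiable:
        warnings.warn(
            "titration does not modulate activity; kd_ts is unidentifiable",
            stacklevel=2,
        )
    elif not plateau:
        warnings.warn(
            "titration never reaches the metal-free plateau; the fit is "
            "weakly identified (f extrapolated)",
            stacklevel=2,
        )

    # delta-method standard errors from the Jacobian at the solution
    f_se = kd_se = math.nan
    dof = edta.size - sol.x.size
    if dof > 0:
        jac = sol.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * (2 * sol.cost / dof)
            theta_se = np.sqrt(np.diag(cov))
            f_se = float(theta_se[0] * f_hat * (1.0 - f_hat))
            kd_se = float(theta_se[1] * kd_hat)
        except np.linalg.LinAlgError:
            pass

    return DepletionModel(
        f=float(np.clip(f_hat, 1e-300, 1.0)),
        kd_ts=float(kd_hat),
        v_max=float(vmaxes[0]),
        f_se=f_se,
        kd_ts_se=kd_se,
        kd_ts_identifiable=identifiable,
        plateau_reached=plateau,
    )
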