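"""Effect-coded full-factorial regression on Gibbs energies.

The observed activation energy of each variant × condition is modeled as

    ΔG_obs = C + Σ β_i·[i] + Σ β_ij·[i][j] + ... + β_1..N·[1]...[N]

with [i] = +1 for the reference level of factor i (wild-type residue,
reference metal) and −1 for the perturbed level.  On a balanced full
factorial the columns are orthogonal, so each coefficient is the
parity-weighted average of the responses and the order-k coefficient
times 2^k equals the k-way thermodynamic-cycle non-additivity.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .energy_core import RT_DEFAULT, FreeEnergy

__all__ = [
    "FactorialDesign",
    "EffectEstimate",
    "ModelFit",
    "build_design_matrix",
    "fit_coupling_model",
    "term_histogram",
    "specificity_response",
]

Term = tuple[str, ...]


@dataclass
class FactorialDesign:
    """Long-format factorial dataset of ΔG responses.

    ``levels`` has one row per observation (condition × replicate) with
    entries ±1 in the order of ``factor_names``; ``responses`` are the
    matching free energies in kcal/mol.
    """

    factor_names: Sequence[str]
    levels: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None
    response_kind: str = "kcat"

    def __post_init__(self) -> None:
        self.factor_names = list(self.factor_names)
        if len(set(self.factor_names)) != len(self.factor_names):
            raise ValueError("factor names must be unique")
        self.levels = np.asarray(self.levels, dtype=int)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.levels.ndim != 2 or self.levels.shape[1] != len(self.factor_names):
            raise ValueError(
                f"levels must be (n_obs, {len(self.factor_names)}), got {self.levels.shape}"
            )
        if self.responses.shape != (self.levels.shape[0],):
            raise ValueError("responses must align with level rows")
        if not np.isin(self.levels, (-1, 1)).all():
            raise ValueError("every factor level must be −1 or +1")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
            if self.replicate_ids.shape != self.responses.shape:
                raise ValueError("replicate_ids must align with responses")

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def n_obs(self) -> int:
        return self.levels.shape[0]

    def condition_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=self.factor_names)
        df["response"] = self.responses
        return df

    @property
    def is_full_factorial(self) -> bool:
        seen = {tuple(row) for row in self.levels}
        return len(seen) == 2**self.n_factors

    @property
    def is_balanced(self) -> bool:
        _, counts = np.unique(self.levels, axis=0, return_counts=True)
        return self.is_full_factorial and len(set(counts)) == 1


@dataclass(frozen=True)
class EffectEstimate:
    """One regression term: an intrinsic (order-1) or coupling energy.

    ``coefficient`` is on the regression scale (kcal/mol); the
    equivalent thermodynamic-cycle non-additivity for the same factor
    subset is ``cycle_energy = 2^order · coefficient``.
    """

    term: Term
    coefficient: float
    std_error: float
    t_value: float
    p_value: float

    @property
    def order(self) -> int:
        return len(self.term)

    @property
    def cycle_energy(self) -> float:
        return (2**self.order) * self.coefficient

    @property
    def name(self) -> str:
        return ":".join(self.term) if self.term else "C"


@dataclass
class ModelFit:
    estimates: list[EffectEstimate]
    r_squared: float
    f_statistic: float
    p_of_f: float
    residual_df: int
    residual_sd: float
    se_available: bool = True
    design: FactorialDesign | None = field(default=None, repr=False)

    def estimate(self, term: Sequence[str]) -> EffectEstimate:
        """Look up one term by its factor subset (order-insensitive)."""
        key = frozenset(term)
        for est in self.estimates:
            if frozenset(est.term) == key:
                return est
        raise KeyError(f"no term for factors {sorted(term)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [e.name for e in self.estimates],
                "order": [e.order for e in self.estimates],
                "coefficient": [e.coefficient for e in self.estimates],
                "std_error": [e.std_error for e in self.estimates],
                "t_value": [e.t_value for e in self.estimates],
                "p_value": [e.p_value for e in self.estimates],
                "cycle_energy": [e.cycle_energy for e in self.estimates],
            }
        )


def _terms(factor_names: Sequence[str], max_order: int) -> list[Term]:
    out: list[Term] = [()]
    for order in range(1, max_order + 1):
        out.extend(itertools.combinations(factor_names, order))
    return out


def build_design_matrix(
    design: FactorialDesign, max_order: int | str = "saturated"
) -> pd.DataFrame:
    """±1 product columns, one per term up to ``max_order``.

    The column for term S at condition c is the product of c's levels
    over the factors in S; the intercept column ("C") is all +1.  For a
    balanced full factorial the columns are mutually orthogonal with
    XᵀX = n·I.
    """
    n = design.n_factors
    if max_order == "saturated":
        order = n
    else:
        order = int(max_order)
        if not 0 <= order <= n:
            raise ValueError(f"max_order must be in [0, {n}], got {order}")
    # contradictory duplicates: same levels must not be declared twice with
    # different replicate structure is fine, but identical replicate ids with
    # differing responses at the same corner are ordinary replicates; nothing
    # to reject here beyond level validation already done.
    cols = {}
    for term in _terms(design.factor_names, order):
        if term:
            idx = [design.factor_names.index(f) for f in term]
            cols[":".join(term)] = design.levels[:, idx].prod(axis=1)
        else:
            cols["C"] = np.ones(design.n_obs, dtype=int)
    return pd.DataFrame(cols)


def fit_coupling_model(
    design: FactorialDesign, max_order: int | str = "saturated"
) -> ModelFit:
    """Ordinary least squares of the ΔG responses on the effect-coded terms.

    Coefficients are in kcal/mol; per-term t tests use the residual
    degrees of freedom.  A saturated fit with a single replicate per
    condition has zero residual df: the coefficients are still exact
    corner averages but standard errors are flagged unavailable rather
    than fabricated.
    """
    X = build_design_matrix(design, max_order)
    if design.n_obs < X.shape[1]:
        raise ValueError(
            f"{design.n_obs} observations cannot identify {X.shape[1]} terms"
        )
    if not design.is_balanced:
        warnings.warn(
            "design is not a balanced full factorial; orthogonal-averaging "
            "equivalence does not hold and coefficients come from generic OLS",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        # statsmodels warns about df on saturated fits; we flag it explicitly.
        warnings.simplefilter("ignore")
        res = sm.OLS(design.responses, X.to_numpy(dtype=float)).fit()
    residual_df = int(res.df_resid)
    se_available = residual_df > 0
    bse = res.bse if se_available else np.full(X.shape[1], np.nan)
    tvals = res.tvalues if se_available else np.full(X.shape[1], np.nan)
    pvals = res.pvalues if se_available else np.full(X.shape[1], np.nan)

    order = design.n_factors if max_order == "saturated" else int(max_order)
    estimates = [
        EffectEstimate(
            term=term,
            coefficient=float(res.params[i]),
            std_error=float(bse[i]),
            t_value=float(tvals[i]),
            p_value=float(pvals[i]),
        )
        for i, term in enumerate(_terms(design.factor_names, order))
    ]
    intercept_only = X.shape[1] == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared) if not intercept_only else 0.0
        f_statistic = float(res.fvalue) if not intercept_only else math.nan
        p_of_f = float(res.f_pvalue) if not intercept_only else math.nan
    if not math.isfinite(r_squared):  # constant responses: zero total SS
        r_squared = 1.0 if res.ssr <= 1e-30 else 0.0
    return ModelFit(
        estimates=estimates,
        r_squared=r_squared,
        f_statistic=f_statistic,
        p_of_f=p_of_f,
        residual_df=residual_df,
        residual_sd=float(np.sqrt(res.scale)) if se_available else math.nan,
        se_available=se_available,
        design=design,
    )


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def term_histogram(
    fit: ModelFit,
    threshold: float = 0.15,
    *,
    scale: str = "coefficient",
    holm: bool = False,
) -> pd.DataFrame:
    """Contribution report: terms sorted by |coefficient|, largest first.

    ``threshold`` (kcal/mol) marks which bars fall in the displayed
    significance band; it filters the display flag only, never the fit.
    ``scale`` selects ``coefficient`` or ``cycle_energy`` as the plotted
    magnitude; ``holm`` applies a Holm step-down adjustment to the raw
    per-term p values.
    """
    if scale not in ("coefficient", "cycle_energy"):
        raise ValueError(f"unknown scale {scale!r}")
    df = fit.to_frame()
    pvals = df["p_value"].to_numpy()
    if holm and fit.se_available:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        df["p_value"] = adj
    df["stars"] = [_stars(p) for p in df["p_value"]]
    df["above_threshold"] = df["coefficient"].abs() > threshold
    df["magnitude"] = df[scale].abs()
    df = df.sort_values("magnitude", ascending=False, kind="stable")
    return df.drop(columns="magnitude").reset_index(drop=True)


def specificity_response(
    kcatKM_target: float, kcatKM_offtarget: float, rt: float = RT_DEFAULT
) -> FreeEnergy:
    """Discrimination free energy −RT·ln[(kcat/K_M)_target/(kcat/K_M)_offtarget].

    Negative values favor the target substrate; the result is a valid
    response for :func:`fit_coupling_model` (kind ``specificity``).
    """
    if not (kcatKM_target > 0 and kcatKM_offtarget > 0):
        raise ValueError(
            "catalytic efficiencies must be strictly positive, got "
            f"{kcatKM_target} and {kcatKM_offtarget}"
        )
    return FreeEnergy(
        -rt * math.log(kcatKM_target / kcatKM_offtarget), kind="specificity"
    )
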