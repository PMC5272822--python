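"""Rate ↔ Gibbs-energy conversion and thermodynamic-cycle algebra.

A thermodynamic cycle is a 2^N factorial perturbation experiment on an
enzyme: each corner of the N-cube is one combination of perturbations
(point mutation, domain deletion, metal substitution, ...) and carries a
measured rate or rate acceleration.  Rates are converted to activation
free energies via ΔG‡ = −RT·ln k, so that additivity of perturbation
effects becomes linearity, and the alternating (parity-signed) sum over
the corners measures the N-way non-additivity — the coupling energy
between the perturbed elements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RT_DEFAULT",
    "GAS_CONSTANT_KCAL",
    "rt_from_temperature",
    "RateMeasurement",
    "FreeEnergy",
    "CycleTable",
    "rate_to_free_energy",
    "free_energy_to_rate",
    "cycle_closure",
    "cycle_coupling",
]

#: RT at the assay temperature, kcal/mol.  Fixed at the printed value used
#: throughout the source analyses rather than recomputed from T, so that
#: energies are bit-compatible with the published numbers.
RT_DEFAULT = 0.592

#: Gas constant in kcal/(mol·K), for the optional temperature override.
GAS_CONSTANT_KCAL = 0.0019872


def rt_from_temperature(temperature_k: float) -> float:
    """RT in kcal/mol at an absolute temperature in kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return GAS_CONSTANT_KCAL * temperature_k


@dataclass(frozen=True)
class RateMeasurement:
    """A rate (s⁻¹) or dimensionless fold-acceleration for one condition.

    Fold-accelerations are ratios relative to an explicitly named
    reference condition (``reference``); absolute rates leave it None.
    """

    label: str
    value: float
    replicate_id: int | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(
                f"rate for condition {self.label!r} must be > 0, got {self.value}"
            )


@dataclass(frozen=True)
class FreeEnergy:
    """A Gibbs energy in kcal/mol.

    ``kind`` records which kinetic quantity it derives from; the sign
    convention is that a larger rate gives a more negative ΔG‡.
    """

    value: float
    kind: str = "kcat"

    _KINDS = ("kcat", "KM", "kcat/KM", "kchem", "specificity")

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"free energy must be finite, got {self.value}")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown free-energy kind {self.kind!r}")


def rate_to_free_energy(
    k: float, rt: float = RT_DEFAULT, *, kind: str = "kcat", label: str | None = None
) -> FreeEnergy:
    """ΔG‡ = −RT·ln k, in kcal/mol.

    ``k`` may be an absolute rate (s⁻¹) or a fold-acceleration relative
    to a reference condition; either way larger k means a more negative
    (more stabilized) activation energy.
    """
    if rt <= 0:
        raise ValueError(f"rt must be positive, got {rt}")
    if not (k > 0):
        where = f" for condition {label!r}" if label else ""
        raise ValueError(f"rate must be strictly positive{where}, got {k}")
    return FreeEnergy(-rt * math.log(k), kind=kind)


def free_energy_to_rate(dg: FreeEnergy | float, rt: float = RT_DEFAULT) -> float:
    """Inverse of :func:`rate_to_free_energy`: k = exp(−ΔG/RT)."""
    if rt <= 0:
        raise ValueError(f"rt must be positive, got {rt}")
    value = dg.value if isinstance(dg, FreeEnergy) else float(dg)
    return math.exp(-value / rt)


def cycle_closure(
    edge_energies: Sequence[float],
    nodes: Sequence[object] | None = None,
    tolerance: float = 1e-9,
) -> tuple[float, bool]:
    """Deviation of a closed free-energy circuit from zero, kcal/mol.

    ``edge_energies`` are signed ΔG values traversed in order around the
    circuit.  If ``nodes`` is given it must list the visited states, one
    more than the edges, with the first equal to the last; an open walk
    is a structural error.  Returns ``(deviation, consistent)`` where
    ``consistent`` is True iff the deviation is within ``tolerance``.
    """
    edges = np.asarray(edge_energies, dtype=float)
    if edges.ndim != 1 or edges.size == 0:
        raise ValueError("edge_energies must be a non-empty 1-D sequence")
    if nodes is not None:
        if len(nodes) != edges.size + 1:
            raise ValueError(
                f"a circuit of {edges.size} edges visits {edges.size + 1} nodes, "
                f"got {len(nodes)}"
            )
        if nodes[0] != nodes[-1]:
            raise ValueError(
                f"circuit is open: starts at {nodes[0]!r}, ends at {nodes[-1]!r}"
            )
    deviation = abs(float(edges.sum()))
    return deviation, deviation <= tolerance


Corner = tuple[int, ...]


def _validate_corner(levels: Iterable[int], n_factors: int) -> Corner:
    corner = tuple(int(v) for v in levels)
    if len(corner) != n_factors:
        raise ValueError(f"corner {corner} does not have {n_factors} levels")
    if any(v not in (-1, 1) for v in corner):
        raise ValueError(f"corner levels must be ±1, got {corner}")
    return corner


@dataclass
class CycleTable:
    """Corner rates of a 2^N factorial cycle, indexed by ±1 level vectors.

    Level +1 is the reference state of a factor (wild type, metal
    present, domain present); −1 is the perturbed state.  The all-(+1)
    corner is the reference corner.
    """

    n_factors: int
    corner_rates: Mapping[Corner, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be ≥ 1")
        clean: dict[Corner, float] = {}
        for levels, rate in self.corner_rates.items():
            corner = _validate_corner(levels, self.n_factors)
            if corner in clean:
                raise ValueError(f"duplicate corner {corner}")
            if not (rate > 0):
                raise ValueError(f"rate at corner {corner} must be > 0, got {rate}")
            clean[corner] = float(rate)
        self.corner_rates = clean

    @property
    def reference_corner(self) -> Corner:
        return (1,) * self.n_factors

    def missing_corners(self) -> list[Corner]:
        full = itertools.product((-1, 1), repeat=self.n_factors)
        return [c for c in full if c not in self.corner_rates]

    def require_complete(self) -> None:
        missing = self.missing_corners()
        if missing:
            raise ValueError(f"cycle is missing corners: {missing}")


def corner_parity(corner: Sequence[int]) -> int:
    """+1 for an even number of perturbed (−1) factors, −1 for odd.

    Equals the product of the ±1 levels.
    """
    return int(np.prod(_validate_corner(corner, len(corner))))


def cycle_coupling(cycle: CycleTable, rt: float = RT_DEFAULT) -> FreeEnergy:
    """N-way non-additivity of a full 2^N cycle, kcal/mol.

    Parity-signed sum over corners of −RT·ln k.  For N = 2 this is the
    textbook double-mutant-cycle formula ΔG11 − ΔG10 − ΔG01 + ΔG00; for
    rates generated from an effect-coded linear model it equals 2^N
    times the N-way coefficient.  Negative values mean the perturbed
    elements jointly stabilize the transition state.  A degenerate N = 1
    "cycle" returns the single-edge ΔG difference.
    """
    cycle.require_complete()
    total = 0.0
    for corner, rate in cycle.corner_rates.items():
        dg = rate_to_free_energy(rate, rt, label=str(corner)).value
        total += corner_parity(corner) * dg
    return FreeEnergy(total, kind="kcat")
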