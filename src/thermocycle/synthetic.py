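"""Synthetic assay generators mirroring the study conditions.

Every downstream fit in this package has a forward model; this module
runs those forward models with known truth so the whole pipeline is
testable without any deposited data:

* 2^N factorial rate tables from the effect-coded linear model, with
  Gaussian noise on the ΔG scale (hence lognormal on rates — the
  multiplicative error structure of rate assays);
* EDTA titrations through the coupled Mg·ATP / Mg·EDTA speciation
  equilibria and the two-parameter depletion model;
* burst (active-site titration) product time courses;
* toy multi-conformation structures with known-by-construction dynamic
  residues.

Defaults are the published study conditions: five factors (four D1
switch sites × metal identity) with a −5 kcal/mol five-way coupling,
metal-free fraction 1.1×10⁻⁵ with a 120 nM transition-state site, a
5 s⁻¹ turnover with chemistry 625-fold faster, and three-fold
replication.  Every generator is a bit-reproducible function of its
arguments and seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .energy_core import RT_DEFAULT
from .factorial import FactorialDesign, Term
from .kinetics import TimeCourse, burst_model
from .metal import (
    KD_MG_ATP_DEFAULT,
    KD_MG_EDTA_DEFAULT,
    DepletionModel,
    EquilibriumSystem,
    Ligand,
    predicted_activity,
    solve_speciation,
)

__all__ = [
    "D1_FACTORS",
    "FIVE_WAY_COUPLING",
    "MODULAR_FACTORS",
    "MODULAR_CYCLE_ENERGY",
    "DEPLETION_TRUTH",
    "BURST_TRUTH",
    "default_equilibrium_system",
    "default_edta_grid",
    "default_burst_times",
    "GeneratorConfig",
    "gen_factorial_dataset",
    "gen_edta_titration",
    "gen_burst_course",
    "gen_toy_structures",
]

#: The four D1-switch sites plus the catalytic-metal identity (+1 = Mg²⁺).
D1_FACTORS = ("I4", "F26", "Y33", "F37", "Metal")

#: Five-way site×metal coupling coefficient, kcal/mol.
FIVE_WAY_COUPLING = -5.0

#: Domain-presence factors of the modular cycle (+1 = domain present).
MODULAR_FACTORS = ("CP1", "ABD")

#: Interdomain coupling of the modular cycle on the cycle-energy
#: (non-additivity) scale, kcal/mol; the matching order-2 regression
#: coefficient is this divided by 2² = 4.
MODULAR_CYCLE_ENERGY = -5.0

#: Metal-depletion truth: metal-free rate fraction, transition-state
#: Mg²⁺ K_D (M), saturating rate (arbitrary units).
DEPLETION_TRUTH = DepletionModel(f=1.1e-5, kd_ts=120e-9, v_max=1.0)

#: Burst truth for a 1 µM enzyme stock: amplitude = active enzyme (M),
#: chemical-step rate 3125 s⁻¹, steady-state velocity 5 s⁻¹ × 1 µM,
#: zero baseline.  k_chem/k_cat = 625.
BURST_TRUTH = {
    "amplitude": 1e-6,
    "k_chem": 3125.0,
    "v_ss": 5e-6,
    "offset": 0.0,
    "enzyme_total": 1e-6,
    "active_fraction": 1.0,
}


def default_equilibrium_system(
    mg_total: float = 5e-6,
    atp_total: float = 1e-3,
    kd_atp: float = KD_MG_ATP_DEFAULT,
    kd_edta: float = KD_MG_EDTA_DEFAULT,
) -> EquilibriumSystem:
    """Assay-like speciation system: µM residual Mg²⁺, mM ATP, EDTA varied.

    With these totals the ATP pool buffers free Mg²⁺ near the 120 nM
    transition-state K_D, so the titration traverses the saturable
    region before EDTA pulls the metal into its sub-nM-K_D complex and
    the activity plateaus at the metal-free floor.
    """
    return EquilibriumSystem(
        mg_total,
        [Ligand("ATP", atp_total, kd_atp), Ligand("EDTA", 0.0, kd_edta)],
    )


def default_edta_grid(n: int = 12, top: float = 3e-2) -> np.ndarray:
    """EDTA totals from zero through the Mg-depletion point to the plateau.

    The top of the grid (30 mM) is far enough past the µM residual metal
    that the free-Mg²⁺ contribution falls below the 1.1×10⁻⁵ metal-free
    floor and the log-activity series levels off, as a real titration
    must for the floor to be measurable.
    """
    return np.concatenate([[0.0], np.geomspace(1e-7, top, n - 1)])


def default_burst_times() -> np.ndarray:
    """Sampling spanning the millisecond burst and the linear phase."""
    return np.concatenate(
        [[0.0], np.geomspace(5e-5, 5e-3, 14), np.linspace(0.02, 1.0, 10)]
    )


@dataclass
class GeneratorConfig:
    """Bundle of study-condition defaults for the generators."""

    seed: int = 0
    noise_sd_dg: float = 0.3  # kcal/mol on the ΔG scale
    replicates: int = 3
    coefficients: Mapping[Term, float] = field(
        default_factory=lambda: {tuple(D1_FACTORS): FIVE_WAY_COUPLING}
    )
    intercept: float = -5.0
    depletion_truth: DepletionModel = field(default_factory=lambda: DEPLETION_TRUTH)
    burst_truth: Mapping[str, float] = field(default_factory=lambda: dict(BURST_TRUTH))
    displacement: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd_dg < 0:
            raise ValueError("noise_sd_dg must be ≥ 0")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")


def gen_factorial_dataset(
    factor_names: Sequence[str] = D1_FACTORS,
    coefficients: Mapping[Term, float] | None = None,
    intercept: float = -5.0,
    noise_sd_dg: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    rt: float = RT_DEFAULT,
    response_kind: str = "kcat",
) -> tuple[FactorialDesign, pd.DataFrame]:
    """Full 2^N factorial rates from the effect-coded linear model.

    Each corner's ΔG is the model value plus Normal(0, ``noise_sd_dg``)
    per replicate; rates are exp(−ΔG/RT).  Returns the long-format
    design (responses on the ΔG scale) and a table with the rates.
    """
    factor_names = list(factor_names)
    if coefficients is None:
        coefficients = {tuple(D1_FACTORS): FIVE_WAY_COUPLING}
    coefficients = dict(coefficients)
    declared = set(factor_names)
    for term in coefficients:
        unknown = set(term) - declared
        if unknown:
            raise ValueError(f"term {term} references undeclared factors {unknown}")
    rng = np.random.default_rng(seed)
    corners = list(itertools.product((1, -1), repeat=len(factor_names)))
    rows, responses, rep_ids = [], [], []
    for corner in corners:
        level = dict(zip(factor_names, corner))
        dg_true = intercept + sum(
            beta * np.prod([level[f] for f in term])
            for term, beta in coefficients.items()
        )
        for rep in range(replicates):
            noise = rng.normal(0.0, noise_sd_dg) if noise_sd_dg > 0 else 0.0
            rows.append(corner)
            responses.append(dg_true + noise)
            rep_ids.append(rep)
    design = FactorialDesign(
        factor_names,
        np.array(rows),
        np.array(responses),
        np.array(rep_ids),
        response_kind=response_kind,
    )
    table = design.condition_table()
    table["replicate"] = rep_ids
    table["rate"] = np.exp(-table["response"] / rt)
    return design, table


def gen_edta_titration(
    truth: DepletionModel = DEPLETION_TRUTH,
    system: EquilibriumSystem | None = None,
    edta_grid: np.ndarray | None = None,
    enzyme_concs: Sequence[float] = (1e-7, 5e-7),
    noise_sd_log: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """EDTA titration through speciation and the depletion activity model.

    Activities scale linearly with enzyme concentration (relative to the
    first listed); lognormal noise of log-sd ``noise_sd_log`` emulates
    multiplicative assay error.
    """
    system = system or default_equilibrium_system()
    edta = np.asarray(default_edta_grid() if edta_grid is None else edta_grid, float)
    rng = np.random.default_rng(seed)
    rows = []
    mg_free = np.array(
        [solve_speciation(system.with_ligand_total("EDTA", e)).mg_free for e in edta]
    )
    ref = enzyme_concs[0]
    for conc in enzyme_concs:
        scale = conc / ref
        for e, m in zip(edta, mg_free):
            v = scale * predicted_activity(m, truth)
            if noise_sd_log > 0:
                v *= np.exp(rng.normal(0.0, noise_sd_log))
            rows.append((e, conc, m, v))
    return pd.DataFrame(rows, columns=["edta_total", "enzyme_conc", "mg_free", "activity"])


def gen_burst_course(
    truth: Mapping[str, float] | None = None,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Burst + linear product time course from the forward model.

    ``noise_sd`` is the absolute Gaussian noise on the product signal,
    in the same units as the amplitude.
    """
    truth = dict(BURST_TRUTH if truth is None else truth)
    t = np.asarray(default_burst_times() if times is None else times, float)
    p = burst_model(t, truth["amplitude"], truth["k_chem"], truth["v_ss"], truth["offset"])
    if noise_sd > 0:
        p = p + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return TimeCourse(
        t,
        p,
        enzyme_total=truth.get("enzyme_total", truth["amplitude"]),
        active_fraction=truth.get("active_fraction", 1.0),
    )


def _chain_coordinates(n_residues: int, seed: int = 0) -> np.ndarray:
    """Self-avoiding compact pseudo-chain of Cα positions.

    Residues follow a serpentine path over a 3.8 Å cubic lattice (so
    consecutive residues sit at bonded distance and the fold is globular
    enough to tessellate within an 8 Å contact cutoff), with a seeded
    sub-Å distortion that removes the lattice's cospherical degeneracy.
    """
    side = int(np.ceil(n_residues ** (1 / 3)))
    path = []
    for iz in range(side):
        for iy in range(side):
            ys = iy if iz % 2 == 0 else side - 1 - iy
            xs = range(side) if ys % 2 == (0 if iz % 2 == 0 else 1) else range(side - 1, -1, -1)
            for ix in xs:
                path.append((ix, ys, iz))
    coords = 3.8 * np.array(path[:n_residues], dtype=float)
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, 0.35, size=coords.shape)


def gen_toy_structures(
    n_residues: int = 12,
    displaced: Sequence[int] = (4, 8),
    displacement: float = 3.0,
    out_dir: str | Path | None = None,
    chain: str = "A",
    seed: int = 0,
) -> dict:
    """Two PDB conformations of a toy chain with known packing changes.

    Conformation B displaces the side chains of the 1-based residue
    numbers in ``displaced`` radially by ``displacement`` Å; the sidecar
    truth records exactly those residues.  Returns a dict with the PDB
    texts (and file paths when ``out_dir`` is given) plus the truth.
    """
    if n_residues < 5:
        raise ValueError("need ≥ 5 residues for a tessellatable chain")
    displaced = sorted(set(int(d) for d in displaced))
    if any(d < 1 or d > n_residues for d in displaced):
        raise ValueError("displaced residue numbers must be within the chain")
    ca = _chain_coordinates(n_residues, seed)
    radial = ca - ca.mean(axis=0)
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    outward = radial / np.where(norms < 1e-9, 1.0, norms)
    cb_a = ca + 1.53 * outward
    cb_b = cb_a.copy()
    for d in displaced:
        cb_b[d - 1] += displacement * outward[d - 1]

    def build_pdb(cb: np.ndarray, label: str) -> str:
        sb = StructureBuilder()
        sb.init_structure(label)
        sb.init_model(0)
        sb.init_chain(chain)
        sb.init_seg("    ")
        serial = 1
        for idx in range(n_residues):
            sb.init_residue("ALA", " ", idx + 1, " ")
            sb.init_atom("CA", ca[idx], 0.0, 1.0, " ", " CA ", serial, "C")
            serial += 1
            sb.init_atom("CB", cb[idx], 0.0, 1.0, " ", " CB ", serial, "C")
            serial += 1
        import io as _io

        buf = _io.StringIO()
        writer = PDBIO()
        writer.set_structure(sb.get_structure())
        writer.save(buf)
        return buf.getvalue()

    result = {
        "conformations": {"open": build_pdb(cb_a, "open"), "closed": build_pdb(cb_b, "closed")},
        "truth": {
            "chain": chain,
            "displaced_residues": displaced,
            "displacement_angstrom": float(displacement),
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in result["conformations"].items():
            path = out / f"toy_{name}.pdb"
            path.write_text(text)
            paths[name] = str(path)
        truth_path = out / "toy_truth.json"
        truth_path.write_text(json.dumps(result["truth"], indent=1))
        result["paths"] = paths
        result["truth_path"] = str(truth_path)
    return result
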