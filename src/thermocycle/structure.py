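"""Differential Delaunay tessellation of residue packing.

Rigid-body conformational changes preserve local packing: the Delaunay
tetrahedra of residue points inside a rigid body are the same in every
conformation.  Tessellating each conformation of the same chain and
intersecting the simplex sets therefore separates *invariant* packing
(within rigid bodies) from *dynamic* simplices that rearrange partners
during the conformational cycle.  The residues of dynamic simplices are
the candidates for long-range coupling; intersecting them with an
externally supplied mutation list (e.g. from multi-state design) gives
the final, experimentally tractable candidate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay

from Bio.PDB import PDBParser

__all__ = [
    "ResidueId",
    "ResiduePointSet",
    "SimplexSet",
    "DynamicContactReport",
    "residue_centroids",
    "tessellate",
    "dynamic_simplices",
    "score_simplices",
    "candidate_intersection",
    "deterministic_jitter",
]

#: (chain id, residue number) exactly as in the coordinate records.
ResidueId = tuple[str, int]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ResiduePointSet:
    """One 3-D point per residue of one conformation.

    Points are side-chain heavy-atom centroids (Cα for glycine or any
    residue without side-chain heavy atoms), in Å; residue ids keep the
    1-based numbering of the source coordinates.
    """

    conformation: str
    residue_ids: list[ResidueId]
    points: np.ndarray
    residue_names: dict[ResidueId, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValueError("residue ids must be unique")
        if self.points.shape != (len(self.residue_ids), 3):
            raise ValueError("points must be (n_residues, 3)")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ResiduePointSet":
        """Rigidly moved copy (used to check invariance of reports)."""
        return ResiduePointSet(
            self.conformation,
            list(self.residue_ids),
            self.points @ np.asarray(rotation).T + np.asarray(translation),
            dict(self.residue_names),
        )

    def restrict(self, keep: Iterable[ResidueId]) -> "ResiduePointSet":
        keep = set(keep)
        idx = [i for i, rid in enumerate(self.residue_ids) if rid in keep]
        return ResiduePointSet(
            self.conformation,
            [self.residue_ids[i] for i in idx],
            self.points[idx],
            {rid: self.residue_names[rid] for rid in self.residue_names if rid in keep},
        )


def residue_centroids(
    structure_path: str | Path,
    chain: str | None = None,
    model_index: int = 0,
    point: str = "centroid",
    conformation: str | None = None,
) -> ResiduePointSet:
    """Extract one representative point per residue from a PDB file.

    ``point`` selects ``centroid`` (side-chain heavy atoms; Cα fallback)
    or ``ca`` (Cα only).  Waters and hetero groups are excluded;
    alternate locations resolve to the highest-occupancy conformer.
    Residues with neither side-chain heavy atoms nor Cα are skipped with
    a warning.
    """
    if point not in ("centroid", "ca"):
        raise ValueError(f"point must be 'centroid' or 'ca', got {point!r}")
    path = Path(structure_path)
    parser = PDBParser(QUIET=True)
    model = list(parser.get_structure(path.stem, str(path)))[model_index]
    ids: list[ResidueId] = []
    names: dict[ResidueId, str] = {}
    coords: list[np.ndarray] = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            hetflag, resseq, _ = res.id
            if hetflag != " ":  # waters and hetero groups
                continue
            rid: ResidueId = (ch.id, resseq)
            atoms = {}
            for atom in res.get_unpacked_list():
                if atom.element == "H":
                    continue
                prev = atoms.get(atom.get_name())
                if prev is None or (atom.get_occupancy() or 0) > (prev.get_occupancy() or 0):
                    atoms[atom.get_name()] = atom
            side = [a for n, a in atoms.items() if n not in _BACKBONE]
            if point == "centroid" and side:
                xyz = np.mean([a.get_coord() for a in side], axis=0)
            elif "CA" in atoms:
                xyz = atoms["CA"].get_coord()
            else:
                warnings.warn(
                    f"residue {rid} has neither side-chain heavy atoms nor CA; skipped",
                    stacklevel=2,
                )
                continue
            ids.append(rid)
            names[rid] = res.get_resname()
            coords.append(np.asarray(xyz, dtype=float))
    if chain is not None and not ids:
        raise ValueError(f"chain {chain!r} not found in {path}")
    return ResiduePointSet(
        conformation or path.stem, ids, np.array(coords).reshape(-1, 3), names
    )


Simplex = frozenset  # frozenset of 4 ResidueId


@dataclass
class SimplexSet:
    """Edge-filtered Delaunay simplices of one conformation."""

    conformation: str
    simplices: set[Simplex]
    max_edge: dict[Simplex, float]
    residue_ids: list[ResidueId]
    residue_names: dict[ResidueId, str] = field(default_factory=dict)
    scores: dict[Simplex, float] = field(default_factory=dict)


def deterministic_jitter(
    residue_ids: Sequence[ResidueId], scale: float = 1e-6
) -> np.ndarray:
    """Symbolic-scale displacement keyed to each residue id.

    Breaks cospherical degeneracies (e.g. lattice-like synthetic
    coordinates) identically on every run and in every conformation, so
    tessellation differences always reflect real coordinate changes.
    """
    out = np.empty((len(residue_ids), 3))
    for i, rid in enumerate(residue_ids):
        key = abs(hash((str(rid[0]), int(rid[1])))) % (2**32)
        rng = np.random.default_rng(key)
        out[i] = rng.standard_normal(3)
    return scale * out


def tessellate(
    points: ResiduePointSet, max_edge: float = 8.0, jitter_scale: float = 1e-6
) -> SimplexSet:
    """Delaunay tessellation with an edge-length filter.

    Simplices with any edge longer than ``max_edge`` Å are dropped —
    these are spurious surface tetrahedra spanning solvent, not packing
    contacts.  Retained simplices satisfy the empty-circumsphere
    property of the (jittered) point set.
    """
    n = len(points.residue_ids)
    if n < 4:
        raise ValueError(f"tessellation needs ≥ 4 residues, got {n}")
    coords = points.points + deterministic_jitter(points.residue_ids, jitter_scale)
    tri = Delaunay(coords)
    simplices: set[Simplex] = set()
    edges: dict[Simplex, float] = {}
    for quad in tri.simplices:
        pts = points.points[quad]
        diffs = pts[:, None, :] - pts[None, :, :]
        longest = float(np.sqrt((diffs**2).sum(-1)).max())
        if longest > max_edge:
            continue
        key = frozenset(points.residue_ids[i] for i in quad)
        simplices.add(key)
        edges[key] = longest
    return SimplexSet(
        points.conformation,
        simplices,
        edges,
        list(points.residue_ids),
        dict(points.residue_names),
    )


@dataclass
class DynamicContactReport:
    """Partition of packing simplices into invariant vs dynamic."""

    invariant: set[Simplex]
    dynamic: set[Simplex]
    dynamic_by_conformation: dict[str, set[Simplex]]
    dynamic_residues: set[ResidueId]

    @property
    def all_simplices(self) -> set[Simplex]:
        return self.invariant | self.dynamic


def dynamic_simplices(tessellations: Sequence[SimplexSet]) -> DynamicContactReport:
    """Classify simplices across ≥ 2 conformations of the same chain.

    Invariant simplices occur in every conformation (rigid-body
    packing); dynamic simplices occur in at least one but not all.  The
    dynamic residue set is the union of residues of dynamic simplices.
    """
    if len(tessellations) < 2:
        raise ValueError("need at least two conformations")
    universe = set(tessellations[0].residue_ids)
    for ts in tessellations[1:]:
        other = set(ts.residue_ids)
        if other != universe:
            diff = sorted(universe ^ other)
            raise ValueError(
                f"conformations have mismatched residue universes; "
                f"symmetric difference: {diff}"
            )
    sets = [ts.simplices for ts in tessellations]
    invariant = set.intersection(*sets)
    union = set.union(*sets)
    dynamic = union - invariant
    per_conf = {ts.conformation: ts.simplices - invariant for ts in tessellations}
    residues: set[ResidueId] = set()
    for s in dynamic:
        residues |= s
    return DynamicContactReport(invariant, dynamic, per_conf, residues)


def score_simplices(
    sset: SimplexSet,
    potential: Mapping[tuple[str, ...], float],
) -> SimplexSet:
    """Attach a composition log-likelihood Λ to every simplex.

    ``potential`` maps a sorted 4-tuple of residue-type names to Λ (a
    uniform table, all zeros, leaves every simplex outside both bands).
    Simplices with Λ > ``high`` are well-packed core motifs; Λ <
    ``low`` marks unfavorable (typically surface) compositions.  Band
    membership is read back with :func:`score_bands`.
    """
    scores: dict[Simplex, float] = {}
    for s in sset.simplices:
        comp = tuple(sorted(sset.residue_names.get(rid, "UNK") for rid in s))
        if comp not in potential:
            raise KeyError(f"no log-likelihood for composition {comp}")
        scores[s] = float(potential[comp])
    return SimplexSet(
        sset.conformation,
        set(sset.simplices),
        dict(sset.max_edge),
        list(sset.residue_ids),
        dict(sset.residue_names),
        scores,
    )


def score_bands(
    sset: SimplexSet, high: float = 0.6, low: float = 0.0
) -> dict[str, set[Simplex]]:
    """Partition scored simplices into Λ bands: high, negative, middle."""
    if not sset.scores:
        raise ValueError("simplex set has no scores; run score_simplices first")
    return {
        "high": {s for s, v in sset.scores.items() if v > high},
        "negative": {s for s, v in sset.scores.items() if v < low},
        "middle": {s for s, v in sset.scores.items() if low <= v <= high},
    }


def candidate_intersection(
    report: DynamicContactReport,
    suggestions: Sequence[tuple[ResidueId, str]],
) -> list[tuple[ResidueId, str]]:
    """Keep externally suggested mutations that fall on dynamic residues.

    ``suggestions`` are (residue id, proposed substitution) pairs, e.g.
    from a multi-state design run; unknown residue ids are dropped with
    a warning.  The intersection of the geometric (dynamic-simplex) and
    energetic (design) filters is the final candidate list.
    """
    known = set()
    for s in report.all_simplices:
        known |= s
    out = []
    for rid, mutation in suggestions:
        if rid not in known:
            warnings.warn(
                f"suggestion {mutation!r} at unknown residue {rid}; dropped",
                stacklevel=2,
            )
            continue
        if rid in report.dynamic_residues:
            out.append((rid, mutation))
    return out
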