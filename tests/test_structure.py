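"""Differential Delaunay tessellation of residue packing."""

import itertools

import numpy as np
import pytest

from thermocycle import (
    ResiduePointSet,
    candidate_intersection,
    dynamic_simplices,
    residue_centroids,
    score_bands,
    score_simplices,
    tessellate,
)
from thermocycle.structure import deterministic_jitter
from thermocycle.synthetic import gen_toy_structures

# Hand-written three-residue fragment: ALA (one side-chain atom, CB),
# GLY (no side chain, Cα rule), SER (two side-chain atoms, true centroid),
# plus a water that must be excluded.
MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.000   0.000   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.000   1.500   0.000  1.00  0.00           C
ATOM      6  N   GLY A   2       4.000   0.000   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       5.000   0.500   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       6.000   0.000   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       7.000   0.000   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       8.000   0.000   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       9.000   0.000   0.000  1.00  0.00           C
ATOM     12  C   SER A   3      10.000   0.000   0.000  1.00  0.00           C
ATOM     13  O   SER A   3      11.000   0.000   0.000  1.00  0.00           O
ATOM     14  CB  SER A   3       9.000   1.000   1.000  1.00  0.00           C
ATOM     15  OG  SER A   3       9.000   2.000   2.000  1.00  0.00           O
HETATM   16  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def toy_pair(tmp_path):
    toy = gen_toy_structures(n_residues=20, displaced=(4, 8), out_dir=tmp_path)
    a = residue_centroids(toy["paths"]["open"], conformation="open")
    b = residue_centroids(toy["paths"]["closed"], conformation="closed")
    return a, b, toy["truth"]


class TestResidueCentroids:
    def test_representative_points(self, mini_pdb):
        ps = residue_centroids(mini_pdb, chain="A")
        assert ps.residue_ids == [("A", 1), ("A", 2), ("A", 3)]
        np.testing.assert_allclose(ps.points[0], [1.0, 1.5, 0.0])  # ALA → CB
        np.testing.assert_allclose(ps.points[1], [5.0, 0.5, 0.0])  # GLY → CA
        np.testing.assert_allclose(ps.points[2], [9.0, 1.5, 1.5])  # SER → mean(CB, OG)
        assert ps.residue_names[("A", 3)] == "SER"
        assert ("A", 101) not in ps.residue_ids  # water excluded

    def test_ca_representation(self, mini_pdb):
        ps = residue_centroids(mini_pdb, point="ca")
        np.testing.assert_allclose(ps.points[0], [1.0, 0.0, 0.0])

    def test_missing_chain_errors(self, mini_pdb):
        with pytest.raises(ValueError, match="chain 'B'"):
            residue_centroids(mini_pdb, chain="B")


def brute_force_delaunay(points):
    """Oracle: every 4-point subset whose circumsphere is empty."""
    n = len(points)
    simplices = set()
    for quad in itertools.combinations(range(n), 4):
        p = points[list(quad)]
        # circumcenter from |x−c|² equal on all four vertices
        A = 2 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(1) - (p[0] ** 2).sum()
        try:
            c = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue  # coplanar quadruple: no circumsphere
        r2 = ((p[0] - c) ** 2).sum()
        others = [i for i in range(n) if i not in quad]
        d2 = ((points[others] - c) ** 2).sum(1)
        if np.all(d2 >= r2 - 1e-9):
            simplices.add(frozenset(quad))
    return simplices


def _point_set(coords, label="conf"):
    ids = [("A", i + 1) for i in range(len(coords))]
    names = {rid: "ALA" for rid in ids}
    return ResiduePointSet(label, ids, np.asarray(coords, float), names)


def _oracle_simplices(ps):
    """Brute-force tessellation of the same jittered coordinates."""
    coords = ps.points + deterministic_jitter(ps.residue_ids)
    quads = brute_force_delaunay(coords)
    return {frozenset(ps.residue_ids[i] for i in q) for q in quads}


class TestTessellate:
    def test_triangular_bipyramid_has_two_simplices(self):
        coords = [
            [1, 0, 0], [-0.5, 0.87, 0], [-0.5, -0.87, 0], [0, 0, 1.2], [0, 0, -1.2],
        ]
        ps = _point_set(coords)
        ts = tessellate(ps, max_edge=np.inf)
        assert len(ts.simplices) == 2
        assert ts.simplices == _oracle_simplices(ps)

    def test_four_noncoplanar_points_single_simplex(self):
        ps = _point_set([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        ts = tessellate(ps, max_edge=np.inf)
        assert len(ts.simplices) == 1

    def test_fewer_than_four_points_is_structural_error(self):
        with pytest.raises(ValueError, match="≥ 4"):
            tessellate(_point_set([[0, 0, 0], [1, 0, 0], [0, 1, 0]]))

    def test_degenerate_cube_with_center_matches_oracle(self):
        cube = list(itertools.product((0.0, 3.0), repeat=3))
        ps = _point_set(cube + [[1.5, 1.5, 1.5]])
        ts = tessellate(ps, max_edge=np.inf)
        assert ts.simplices == _oracle_simplices(ps)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_points_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        ps = _point_set(10 * rng.random((n, 3)))
        ts = tessellate(ps, max_edge=np.inf)
        assert ts.simplices == _oracle_simplices(ps)

    @pytest.mark.parametrize("seed", range(5))
    def test_empty_circumsphere_property_post_hoc(self, seed):
        rng = np.random.default_rng(50 + seed)
        ps = _point_set(12 * rng.random((12, 3)))
        ts = tessellate(ps, max_edge=np.inf)
        coords = ps.points + deterministic_jitter(ps.residue_ids)
        index = {rid: i for i, rid in enumerate(ps.residue_ids)}
        for simplex in ts.simplices:
            quad = [index[rid] for rid in simplex]
            p = coords[quad]
            A = 2 * (p[1:] - p[0])
            b = (p[1:] ** 2).sum(1) - (p[0] ** 2).sum()
            c = np.linalg.solve(A, b)
            r2 = ((p[0] - c) ** 2).sum()
            others = [i for i in range(len(coords)) if i not in quad]
            assert np.all(((coords[others] - c) ** 2).sum(1) >= r2 - 1e-9)

    def test_edge_filter_drops_long_simplices(self):
        rng = np.random.default_rng(1)
        ps = _point_set(10 * rng.random((10, 3)))
        full = tessellate(ps, max_edge=np.inf)
        cut = tessellate(ps, max_edge=6.0)
        assert cut.simplices <= full.simplices
        assert all(cut.max_edge[s] <= 6.0 for s in cut.simplices)
        assert all(full.max_edge[s] > 6.0 for s in full.simplices - cut.simplices)


class TestDynamicSimplices:
    def test_identical_conformations_have_no_dynamic_simplices(self):
        rng = np.random.default_rng(2)
        coords = 10 * rng.random((10, 3))
        report = dynamic_simplices(
            [tessellate(_point_set(coords, "a")), tessellate(_point_set(coords, "b"))]
        )
        assert report.dynamic == set()
        assert report.dynamic_residues == set()

    def test_displaced_point_flips_exactly_the_differing_simplices(self):
        rng = np.random.default_rng(4)
        coords = 8 * rng.random((10, 3))
        moved = coords.copy()
        moved[3] += [6.0, 0, 0]
        ps_a, ps_b = _point_set(coords, "a"), _point_set(moved, "b")
        ts_a = tessellate(ps_a, max_edge=np.inf)
        ts_b = tessellate(ps_b, max_edge=np.inf)
        report = dynamic_simplices([ts_a, ts_b])
        # oracle: symmetric set algebra on brute-force tessellations
        oa, ob = _oracle_simplices(ps_a), _oracle_simplices(ps_b)
        assert report.invariant == oa & ob
        assert report.dynamic == (oa | ob) - (oa & ob)

    def test_symmetric_in_conformation_order_and_partitions(self, toy_pair):
        a, b, _ = toy_pair
        ts_a, ts_b = tessellate(a), tessellate(b)
        r1 = dynamic_simplices([ts_a, ts_b])
        r2 = dynamic_simplices([ts_b, ts_a])
        assert r1.invariant == r2.invariant and r1.dynamic == r2.dynamic
        union = ts_a.simplices | ts_b.simplices
        assert r1.invariant | r1.dynamic == union
        assert r1.invariant & r1.dynamic == set()

    def test_three_conformations_invariant_is_intersection(self):
        rng = np.random.default_rng(9)
        coords = 8 * rng.random((9, 3))
        tessellations = []
        for k in range(3):
            c = coords.copy()
            c[k] += [5.0, 0, 0]  # cyclically moving point
            tessellations.append(tessellate(_point_set(c, f"c{k}"), max_edge=np.inf))
        report = dynamic_simplices(tessellations)
        assert report.invariant == set.intersection(
            *[t.simplices for t in tessellations]
        )

    def test_mismatched_universe_is_structural_error(self):
        rng = np.random.default_rng(6)
        a = _point_set(10 * rng.random((8, 3)), "a")
        b = _point_set(10 * rng.random((7, 3)), "b")
        with pytest.raises(ValueError, match="symmetric difference"):
            dynamic_simplices([tessellate(a, np.inf), tessellate(b, np.inf)])

    def test_rigid_motion_of_all_conformations_leaves_report_unchanged(self, toy_pair):
        a, b, _ = toy_pair
        base = dynamic_simplices([tessellate(a), tessellate(b)])
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([12.0, -4.0, 7.5])
        moved = dynamic_simplices(
            [
                tessellate(a.transformed(rot, shift)),
                tessellate(b.transformed(rot, shift)),
            ]
        )
        assert moved.invariant == base.invariant
        assert moved.dynamic == base.dynamic
        assert moved.dynamic_residues == base.dynamic_residues

    def test_toy_truth_residues_are_recovered_as_dynamic(self, toy_pair):
        a, b, truth = toy_pair
        report = dynamic_simplices([tessellate(a), tessellate(b)])
        dynamic_numbers = {rid[1] for rid in report.dynamic_residues}
        assert set(truth["displaced_residues"]) <= dynamic_numbers


class TestScoring:
    def _scored(self, table):
        rng = np.random.default_rng(3)
        ps = _point_set(8 * rng.random((8, 3)))
        ts = tessellate(ps, max_edge=np.inf)
        return ts, score_simplices(ts, table)

    def test_uniform_table_gives_zero_scores_outside_both_bands(self):
        table = {("ALA", "ALA", "ALA", "ALA"): 0.0}
        _, scored = self._scored(table)
        bands = score_bands(scored)
        assert all(v == 0.0 for v in scored.scores.values())
        assert bands["high"] == set() and bands["negative"] == set()

    def test_hand_built_table_places_simplex_in_high_band(self):
        table = {("ALA", "ALA", "ALA", "ALA"): 1.0}
        _, scored = self._scored(table)
        assert all(v == 1.0 for v in scored.scores.values())
        assert score_bands(scored)["high"] == scored.simplices

    def test_band_counts_equal_independent_recount(self):
        rng = np.random.default_rng(12)
        ps = _point_set(8 * rng.random((10, 3)))
        ts = tessellate(ps, max_edge=np.inf)
        # random per-simplex scores via a composition table keyed by the
        # (single) ALA composition won't vary; vary residue names instead
        names = ["ALA", "GLY", "SER", "PHE", "ILE"]
        for i, rid in enumerate(ts.residue_ids):
            ts.residue_names[rid] = names[i % len(names)]
        comps = {
            tuple(sorted(ts.residue_names[r] for r in s)) for s in ts.simplices
        }
        table = {c: float(rng.normal()) for c in comps}
        scored = score_simplices(ts, table)
        bands = score_bands(scored)
        high = sum(1 for s in scored.simplices if scored.scores[s] > 0.6)
        neg = sum(1 for s in scored.simplices if scored.scores[s] < 0.0)
        assert len(bands["high"]) == high and len(bands["negative"]) == neg

    def test_missing_composition_is_an_error_naming_it(self):
        with pytest.raises(KeyError, match="ALA"):
            self._scored({("GLY", "GLY", "GLY", "GLY"): 0.0})


class TestCandidateIntersection:
    def _report(self):
        # compact 20-point globule with one displaced point: a local
        # rearrangement, so dynamic residues are a proper subset
        from thermocycle.synthetic import _chain_coordinates

        coords = _chain_coordinates(20, seed=0)
        moved = coords.copy()
        moved[3] += [3.0, 0, 0]
        return dynamic_simplices(
            [
                tessellate(_point_set(coords, "a")),
                tessellate(_point_set(moved, "b")),
            ]
        )

    def test_empty_suggestions_give_empty_output(self):
        assert candidate_intersection(self._report(), []) == []

    def test_suggestions_on_invariant_residues_are_filtered_out(self):
        report = self._report()
        static = sorted(
            set().union(*report.invariant) - report.dynamic_residues
        )[:2]
        suggestions = [(rid, "I4V") for rid in static]
        assert candidate_intersection(report, suggestions) == []

    def test_intersection_against_known_dynamic_set(self):
        report = self._report()
        dyn = sorted(report.dynamic_residues)[:2]
        static = sorted(
            set().union(*report.all_simplices) - report.dynamic_residues
        )[:1]
        suggestions = [(dyn[0], "I4V"), (dyn[1], "F26L"), (static[0], "Y33F")]
        got = candidate_intersection(report, suggestions)
        assert got == [(dyn[0], "I4V"), (dyn[1], "F26L")]

    def test_unknown_residue_warns_and_drops(self):
        report = self._report()
        with pytest.warns(UserWarning, match="unknown residue"):
            got = candidate_intersection(report, [(("Z", 999), "F37I")])
        assert got == []
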