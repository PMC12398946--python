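"""Distances, dihedrals, chi1, Burgi-Dunitz and butterfly-bend constructions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from putachannel.errors import AtomNotFoundError, DegenerateGeometryError, EmptySelectionError
from putachannel.geometry import (
    active_site_separation,
    burgi_dunitz,
    butterfly_bend,
    chi1,
    dihedral,
    distance,
    gate_distance_static,
    geometry_report,
    min_group_distance,
)

from conftest import (
    make_atom,
    make_model,
    place_by_internal,
    random_rotation,
    synthetic_flavin,
)

coords = st.floats(min_value=-50, max_value=50, allow_nan=False)
vec3 = st.tuples(coords, coords, coords).map(np.array)


class TestDistance:
    def test_identical_and_pythagorean(self):
        a = make_atom("A1", (0, 0, 0))
        b = make_atom("A2", (3, 4, 0))
        assert distance(a, a) == 0.0
        assert distance(a, b) == pytest.approx(5.0)
        assert distance(b, a) == pytest.approx(5.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(vec3, vec3, vec3)
    def test_triangle_inequality(self, p, q, r):
        assert distance(p, r) <= distance(p, q) + distance(q, r) + 1e-9


class TestMinGroupDistance:
    def test_shared_position_gives_zero(self):
        ga = [make_atom("C1", (1, 2, 3)), make_atom("C2", (9, 9, 9))]
        gb = [make_atom("N1", (1, 2, 3))]
        assert min_group_distance(ga, gb) == 0.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        ga = [make_atom(f"A{i}", p) for i, p in enumerate(rng.normal(size=(20, 3)) * 10)]
        gb = [make_atom(f"B{i}", p) for i, p in enumerate(rng.normal(size=(20, 3)) * 10)]
        brute = min(
            np.linalg.norm(x.position - y.position) for x in ga for y in gb
        )
        assert min_group_distance(ga, gb) == pytest.approx(brute, rel=1e-12)

    def test_hydrogens_excluded_and_empty_group_errors(self):
        ga = [make_atom("H1", (0, 0, 0), element="H")]
        gb = [make_atom("C1", (1, 0, 0))]
        with pytest.raises(EmptySelectionError):
            min_group_distance(ga, gb, heavy_only=True)


class TestDihedral:
    def _frame(self, torsion):
        a = np.array([1.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.5, 0.0, 0.0])
        d = place_by_internal(a, b, c, 1.5, 109.5, torsion)
        return a, b, c, d

    @pytest.mark.parametrize("torsion", [0.0, 180.0, 60.0, -60.0, 137.2])
    def test_constructed_torsions(self, torsion):
        a, b, c, d = self._frame(torsion)
        assert dihedral(a, b, c, d) == pytest.approx(torsion, abs=1e-8)

    def test_reversal_symmetry(self):
        a, b, c, d = self._frame(73.0)
        assert dihedral(d, c, b, a) == pytest.approx(dihedral(a, b, c, d), abs=1e-8)

    def test_mirror_flips_sign(self):
        a, b, c, d = self._frame(73.0)
        mirror = np.diag([1.0, 1.0, -1.0])
        pts = [p @ mirror for p in (a, b, c, d)]
        assert dihedral(*pts) == pytest.approx(-73.0, abs=1e-8)

    def test_rigid_motion_invariance(self):
        a, b, c, d = self._frame(-118.0)
        rng = np.random.default_rng(3)
        for _ in range(5):
            rot = random_rotation(rng)
            t = rng.normal(size=3) * 20
            pts = [p @ rot.T + t for p in (a, b, c, d)]
            assert dihedral(*pts) == pytest.approx(dihedral(a, b, c, d), abs=1e-9)

    def test_collinear_errors(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestChi1:
    def _residue(self, resname, gamma_name, chi):
        n = np.array([0.0, 1.45, 0.0])
        ca = np.array([0.0, 0.0, 0.0])
        cb = place_by_internal((1.0, 2.0, 0.5), n, ca, 1.53, 110.5, 122.0)
        g = place_by_internal(n, ca, cb, 1.42, 110.0, chi)
        return [
            make_atom("N", n, resname=resname, resnum=844),
            make_atom("CA", ca, resname=resname, resnum=844),
            make_atom("CB", cb, resname=resname, resnum=844),
            make_atom(gamma_name, g, resname=resname, resnum=844),
        ]

    @pytest.mark.parametrize(
        "resname,gamma,chi", [("SER", "OG", 55.0), ("CYS", "SG", -69.0), ("THR", "OG1", 180.0)]
    )
    def test_constructed_rotamers(self, resname, gamma, chi):
        model = make_model(self._residue(resname, gamma, chi))
        assert chi1(model, "A", 844) == pytest.approx(chi, abs=1e-6)

    def test_glycine_has_no_chi1(self):
        model = make_model([make_atom("N", (0, 1.4, 0), resname="GLY"),
                            make_atom("CA", (0, 0, 0), resname="GLY")])
        with pytest.raises(AtomNotFoundError):
            chi1(model, "A", 1)

    def test_missing_gamma_named_in_error(self):
        atoms = self._residue("SER", "OG", 55.0)[:3]
        with pytest.raises(AtomNotFoundError, match="OG"):
            chi1(make_model(atoms), "A", 844)


class TestBurgiDunitz:
    def test_collinear_and_right_angle(self):
        c = make_atom("C", (0, 0, 0))
        o = make_atom("O", (0, 0, 1.23))
        nu_lin = make_atom("OG", (0, 0, -2.8))
        nu_rt = make_atom("OG", (2.8, 0, 0))
        assert burgi_dunitz(nu_lin, c, o) == pytest.approx(180.0)
        assert burgi_dunitz(nu_rt, c, o) == pytest.approx(90.0)

    def test_constructed_attack_angle(self):
        theta = np.radians(107.0)
        c = make_atom("C", (0, 0, 0))
        o = make_atom("O", (0, 0, 1.23))
        nu = make_atom("SG", (2.9 * np.sin(theta), 0, 2.9 * np.cos(theta)))
        assert burgi_dunitz(nu, c, o) == pytest.approx(107.0, abs=1e-9)

    def test_rigid_motion_invariance_and_range(self):
        rng = np.random.default_rng(8)
        c = make_atom("C", (0, 0, 0))
        o = make_atom("O", (0, 0, 1.23))
        nu = make_atom("SG", (2.0, 1.0, -1.5))
        ref = burgi_dunitz(nu, c, o)
        assert 0.0 <= ref <= 180.0
        for _ in range(5):
            rot = random_rotation(rng)
            t = rng.normal(size=3) * 15
            moved = [
                make_atom(a.atom_name, a.position @ rot.T + t) for a in (nu, c, o)
            ]
            assert burgi_dunitz(*moved) == pytest.approx(ref, abs=1e-9)

    def test_coincident_atoms_error(self):
        c = make_atom("C", (0, 0, 0))
        with pytest.raises(DegenerateGeometryError):
            burgi_dunitz(c, c, make_atom("O", (0, 0, 1)))


class TestButterflyBend:
    @pytest.mark.parametrize("fold", [0.0, 5.0, 10.0, 20.0, 40.0])
    def test_constructed_fold_angles(self, fold):
        model = make_model(synthetic_flavin(fold))
        assert butterfly_bend(model, "A") == pytest.approx(fold, abs=0.5)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(21)
        atoms = synthetic_flavin(25.0)
        ref = butterfly_bend(make_model(atoms), "A")
        rot = random_rotation(rng)
        t = rng.normal(size=3) * 30
        moved = [
            make_atom(a.atom_name, a.position @ rot.T + t, resname="FAD", resnum=500)
            for a in atoms
        ]
        assert butterfly_bend(make_model(moved), "A") == pytest.approx(ref, abs=1e-9)

    def test_c4a_alias_accepted(self):
        atoms = [
            make_atom("C4A" if a.atom_name == "C4X" else a.atom_name, a.position,
                      resname="FAD", resnum=500)
            for a in synthetic_flavin(20.0)
        ]
        assert butterfly_bend(make_model(atoms), "A") == pytest.approx(20.0, abs=0.5)

    def test_missing_ring_atom_named(self):
        atoms = [a for a in synthetic_flavin(10.0) if a.atom_name != "C7"]
        with pytest.raises(AtomNotFoundError, match="C7"):
            butterfly_bend(make_model(atoms), "A")


class TestSiteMetrics:
    def test_gate_distance_echoes_construction(self):
        atoms = [
            make_atom("CZ", (0, 0, 0), resname="ARG", resnum=488),
            make_atom("CD", (3.9, 0, 0), resname="GLU", resnum=225),
        ]
        assert gate_distance_static(make_model(atoms), "A") == pytest.approx(3.9)

    def test_truncated_side_chain_errors(self):
        atoms = [
            make_atom("CB", (0, 0, 0), resname="ARG", resnum=488),
            make_atom("CD", (3.9, 0, 0), resname="GLU", resnum=225),
        ]
        with pytest.raises(AtomNotFoundError):
            gate_distance_static(make_model(atoms), "A")

    def test_active_site_separation_analytic(self):
        atoms = [
            make_atom("N5", (0, 0, 0), resname="FAD", resnum=500),
            make_atom("SG", (40, 9, 12), resname="CYS", resnum=844),
        ]
        expect = np.linalg.norm([40.0, 9.0, 12.0])
        assert active_site_separation(make_model(atoms), "A") == pytest.approx(expect)
        coincident = [
            make_atom("N5", (1, 1, 1), resname="FAD", resnum=500),
            make_atom("OG", (1, 1, 1), resname="SER", resnum=844),
        ]
        assert active_site_separation(make_model(coincident), "A") == 0.0

    def test_geometry_report_isolates_missing_metrics(self):
        model = make_model(synthetic_flavin(20.0))
        report = geometry_report(model, "A")
        assert report["butterfly_bend"]["value"] == pytest.approx(20.0, abs=0.5)
        assert "error" in report["gate_distance"]

    def test_geometry_report_ligand_metrics(self):
        atoms = synthetic_flavin(20.0) + [
            make_atom("C5", (1.2, -1.66, 0.0), resname="P5C", resnum=901, occ=0.73),
            make_atom("N1", (2.0, -2.5, 0.0), resname="P5C", resnum=901, occ=0.73),
            make_atom("CA", (1.0, -6.0, 0.2), resname="PRO", resnum=902),
        ]
        report = geometry_report(make_model(atoms), "A", ligand_resnames=["P5C", "PRO"])
        # flavin N5 sits at (1.2, 0, 0): the adduct bond length is the
        # constructed 1.66 A offset
        assert report["n5_c5_bond"]["value"] == pytest.approx(1.66, abs=1e-9)
        assert report["occupancy_P5C"]["value"] == pytest.approx(0.73)
        expect = min(
            np.linalg.norm(np.array([1.2, -1.66, 0.0]) - np.array([1.0, -6.0, 0.2])),
            np.linalg.norm(np.array([2.0, -2.5, 0.0]) - np.array([1.0, -6.0, 0.2])),
        )
        assert report["secondary_site_distance"]["value"] == pytest.approx(expect)
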