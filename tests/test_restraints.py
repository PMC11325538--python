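"""TR coordinate measurement, dihedral enumeration, restraint energies."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from abfekit.anchors import AnchorSet, SearchZone, select_anchors
from abfekit.restraints import (RestraintSchedule, TRRestraint, build_restraints,
                                conformational_energy, dihedral_deg,
                                enumerate_ligand_dihedrals, manifest_dict,
                                measure_tr_coordinates, read_manifest,
                                restraint_energy, tr_restraint_energy,
                                wrap_degrees, write_disang, write_manifest)
from abfekit.structio import perceive_bonds

from conftest import build_structure


def _anchor_fixture():
    # P3, P2, P1 protein; L1, L2, L3 ligand — trans arrangement in the xy plane
    positions = [
        [-1.0, 1.0, 0.0],   # 1 P3 (opposite side from L1: trans about P2-P1)
        [0.0, 1.0, 0.0],    # 2 P2
        [0.0, 0.0, 0.0],    # 3 P1
        [5.0, 0.0, 0.0],    # 4 L1
        [5.0, -3.0, 0.0],   # 5 L2
        [8.0, -3.0, 0.0],   # 6 L3
    ]
    s = build_structure(positions, names=["C", "CA", "N", "C1", "C2", "C3"],
                        roles=["protein"] * 3 + ["ligand"] * 3)
    anchors = AnchorSet(P1=3, P2=2, P3=1, L1=4, L2=5, L3=6,
                        zone=SearchZone(center=np.array([5.0, 0.0, 0.0]), radius=3.0))
    return s, anchors


class TestMeasureTRCoordinates:
    def test_axis_aligned_distance(self):
        s, anchors = _anchor_fixture()
        r, *_ = measure_tr_coordinates(s, anchors)
        assert r == pytest.approx(5.0)

    def test_perpendicular_theta(self):
        s, anchors = _anchor_fixture()
        _, theta, Theta, *_ = measure_tr_coordinates(s, anchors)
        assert theta == pytest.approx(90.0)   # P2-P1-L1
        assert Theta == pytest.approx(90.0)   # P1-L1-L2

    def test_coplanar_trans_dihedral_is_180(self):
        s, anchors = _anchor_fixture()
        *_, phi, Phi, Psi = measure_tr_coordinates(s, anchors)
        assert phi == pytest.approx(180.0)    # P3-P2-P1-L1 trans
        assert Phi == pytest.approx(180.0)    # P2-P1-L1-L2 trans
        assert Psi == pytest.approx(180.0)    # P1-L1-L2-L3 trans

    def test_coincident_anchors_are_an_error(self):
        s, anchors = _anchor_fixture()
        bad = s.with_positions(np.vstack([s.positions()[:3],
                                          [[0.0, 0.0, 0.0]], s.positions()[4:]]))
        with pytest.raises(ValueError, match="undefined|coincide"):
            measure_tr_coordinates(bad, anchors)

    def test_invariant_under_rigid_transform(self):
        s, anchors = _anchor_fixture()
        ref = measure_tr_coordinates(s, anchors)
        Q = Rotation.random(random_state=2).as_matrix()
        moved = s.with_positions(s.positions() @ Q.T + np.array([3.0, -7.0, 11.0]))
        got = measure_tr_coordinates(moved, anchors)
        np.testing.assert_allclose(got, ref, atol=1e-9)


class TestRestraintEnergy:
    def _tr(self, **kwargs):
        s, anchors = _anchor_fixture()
        coords = measure_tr_coordinates(s, anchors)
        return TRRestraint(anchors, *coords, **kwargs)

    def test_zero_at_references_any_scale(self):
        tr = self._tr()
        values = tr.references
        for scale in (0.0, 0.3, 1.0):
            assert tr_restraint_energy(values, tr, scale) == 0.0

    def test_half_k_dx_squared_for_distance(self):
        tr = self._tr(k_r=10.0)
        values = (tr.r0 + 1.0,) + tr.references[1:]
        assert tr_restraint_energy(values, tr, 1.0) == pytest.approx(5.0)

    def test_dihedral_wrap_uses_short_arc(self):
        anchors = self._tr().anchors
        tr = TRRestraint(anchors, 5.0, 90.0, 90.0, -179.0, 0.0, 0.0,
                         k_r=10.0, k_phi=100.0)
        values = (5.0, 90.0, 90.0, 179.0, 0.0, 0.0)
        expected = 0.5 * 100.0 * math.radians(2.0) ** 2
        assert tr_restraint_energy(values, tr, 1.0) == pytest.approx(expected)
        assert tr_restraint_energy(values, tr, 1.0) < 0.1  # not the 358° arc

    def test_scale_out_of_range_rejected(self):
        tr = self._tr()
        with pytest.raises(ValueError, match="scale"):
            tr_restraint_energy(tr.references, tr, 1.5)

    def test_dispatch_matches_direct_calls(self):
        tr = self._tr()
        assert restraint_energy(tr.references, tr, 0.5) == tr_restraint_energy(
            tr.references, tr, 0.5)

    @given(delta=st.floats(min_value=0.0, max_value=720.0))
    def test_wrap_symmetry_of_dihedral_energy(self, delta):
        anchors = self._tr().anchors
        tr = TRRestraint(anchors, 5.0, 90.0, 90.0, 30.0, 0.0, 0.0, k_phi=100.0)
        up = (5.0, 90.0, 90.0, 30.0 + delta, 0.0, 0.0)
        down = (5.0, 90.0, 90.0, 30.0 - delta, 0.0, 0.0)
        assert tr_restraint_energy(up, tr, 1.0) == pytest.approx(
            tr_restraint_energy(down, tr, 1.0), abs=1e-9)

    @given(x=st.floats(min_value=-1e4, max_value=1e4))
    def test_wrap_degrees_lands_in_half_open_interval(self, x):
        w = wrap_degrees(x)
        assert -180.0 < w <= 180.0
        assert abs(math.remainder(x - w, 360.0)) < 1e-6


class TestDihedralEnumeration:
    def test_butane_like_chain_has_one_dihedral(self):
        s = build_structure([[0, 0, 0], [1.5, 0, 0], [2.3, 1.3, 0], [3.8, 1.3, 0]],
                            bonds=[(1, 2), (2, 3), (3, 4)])
        assert enumerate_ligand_dihedrals(s) == [(1, 2, 3, 4)]

    def test_terminal_hydrogens_are_excluded(self):
        s = build_structure(
            [[0, 0, 0], [1.5, 0, 0], [2.3, 1.3, 0], [3.8, 1.3, 0], [-0.6, 0.9, 0]],
            elements=["C", "C", "C", "C", "H"],
            bonds=[(1, 2), (2, 3), (3, 4), (1, 5)])
        assert enumerate_ligand_dihedrals(s) == [(1, 2, 3, 4)]

    def test_branched_toy_matches_bruteforce_graph_walk(self):
        rng = np.random.default_rng(5)
        # 12 heavy atoms in a random tree with an extra ring-closing bond
        pos = rng.uniform(0, 8, size=(12, 3))
        bonds = [(i + 1, int(rng.integers(1, i + 1))) for i in range(1, 12)]
        bonds.append((1, 12))
        bonds = [tuple(sorted(b)) for b in bonds]
        s = build_structure(pos, bonds=bonds)
        got = set(enumerate_ligand_dihedrals(s))
        adj = {i: set() for i in range(1, 13)}
        for a, b in bonds:
            adj[a].add(b)
            adj[b].add(a)
        expected = set()
        for j in adj:
            for k in adj[j]:
                for i in adj[j] - {k}:
                    for l in adj[k] - {j, i}:
                        quad = (i, j, k, l)
                        expected.add(min(quad, quad[::-1]))
        assert got == expected


class TestBuildRestraints:
    def test_references_measured_from_input_conformation(self, toy_complex, toy_zone):
        s = perceive_bonds(toy_complex)
        anchors = select_anchors(s, 2, 6, 10, toy_zone)
        bundle = build_restraints(s, anchors)
        assert bundle.tr.references == measure_tr_coordinates(s, anchors)
        # energy of the build conformation at full scale is exactly zero
        assert tr_restraint_energy(measure_tr_coordinates(s, anchors), bundle.tr, 1.0) == 0.0
        values = [dihedral_deg(*(s.atom(i).position for i in d.serials))
                  for d in bundle.ligand_conf.dihedrals]
        assert conformational_energy(values, bundle.ligand_conf, 1.0) == 0.0

    def test_com_restraints_cover_backbone_and_ligand(self, toy_complex, toy_zone):
        s = perceive_bonds(toy_complex)
        anchors = select_anchors(s, 2, 6, 10, toy_zone)
        bundle = build_restraints(s, anchors)
        assert len(bundle.com) == 2
        for com in bundle.com:
            assert len(com.serials) > 0

    def test_manifest_roundtrip(self, tmp_path, toy_complex, toy_zone):
        s = perceive_bonds(toy_complex)
        anchors = select_anchors(s, 2, 6, 10, toy_zone)
        bundle = build_restraints(s, anchors)
        path = tmp_path / "manifest.json"
        write_manifest(bundle, path)
        back = read_manifest(path)
        assert manifest_dict(back) == manifest_dict(bundle)

    def test_disang_lists_all_restraints(self, tmp_path, toy_complex, toy_zone):
        s = perceive_bonds(toy_complex)
        anchors = select_anchors(s, 2, 6, 10, toy_zone)
        bundle = build_restraints(s, anchors)
        path = tmp_path / "restraints.rst"
        write_disang(bundle, path)
        text = path.read_text()
        assert text.count("&rst") == 6 + len(bundle.ligand_conf) + len(bundle.protein_conf)


class TestRestraintSchedule:
    def test_attach_must_be_nondecreasing(self):
        RestraintSchedule(factors=(0.0, 0.25, 1.0), mode="attach")
        with pytest.raises(ValueError, match="nondecreasing"):
            RestraintSchedule(factors=(0.0, 0.5, 0.25, 1.0), mode="attach")

    def test_release_must_be_nonincreasing(self):
        RestraintSchedule(factors=(1.0, 0.5, 0.0), mode="release")
        with pytest.raises(ValueError, match="nonincreasing"):
            RestraintSchedule(factors=(1.0, 0.2, 0.5, 0.0), mode="release")

    def test_end_states_required(self):
        with pytest.raises(ValueError, match="end states"):
            RestraintSchedule(factors=(0.1, 1.0), mode="attach")
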