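"""Anchor selection: search zone, L1/L2/L3 rules, pose stability."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abfekit.anchors import (UNSTABLE_POSE, SearchZone, UnstablePose, find_l1,
                             select_anchor_chain, select_anchors,
                             validate_protein_anchors)
from abfekit.structio import apply_superposition, superpose, Superposition

from conftest import build_structure


def _protein(positions):
    return build_structure(positions, names=["CA"] * len(positions),
                           roles=["protein"] * len(positions),
                           resname="ALA", chain="A")


class TestValidateProteinAnchors:
    def test_collinear_anchors_fail_angle_rule(self):
        s = _protein([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        report = validate_protein_anchors(s, 1, 2, 3)
        assert not report.ok
        assert any("angle" in f for f in report.failures())

    def test_well_separated_right_angle_passes(self):
        s = _protein([[0, 0, 0], [10, 0, 0], [10, 10, 0]])
        assert validate_protein_anchors(s, 1, 2, 3).ok

    def test_short_distance_fails_distance_rule(self):
        s = _protein([[0, 0, 0], [1, 0, 0], [1, 10, 0]])
        report = validate_protein_anchors(s, 1, 2, 3, min_dist=5.0)
        assert any("distance" in f for f in report.failures())

    def test_non_backbone_atom_fails_with_reason(self):
        s = build_structure([[0, 0, 0], [10, 0, 0], [10, 10, 0]],
                            names=["CB", "CA", "CA"], roles=["protein"] * 3,
                            resname="ALA", chain="A")
        report = validate_protein_anchors(s, 1, 2, 3)
        assert any("backbone" in f for f in report.failures())

    def test_nonexistent_serial_is_an_error(self):
        s = _protein([[0, 0, 0], [10, 0, 0], [10, 10, 0]])
        with pytest.raises(KeyError):
            validate_protein_anchors(s, 1, 2, 99)


class TestFindL1:
    def test_closest_in_zone_atom_wins(self):
        s = build_structure([[1.7, 0, 0], [3.5, 0, 0]])
        zone = SearchZone(center=np.zeros(3), radius=3.0)
        assert find_l1(s, zone) == 1

    def test_all_atoms_outside_zone_is_unstable_pose(self):
        s = build_structure([[5.0, 0, 0], [7.0, 0, 0]])
        zone = SearchZone(center=np.zeros(3), radius=3.0)
        result = find_l1(s, zone)
        assert isinstance(result, UnstablePose)
        assert result is UNSTABLE_POSE
        assert not result  # falsy sentinel, distinct from an error

    def test_hydrogens_are_not_candidates(self):
        s = build_structure([[0.5, 0, 0], [1.0, 0, 0]], elements=["H", "C"])
        zone = SearchZone(center=np.zeros(3), radius=3.0)
        assert find_l1(s, zone) == 2

    def test_no_ligand_role_is_an_error(self):
        s = _protein([[0, 0, 0]])
        with pytest.raises(ValueError, match="ligand"):
            find_l1(s, SearchZone(center=np.zeros(3), radius=3.0))

    def test_matches_exhaustive_argmin_on_random_ligand(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(-5, 5, size=(50, 3))
        s = build_structure(pos)
        zone = SearchZone(center=np.array([0.5, -0.5, 0.2]), radius=4.0)
        dists = np.linalg.norm(pos - zone.center, axis=1)
        inside = np.where(dists <= zone.radius)[0]
        expected = int(inside[np.argmin(dists[inside])]) + 1
        assert find_l1(s, zone) == expected


class TestSelectAnchorChain:
    def test_exact_right_angle_beats_straight(self):
        # prev_a at origin-y, prev_b at origin; 90° candidate vs 180° candidate
        s = build_structure([[0, 3, 0], [0, 0, 0], [3, 0, 0], [0, -3, 0]])
        assert select_anchor_chain(s, 1, 2, dist_range=(2.5, 5.0)) == 3

    def test_single_in_range_candidate_is_chosen(self):
        s = build_structure([[0, 3, 0], [0, 0, 0], [2.0, 2.0, 0]])
        # candidate 3 at 45° is the only atom in range
        assert select_anchor_chain(s, 1, 2, dist_range=(2.5, 5.0)) == 3

    def test_no_candidate_advises_widening_range(self):
        s = build_structure([[0, 3, 0], [0, 0, 0], [9.0, 0, 0]])
        with pytest.raises(ValueError, match="widen"):
            select_anchor_chain(s, 1, 2, dist_range=(2.5, 5.0))

    def test_matches_exhaustive_argmin_with_tie_break(self):
        rng = np.random.default_rng(23)
        pos = np.vstack([[0, 4, 0], [0, 0, 0], rng.uniform(-5, 5, size=(30, 3))])
        s = build_structure(pos)
        lo, hi = 2.5, 5.0
        best = None
        for serial in range(3, 33):
            p = pos[serial - 1]
            d = np.linalg.norm(p - pos[1])
            if not lo <= d <= hi:
                continue
            v1 = pos[0] - pos[1]
            cosang = np.dot(v1, p - pos[1]) / (np.linalg.norm(v1) * d)
            dev = abs(np.degrees(np.arccos(np.clip(cosang, -1, 1))) - 90.0)
            if best is None or (dev, serial) < best:
                best = (dev, serial)
        assert select_anchor_chain(s, 1, 2, dist_range=(lo, hi)) == best[1]


class TestFullSelection:
    def test_deterministic(self, toy_complex, toy_zone):
        a1 = select_anchors(toy_complex, 2, 6, 10, toy_zone)
        a2 = select_anchors(toy_complex, 2, 6, 10, toy_zone)
        assert a1.ligand_serials == a2.ligand_serials

    def test_anchor_set_invariants_hold(self, toy_complex, toy_zone):
        a = select_anchors(toy_complex, 2, 6, 10, toy_zone)
        assert len(set(a.protein_serials + a.ligand_serials)) == 6
        for serial in a.ligand_serials:
            assert toy_complex.role(serial) == "ligand"
            assert not toy_complex.atom(serial).is_hydrogen
        d12 = np.linalg.norm(toy_complex.atom(a.L1).position - toy_complex.atom(a.L2).position)
        d23 = np.linalg.norm(toy_complex.atom(a.L2).position - toy_complex.atom(a.L3).position)
        assert a.l1l2_range[0] <= d12 <= a.l1l2_range[1]
        assert a.l2l3_range[0] <= d23 <= a.l2l3_range[1]

    def test_frame_covariance_under_rigid_transform(self, toy_complex, toy_zone):
        ref = select_anchors(toy_complex, 2, 6, 10, toy_zone)
        Q = Rotation.random(random_state=4).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        sp = Superposition(rotation=Q, translation=t, rmsd=0.0, atom_mapping=())
        moved = apply_superposition(toy_complex, sp)
        moved_zone = SearchZone(center=Q @ toy_zone.center + t, radius=toy_zone.radius)
        got = select_anchors(moved, 2, 6, 10, moved_zone)
        assert got.ligand_serials == ref.ligand_serials

    def test_unstable_pose_propagates(self, toy_complex):
        far_zone = SearchZone(center=np.array([100.0, 100.0, 100.0]), radius=3.0)
        assert select_anchors(toy_complex, 2, 6, 10, far_zone) is UNSTABLE_POSE

    def test_reselection_after_superposition_matches(self, toy_complex, toy_zone):
        ref = select_anchors(toy_complex, 2, 6, 10, toy_zone)
        Q = Rotation.random(random_state=8).as_matrix()
        sp = Superposition(rotation=Q, translation=np.array([-4.0, 9.0, 1.0]),
                           rmsd=0.0, atom_mapping=())
        moved = apply_superposition(toy_complex, sp)
        back = superpose(moved, toy_complex)
        restored = apply_superposition(moved, back)
        got = select_anchors(restored, 2, 6, 10, toy_zone)
        assert got.ligand_serials == ref.ligand_serials
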