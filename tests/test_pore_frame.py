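"""Kabsch superposition, frame alignment and pore coordinates."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from porewatch import pore_frame as pf
from porewatch.errors import GeometryError, TopologyError
from porewatch.trajectory_core import MoleculeTracks

from oracles import superpose_numeric


def hexamer_ca(n_extra=12, seed=0):
    """A rigid 'hexamer' Cα cloud: a ring plus random interior points."""
    rng = np.random.default_rng(seed)
    angles = np.arange(6) * np.pi / 3
    ring = np.column_stack([2.0 * np.cos(angles), 2.0 * np.sin(angles), np.zeros(6)])
    extra = rng.normal(0, 1.0, size=(n_extra, 3))
    return np.vstack([ring, extra])


class TestKabsch:
    def test_identity_superposition(self):
        ref = hexamer_ca()
        t = pf.kabsch_superpose(ref, ref)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)
        assert t.rmsd < 1e-12

    def test_recovers_known_rigid_transform(self):
        ref = hexamer_ca()
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        mobile = ref @ R.T + shift
        t = pf.kabsch_superpose(mobile, ref)
        np.testing.assert_allclose(t.apply(mobile), ref, atol=1e-9)
        assert t.rmsd < 1e-9
        np.testing.assert_allclose(t.rotation @ R, np.eye(3), atol=1e-9)

    def test_rmsd_matches_numeric_minimisation_under_noise(self):
        rng = np.random.default_rng(7)
        ref = hexamer_ca()
        R = Rotation.from_euler("xyz", [10, -20, 45], degrees=True).as_matrix()
        mobile = ref @ R.T + np.array([0.3, 0.1, -0.2]) + rng.normal(0, 0.05, ref.shape)
        t = pf.kabsch_superpose(mobile, ref)
        oracle_rmsd = superpose_numeric(mobile, ref)
        assert t.rmsd == pytest.approx(oracle_rmsd, abs=1e-5)

    def test_rotation_matches_mdanalysis(self):
        """Independent cross-check against MDAnalysis' superposition."""
        from MDAnalysis.analysis.align import rotation_matrix

        rng = np.random.default_rng(11)
        ref = hexamer_ca()
        mobile = ref @ Rotation.random(random_state=3).as_matrix().T + rng.normal(
            0, 0.1, ref.shape
        )
        t = pf.kabsch_superpose(mobile, ref)
        R_mda, rmsd_mda = rotation_matrix(mobile - mobile.mean(0), ref - ref.mean(0))
        np.testing.assert_allclose(t.rotation, R_mda, atol=1e-8)
        assert t.rmsd == pytest.approx(rmsd_mda, abs=1e-8)

    def test_degenerate_point_set_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            pf.kabsch_superpose(line, line)

    def test_reflection_is_never_returned(self):
        ref = hexamer_ca()
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        t = pf.kabsch_superpose(mirrored, ref)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


def _poredef(reference, orientation=1):
    return pf.PoreFrameDefinition(
        reference_ca=reference,
        pore_ca_indices=np.arange(6),
        pore_residue=40,
        orientation=orientation,
    )


def _mk_tracks(positions):
    F, M, _ = positions.shape
    return MoleculeTracks(
        species="PD",
        positions=positions,
        molecule_ids=np.arange(M),
        times=0.1 * np.arange(F),
    )


class TestAlignTrajectory:
    def test_identity_frame_only_shifts_origin_to_pore_centroid(self):
        ref = hexamer_ca()
        poredef = _poredef(ref)
        ca = ref[None, :, :]
        mol = np.array([[[0.5, 0.5, 1.0]]])
        out = pf.align_trajectory(ca, {"PD": _mk_tracks(mol)}, poredef)
        expected = mol[0, 0] - poredef.pore_centroid
        np.testing.assert_allclose(out.tracks["PD"].positions[0, 0], expected, atol=1e-12)

    def test_rigid_motion_invariance(self):
        ref = hexamer_ca()
        poredef = _poredef(ref)
        mol = np.array([[[0.5, 0.5, 1.0], [-1.0, 0.3, -0.4]]])
        base = pf.align_trajectory(ref[None], {"PD": _mk_tracks(mol)}, poredef)
        R = Rotation.from_euler("xyz", [33, 12, -70], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 2.0])
        moved_ca = (ref @ R.T + shift)[None]
        moved_mol = (mol[0] @ R.T + shift)[None]
        out = pf.align_trajectory(moved_ca, {"PD": _mk_tracks(moved_mol)}, poredef)
        np.testing.assert_allclose(
            out.tracks["PD"].positions, base.tracks["PD"].positions, atol=1e-9
        )

    def test_alignment_is_idempotent(self):
        rng = np.random.default_rng(5)
        ref = hexamer_ca()
        poredef = _poredef(ref)
        ca = ref[None] + rng.normal(0, 0.05, (1,) + ref.shape)
        mol = rng.normal(0, 1, size=(1, 3, 3))
        once = pf.align_trajectory(ca, {"PD": _mk_tracks(mol)}, poredef)
        aligned_ca = np.array([once.transforms[0].apply(ca[0])])
        # after the first pass the Cα cloud sits in the pore frame whose
        # origin is the pore centroid; align against the same convention
        shifted_ref = ref - poredef.pore_centroid
        poredef2 = _poredef(shifted_ref)
        twice = pf.align_trajectory(aligned_ca, once.tracks, poredef2)
        np.testing.assert_allclose(
            twice.tracks["PD"].positions, once.tracks["PD"].positions, atol=1e-9
        )

    def test_orientation_sign_flips_d_pore(self):
        ref = hexamer_ca()
        mol = np.array([[[0.5, 0.5, 1.0], [0.1, -0.2, -0.7]]])
        plus = pf.align_trajectory(ref[None], {"PD": _mk_tracks(mol)}, _poredef(ref, 1))
        minus = pf.align_trajectory(ref[None], {"PD": _mk_tracks(mol)}, _poredef(ref, -1))
        d_plus, r_plus = pf.pore_coordinates(plus.tracks["PD"].positions)
        d_minus, r_minus = pf.pore_coordinates(minus.tracks["PD"].positions)
        np.testing.assert_allclose(d_minus, -d_plus, atol=1e-12)
        np.testing.assert_allclose(r_minus, r_plus, atol=1e-12)

    def test_rmsd_never_increases(self):
        rng = np.random.default_rng(9)
        ref = hexamer_ca()
        poredef = _poredef(ref)
        R = Rotation.random(random_state=1).as_matrix()
        ca = (ref @ R.T + [1, 2, 3] + rng.normal(0, 0.1, ref.shape))[None]
        out = pf.align_trajectory(ca, {}, poredef)
        assert out.transforms[0].rmsd <= out.rmsd_before[0]

    def test_mismatched_ca_count_raises(self):
        ref = hexamer_ca()
        with pytest.raises(TopologyError):
            pf.align_trajectory(ref[None, :5], {}, _poredef(ref))


class TestPoreCoordinates:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0.0, 0.0, 0.0), (0.0, 0.0)),
            ((0.3, 0.4, -0.6), (-0.6, 0.5)),  # 3-4-5 triangle
            ((1.0, 0.0, 2.5), (2.5, 1.0)),
        ],
    )
    def test_known_points(self, point, expected):
        d, r = pf.pore_coordinates(np.array(point))
        assert (d, r) == pytest.approx(expected)

    def test_matches_bruteforce_distance_to_axis(self, rng):
        pts = rng.normal(0, 2, size=(100, 3))
        d, r = pf.pore_coordinates(pts)
        # distance from point to the z axis, computed from the definition
        axis_pt = pts.copy()
        axis_pt[:, 0] = axis_pt[:, 1] = 0.0
        brute_r = np.linalg.norm(pts - axis_pt, axis=1)
        np.testing.assert_allclose(r, brute_r, atol=1e-12)
        np.testing.assert_array_equal(d, pts[:, 2])
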