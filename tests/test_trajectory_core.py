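"""Structure/trajectory loading and centre-of-geometry tracks."""

import numpy as np
import pytest

from porewatch import trajectory_core as tc
from porewatch.errors import (
    ConfigurationError,
    FormatError,
    SelectionError,
    TopologyError,
    ValidationError,
)


class TestLoadStructure:
    def test_pdb_coordinates_converted_to_nm(self, pdb_file):
        s = tc.load_structure(pdb_file)
        assert s.n_atoms == 3
        np.testing.assert_allclose(s.coords[0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.coords[2], [1.25, 2.25, 3.25])
        assert list(s.res_names) == ["ALA", "ALA", "CLA"]

    def test_gro_box_vectors_read(self, gro_file):
        s = tc.load_structure(gro_file)
        np.testing.assert_allclose(s.box, [4.0, 5.0, 6.0])
        np.testing.assert_allclose(s.coords[1], [1.5, 2.5, 3.5])

    def test_truncated_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.gro"
        bad.write_text("tiny system\n    5\n    1ALA     CA    1   1.0")
        with pytest.raises(FormatError):
            tc.load_structure(bad)

    def test_unknown_dialect_raises_configuration_error(self, pdb_file):
        with pytest.raises(ConfigurationError):
            tc.load_structure(pdb_file, dialect="cif")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            tc.load_structure(tmp_path / "nope.pdb")


class TestLoadTrajectory:
    def test_xyz_times_synthesised_from_stride(self, pdb_file, xyz_two_frames):
        top = tc.load_structure(pdb_file)
        traj = tc.load_trajectory(
            xyz_two_frames, top, stride_ns=0.1, box=[10.0, 10.0, 10.0]
        )
        assert traj.n_frames == 2
        np.testing.assert_allclose(traj.times, [0.0, 0.1])
        np.testing.assert_allclose(traj.coords[1, 0], [1.05, 2.05, 3.05])

    def test_missing_stride_raises(self, pdb_file, xyz_two_frames):
        top = tc.load_structure(pdb_file)
        with pytest.raises(ConfigurationError):
            tc.load_trajectory(xyz_two_frames, top, box=[10.0] * 3)

    def test_atom_count_mismatch_raises_topology_error(self, gro_file, xyz_two_frames):
        top = tc.load_structure(gro_file)  # 2 atoms vs 3 in trajectory
        with pytest.raises(TopologyError):
            tc.load_trajectory(xyz_two_frames, top, stride_ns=0.1, box=[10.0] * 3)

    def test_single_frame_trajectory(self, pdb_file, tmp_path):
        p = tmp_path / "one.xyz"
        p.write_text("3\nf\nC 1 2 3\nC 4 5 6\nCl 7 8 9\n")
        top = tc.load_structure(pdb_file)
        traj = tc.load_trajectory(p, top, stride_ns=0.5, box=[10.0] * 3)
        assert traj.n_frames == 1

    def test_nan_coordinate_raises_validation_error(self, pdb_file, tmp_path):
        p = tmp_path / "nan.xyz"
        p.write_text("3\nf\nC nan 2 3\nC 4 5 6\nCl 7 8 9\n")
        top = tc.load_structure(pdb_file)
        with pytest.raises(ValidationError):
            tc.load_trajectory(p, top, stride_ns=0.5, box=[10.0] * 3)


def _tracks_fixture(atom_coords_per_frame, resnames, resids, box=10.0):
    """Assemble Structure + Trajectory around explicit per-frame coordinates."""
    n = len(resnames)
    structure = tc.Structure(
        atom_names=np.array(["X"] * n, dtype=object),
        res_names=np.array(resnames, dtype=object),
        res_ids=np.array(resids),
        chain_ids=np.array([""] * n, dtype=object),
        coords=np.asarray(atom_coords_per_frame[0], dtype=float),
    )
    coords = np.asarray(atom_coords_per_frame, dtype=float)
    F = coords.shape[0]
    traj = tc.Trajectory(
        coords=coords,
        times=0.1 * np.arange(F),
        box=np.tile([box, box, box], (F, 1)),
    )
    return structure, traj


class TestCentersOfGeometry:
    def test_monatomic_track_equals_atom_coordinates(self):
        frames = [[[1.0, 2.0, 3.0]], [[1.5, 2.5, 3.5]]]
        s, t = _tracks_fixture(frames, ["CLA"], [1])
        tr = tc.centers_of_geometry(t, tc.SpeciesSelection("Cl", ["CLA"]), s)
        np.testing.assert_array_equal(tr.positions[:, 0, :], np.asarray(frames)[:, 0])

    def test_two_atom_midpoint(self):
        frames = [[[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]]
        s, t = _tracks_fixture(frames, ["PDO", "PDO"], [1, 1])
        tr = tc.centers_of_geometry(t, tc.SpeciesSelection("PD", ["PDO"]), s)
        np.testing.assert_allclose(tr.positions[0, 0], [0, 0, 0.5])

    def test_molecule_straddling_periodic_boundary_reassembled(self):
        # atoms at z=9.9 and z=0.1 in a 10 nm box: the molecule is whole
        # across the boundary; its centre is 10.0 = 0.0, not 5.0
        frames = [[[0.0, 0.0, 9.9], [0.0, 0.0, 0.1]]]
        s, t = _tracks_fixture(frames, ["PDO", "PDO"], [1, 1])
        tr = tc.centers_of_geometry(t, tc.SpeciesSelection("PD", ["PDO"]), s)
        z = tr.positions[0, 0, 2]
        assert abs(z % 10.0) < 1e-12 or abs(z % 10.0 - 10.0) < 1e-12

    def test_empty_selection_raises(self):
        s, t = _tracks_fixture([[[0.0, 0.0, 0.0]]], ["SOL"], [1])
        with pytest.raises(SelectionError):
            tc.centers_of_geometry(t, tc.SpeciesSelection("Cl", ["CLA"]), s)

    def test_translation_equivariance(self, rng):
        coords = rng.uniform(1, 4, size=(2, 4, 3))
        s, t = _tracks_fixture(coords, ["PDO"] * 2 + ["SOL"] * 2, [1, 1, 2, 2])
        sel = tc.SpeciesSelection("PD", ["PDO"])
        base = tc.centers_of_geometry(t, sel, s)
        v = np.array([0.3, -0.2, 0.7])
        s2, t2 = _tracks_fixture(coords + v, ["PDO"] * 2 + ["SOL"] * 2, [1, 1, 2, 2])
        shifted = tc.centers_of_geometry(t2, sel, s2)
        np.testing.assert_allclose(shifted.positions, base.positions + v, atol=1e-12)

    def test_wrap_invariance(self, rng):
        """Wrapping any atom by integer box vectors leaves centres unchanged."""
        coords = rng.uniform(1, 4, size=(3, 2, 3))
        s, t = _tracks_fixture(coords, ["PDO", "PDO"], [1, 1])
        sel = tc.SpeciesSelection("PD", ["PDO"])
        base = tc.centers_of_geometry(t, sel, s)
        wrapped = coords.copy()
        wrapped[:, 1, :] += np.array([10.0, -20.0, 10.0])  # integer box shifts
        s2, t2 = _tracks_fixture(wrapped, ["PDO", "PDO"], [1, 1])
        out = tc.centers_of_geometry(t2, sel, s2)
        np.testing.assert_allclose(out.positions, base.positions, atol=1e-9)


class TestTrackIO:
    def test_h5_round_trip(self, tmp_path, rng):
        tr = tc.MoleculeTracks(
            species="PD",
            positions=rng.normal(size=(4, 3, 3)),
            molecule_ids=np.arange(3),
            times=0.1 * np.arange(4),
        )
        path = tmp_path / "tracks.h5"
        tc.write_tracks_h5(tr, path)
        back = tc.read_tracks_h5(path)
        assert back.species == "PD"
        np.testing.assert_array_equal(back.positions, tr.positions)

    def test_tsv_has_one_row_per_molecule_frame(self, tmp_path, rng):
        import pandas as pd

        tr = tc.MoleculeTracks(
            species="PD",
            positions=rng.normal(size=(4, 3, 3)),
            molecule_ids=np.arange(3),
            times=0.1 * np.arange(4),
        )
        path = tmp_path / "tracks.tsv"
        tc.write_tracks_tsv(tr, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 12
        assert set(df.columns) == {"molecule_id", "frame", "t_ns", "x_nm", "y_nm", "z_nm"}


class TestTrajectoryInvariants:
    def test_times_must_increase(self):
        with pytest.raises(ValidationError):
            tc.Trajectory(
                coords=np.zeros((2, 1, 3)),
                times=np.array([0.2, 0.1]),
                box=np.tile([5.0, 5.0, 5.0], (2, 1)),
            )
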