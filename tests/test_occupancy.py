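"""Axial occupancy profiles and replica aggregation."""

import numpy as np
import pytest

from porewatch import occupancy as occ
from porewatch.errors import InputError
from porewatch.spatial_density import bulk_density


class TestInCylinder:
    @pytest.mark.parametrize(
        "d,r,expected",
        [
            (0.0, 0.69, True),
            (0.0, 0.71, False),
            (0.0, 0.7, True),  # radial boundary inclusive
            (3.0, 0.0, True),  # axial boundary inclusive
            (3.01, 0.0, False),
            (-3.01, 0.0, False),
        ],
    )
    def test_boundary_conventions(self, d, r, expected):
        spec = occ.CylinderSpec(radius=0.7, z_lo=-3.0, z_hi=3.0)
        assert bool(occ.in_cylinder(d, r, spec)) is expected


class TestAxialProfile:
    def test_single_static_molecule_occupies_one_bin(self):
        pos = np.tile([0.0, 0.0, 0.05], (10, 1, 1))
        spec = occ.CylinderSpec(radius=0.7, z_lo=-0.5, z_hi=0.5)
        p = occ.axial_profile(pos, "PD", spec, bin_width=0.1)
        idx = np.searchsorted(p.bin_edges, 0.05) - 1
        assert p.n_mol[idx] == 1.0
        assert p.n_mol.sum() == 1.0

    def test_half_time_occupancy(self):
        pos = np.zeros((4, 1, 3))
        pos[2:, 0, 0] = 5.0  # outside the cylinder for half the frames
        spec = occ.CylinderSpec(radius=0.7, z_lo=-0.5, z_hi=0.5)
        p = occ.axial_profile(pos, "PD", spec, bin_width=1.0)
        assert p.n_mol.sum() == 0.5

    def test_total_equals_time_averaged_cylinder_occupancy(self, rng):
        """Conservation: sum over bins == direct time-averaged count."""
        pos = rng.uniform(-2, 2, size=(50, 30, 3))
        spec = occ.CylinderSpec(radius=0.7, z_lo=-1.5, z_hi=1.5)
        p = occ.axial_profile(pos, "X", spec, bin_width=0.1)
        d = pos[..., 2]
        r = np.hypot(pos[..., 0], pos[..., 1])
        direct = occ.in_cylinder(d, r, spec).sum() / pos.shape[0]
        assert p.n_mol.sum() == pytest.approx(direct, abs=1e-12)

    def test_invariant_under_frame_reordering(self, rng):
        pos = rng.uniform(-2, 2, size=(20, 10, 3))
        spec = occ.CylinderSpec(radius=0.7, z_lo=-1.5, z_hi=1.5)
        a = occ.axial_profile(pos, "X", spec)
        b = occ.axial_profile(pos[::-1], "X", spec)
        np.testing.assert_array_equal(a.n_mol, b.n_mol)

    def test_uniform_gas_matches_analytic_expectation(self, rng):
        """Ideal gas: per-bin N_mol ~ rho * pi r^2 * dz within 3 SE."""
        L = 5.0
        n, F = 400, 400
        pos = rng.uniform(-L / 2, L / 2, size=(F, n, 3))
        rho = n / L**3
        spec = occ.CylinderSpec(radius=0.7, z_lo=-2.0, z_hi=2.0)
        p = occ.axial_profile(pos, "X", spec, bin_width=0.25)
        expected = rho * np.pi * 0.7**2 * 0.25
        # counts are Poisson-ish: SE of a per-bin mean over F frames;
        # 4 sigma per bin because 16 bins are tested simultaneously
        se = np.sqrt(expected / F)
        assert np.all(np.abs(p.n_mol - expected) < 4 * se + 1e-9)

    def test_zero_frames_rejected(self):
        with pytest.raises(InputError):
            occ.axial_profile(np.empty((0, 1, 3)), "X")


class TestAggregateReplicas:
    def test_identical_profiles_have_zero_se(self):
        edges = np.linspace(-1, 1, 11)
        p = occ.AxialProfile("X", edges, np.ones(10))
        agg = occ.aggregate_replicas([p, p, p])
        np.testing.assert_array_equal(agg.n_mol, p.n_mol)
        np.testing.assert_array_equal(agg.se, 0)
        assert agg.n_replicas == 3

    def test_known_spread(self):
        edges = np.array([0.0, 1.0])
        profiles = [occ.AxialProfile("X", edges, [v]) for v in (1.0, 2.0, 3.0)]
        agg = occ.aggregate_replicas(profiles)
        assert agg.n_mol[0] == pytest.approx(2.0)
        assert agg.se[0] == pytest.approx(1.0 / np.sqrt(3))

    def test_single_replica_warns_and_zero_se(self):
        p = occ.AxialProfile("X", np.array([0.0, 1.0]), [2.0])
        with pytest.warns(UserWarning):
            agg = occ.aggregate_replicas([p])
        assert agg.se[0] == 0.0

    def test_mismatched_bins_rejected(self):
        a = occ.AxialProfile("X", np.array([0.0, 1.0]), [1.0])
        b = occ.AxialProfile("X", np.array([0.0, 2.0]), [1.0])
        with pytest.raises(InputError):
            occ.aggregate_replicas([a, b])


class TestEnrichment:
    def test_uniform_gas_at_bulk_has_unit_ratio(self, rng):
        L = 5.0
        conc = 150.0
        rho = bulk_density(conc)
        n = int(round(rho * L**3))
        pos = rng.uniform(-L / 2, L / 2, size=(3000, n, 3))
        spec = occ.CylinderSpec(radius=0.7, z_lo=-2.0, z_hi=2.0)
        p = occ.axial_profile(pos, "Cl", spec, bin_width=0.5)
        ratio = occ.enrichment_profile(p, conc)
        per_bin = rho * np.pi * 0.7**2 * 0.5
        se = np.sqrt(per_bin / 3000) / per_bin
        assert np.all(np.abs(ratio - 1.0) < 4 * se)

    def test_doubled_density_doubles_ratio(self, rng):
        L = 5.0
        conc = 150.0
        rho = bulk_density(conc)
        n = int(round(2 * rho * L**3))  # twice the bulk concentration
        pos = rng.uniform(-L / 2, L / 2, size=(3000, n, 3))
        spec = occ.CylinderSpec(radius=0.7, z_lo=-2.0, z_hi=2.0)
        ratio = occ.enrichment_profile(
            occ.axial_profile(pos, "Cl", spec, bin_width=0.5), conc
        )
        per_bin = 2 * rho * np.pi * 0.7**2 * 0.5
        se = np.sqrt(per_bin / 3000) / (per_bin / 2)
        assert np.all(np.abs(ratio - 2.0) < 4 * se)

    def test_boltzmann_weighted_gas_recovers_well_depth(self, rng):
        """Enrichment through the occupancy pipeline on a rejection-sampled
        gas with a -2 kT cylindrical well recovers exp(2) in the core."""
        well, r_chan, half, L = -2.0, 0.7, 0.5, 4.0
        n_target = 150_000
        pts = []
        while len(pts) < n_target:
            p = rng.uniform(-L / 2, L / 2, size=(n_target, 3))
            r = np.hypot(p[:, 0], p[:, 1])
            U = np.where((r <= r_chan) & (np.abs(p[:, 2]) <= half), well, 0.0)
            keep = rng.uniform(0, 1, len(p)) < np.exp(-(U - well))
            pts.extend(p[keep])
        pos = np.asarray(pts[:n_target])[:, None, :]
        # effective bulk concentration from the sampled far region
        far = np.abs(pos[..., 2]) > half + 0.5
        rho_bulk = far.sum() / (pos.shape[0] * L**2 * (L - 2 * (half + 0.5)))
        conc = rho_bulk / bulk_density(1.0)
        spec = occ.CylinderSpec(radius=r_chan, z_lo=-half, z_hi=half)
        prof = occ.axial_profile(pos, "ion", spec, bin_width=2 * half)
        ratio = occ.enrichment_profile(prof, conc)[0]
        assert ratio == pytest.approx(np.exp(-well), rel=0.05)

    def test_empty_species_ratio_zero(self):
        p = occ.AxialProfile("Na", np.array([0.0, 0.1]), [0.0])
        assert occ.enrichment_profile(p, 150.0)[0] == 0.0

    def test_zero_bulk_rejected(self):
        p = occ.AxialProfile("Na", np.array([0.0, 0.1]), [0.0])
        with pytest.raises(InputError):
            occ.enrichment_profile(p, 0.0)
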