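"""Pore-radius profiling, RMSF/RMSD and cavity water counts."""

import numpy as np
import pytest

import poreflow as pf
from poreflow.synth import make_cylinder_pore
from tests.conftest import frames_from_positions

Z = np.arange(-10, 10.25, 0.5)


class TestPoreRadius:
    def test_cylinder_value_everywhere(self):
        s = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0, n_rings=31)
        p = pf.pore_radius_profile(s, Z, pf.ProbeParams(seed=0))
        np.testing.assert_allclose(p.radius_mean, 3.5, atol=0.05)

    def test_seed_independence(self):
        s = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0, n_rings=31)
        p1 = pf.pore_radius_profile(s, Z, pf.ProbeParams(seed=1))
        p2 = pf.pore_radius_profile(s, Z, pf.ProbeParams(seed=12345))
        assert np.max(np.abs(p1.radius_mean - p2.radius_mean)) <= 0.05

    def test_hourglass_waist(self):
        s = make_cylinder_pore(lambda z: 6.0 - 3.0 * (1 - abs(z) / 15.0),
                               atom_vdw=1.5, z_extent=30.0, n_rings=61)
        p = pf.pore_radius_profile(s, Z, pf.ProbeParams(seed=0))
        i0 = np.argmin(np.abs(Z))
        assert p.radius_mean[i0] == pytest.approx(1.5, abs=0.05)
        assert np.argmin(p.radius_mean) == i0
        # monotone increase away from the waist (allow optimiser jitter)
        left = p.radius_mean[: i0 + 1]
        right = p.radius_mean[i0:]
        assert np.all(np.diff(left) <= 0.06)
        assert np.all(np.diff(right) >= -0.06)

    def test_adding_atoms_never_widens_the_pore(self):
        wide = make_cylinder_pore(6.0, atom_vdw=1.5, z_extent=30.0, n_rings=31)
        narrow_ring = make_cylinder_pore(4.0, atom_vdw=1.5, z_extent=6.0,
                                         n_rings=7)
        combined = pf.build_structure(
            list(wide.atoms["atom_name"]) + list(narrow_ring.atoms["atom_name"]),
            list(wide.atoms["residue_name"]) + list(narrow_ring.atoms["residue_name"]),
            list(range(1, wide.n_atoms + narrow_ring.n_atoms + 1)),
            np.vstack([wide.positions, narrow_ring.positions]),
        )
        combined.atoms["vdw_radius"] = 1.5
        p_wide = pf.pore_radius_profile(wide, Z, pf.ProbeParams(seed=0))
        p_comb = pf.pore_radius_profile(combined, Z, pf.ProbeParams(seed=0))
        assert np.all(p_comb.radius_mean <= p_wide.radius_mean + 0.02)

    def test_seed_point_inside_atom_raises(self):
        blocked = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0,
                                     n_rings=31)
        plug = pf.build_structure(["C"], ["PLG"], [999],
                                  np.array([[0.0, 0.0, -10.0]]))
        s = pf.build_structure(
            list(blocked.atoms["atom_name"]) + ["C"],
            list(blocked.atoms["residue_name"]) + ["PLG"],
            list(range(1, blocked.n_atoms + 2)),
            np.vstack([blocked.positions, plug.positions]),
        )
        s.atoms["vdw_radius"] = 1.5
        with pytest.raises(pf.SeedPointError):
            pf.pore_radius_profile(s, Z, pf.ProbeParams(seed=0))


class TestTrajectoryProfile:
    def _breathing(self, amp=1.0, n_frames=16):
        base = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0, n_rings=31)
        r0 = np.hypot(base.positions[:, 0], base.positions[:, 1])
        phases = np.linspace(0, 2 * np.pi, n_frames, endpoint=False)
        pos = []
        for ph in phases:
            scale = (5.0 + amp * np.sin(ph)) / 5.0
            p = base.positions.copy()
            p[:, 0] *= scale
            p[:, 1] *= scale
            pos.append(p)
        return base, frames_from_positions(base, np.stack(pos))

    def test_static_trajectory_has_zero_sd(self):
        base = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0, n_rings=16)
        frames = frames_from_positions(base, np.tile(base.positions, (5, 1, 1)))
        p = pf.trajectory_pore_profile(frames, Z, pf.ProbeParams(seed=0))
        np.testing.assert_allclose(p.radius_sd, 0.0, atol=1e-9)

    def test_breathing_cylinder_moments(self):
        """Mean radius a0 - vdw; SD = amplitude / sqrt(2) for a sine."""
        _, frames = self._breathing(amp=1.0)
        p = pf.trajectory_pore_profile(frames, np.array([0.0]),
                                       pf.ProbeParams(seed=0))
        assert p.radius_mean[0] == pytest.approx(3.5, abs=0.1)
        assert p.radius_sd[0] == pytest.approx(1.0 / np.sqrt(2), abs=0.1)

    def test_stride_subsampling_consistency(self):
        base = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0, n_rings=16)
        frames = frames_from_positions(base, np.tile(base.positions, (6, 1, 1)))
        p1 = pf.trajectory_pore_profile(frames, Z, pf.ProbeParams(seed=0), stride=1)
        p2 = pf.trajectory_pore_profile(frames, Z, pf.ProbeParams(seed=0), stride=2)
        assert np.max(np.abs(p1.radius_mean - p2.radius_mean)) <= 0.05


class TestRmsf:
    def _jitter_frames(self, sigma_nm, n_atoms=200, n_frames=400, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-10, 10, size=(n_atoms, 3))
        s = pf.build_structure(["CA"] * n_atoms, ["ALA"] * n_atoms,
                               list(range(1, n_atoms + 1)), base,
                               box=np.array([60.0, 60.0, 60.0]))
        pos = base[None] + sigma_nm * 10 * rng.standard_normal(
            (n_frames, n_atoms, 3))
        return s, frames_from_positions(s, pos)

    def test_static_structure_is_zero(self):
        s, _ = self._jitter_frames(0.0, n_frames=5)
        frames = frames_from_positions(s, np.tile(s.positions, (5, 1, 1)))
        prof = pf.rmsf_profile(frames, pf.SelectionSpec("all"))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_isotropic_jitter_closed_form(self):
        """RMSF = sqrt(3) sigma for isotropic Gaussian jitter per coordinate."""
        _, frames = self._jitter_frames(0.1)
        prof = pf.rmsf_profile(frames, pf.SelectionSpec("all"))
        expected = np.sqrt(3) * 0.1
        assert prof.rmsf.mean() == pytest.approx(expected, rel=0.02)

    def test_rmsf_linear_in_sigma(self):
        _, f1 = self._jitter_frames(0.05, seed=3)
        _, f2 = self._jitter_frames(0.10, seed=3)
        p1 = pf.rmsf_profile(f1, pf.SelectionSpec("all"))
        p2 = pf.rmsf_profile(f2, pf.SelectionSpec("all"))
        assert p2.rmsf.mean() / p1.rmsf.mean() == pytest.approx(2.0, rel=1e-6)

    def test_rigid_motion_invariance(self):
        s, frames = self._jitter_frames(0.1, n_frames=50)
        th = 0.5
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = frames_from_positions(s, frames.positions @ rot.T + 7.0)
        p1 = pf.rmsf_profile(frames, pf.SelectionSpec("all"))
        p2 = pf.rmsf_profile(moved, pf.SelectionSpec("all"))
        np.testing.assert_allclose(p1.rmsf, p2.rmsf, atol=1e-9)

    def test_single_frame_is_undefined(self, ring_structure):
        frames = frames_from_positions(ring_structure,
                                       ring_structure.positions[None])
        with pytest.raises(pf.ContractError):
            pf.rmsf_profile(frames, pf.SelectionSpec("all"))

    def test_replica_mean_and_sd(self):
        _, f1 = self._jitter_frames(0.1, seed=1)
        _, f2 = self._jitter_frames(0.1, seed=2)
        prof = pf.rmsf_profile([f1, f2], pf.SelectionSpec("all"))
        assert prof.sd is not None
        assert prof.rmsf.mean() == pytest.approx(np.sqrt(3) * 0.1, rel=0.02)


class TestRmsd:
    def test_reference_against_itself_is_zero(self, ring_structure):
        frames = frames_from_positions(ring_structure,
                                       np.tile(ring_structure.positions,
                                               (3, 1, 1)))
        np.testing.assert_allclose(
            pf.rmsd_series(frames, pf.SelectionSpec("all")), 0.0, atol=1e-9
        )

    def test_rigid_translation_superposes_to_zero(self, ring_structure):
        pos = np.stack([ring_structure.positions,
                        ring_structure.positions + [3.0, -1.0, 2.0]])
        frames = frames_from_positions(ring_structure, pos)
        series = pf.rmsd_series(frames, pf.SelectionSpec("all"))
        assert series[1] == pytest.approx(0.0, abs=1e-9)

    def test_half_displaced_closed_form(self):
        """1 Å shift of half the atoms: raw RMSD = sqrt(0.5) Å = 0.0707 nm."""
        rng = np.random.default_rng(0)
        n = 400
        base = rng.uniform(-20, 20, size=(n, 3))
        s = pf.build_structure(["CA"] * n, ["ALA"] * n, list(range(1, n + 1)),
                               base, box=np.array([80.0] * 3))
        moved = base.copy()
        moved[: n // 2, 2] += 1.0
        frames = frames_from_positions(s, np.stack([base, moved]))
        raw = pf.rmsd_series(frames, pf.SelectionSpec("all"), superpose=False)
        assert raw[1] == pytest.approx(np.sqrt(0.5) / 10, abs=1e-9)
        fitted = pf.rmsd_series(frames, pf.SelectionSpec("all"))
        assert fitted[1] <= raw[1]  # superposition can only reduce it


class TestCavityWater:
    def _water_frames(self, water_pos, n_frames=4, box=40.0):
        n = len(water_pos)
        s = pf.build_structure(["OW"] * n, ["SOL"] * n, list(range(1, n + 1)),
                               water_pos, box=np.array([box] * 3))
        return frames_from_positions(s, np.tile(water_pos, (n_frames, 1, 1)),
                                     box=[box] * 3)

    def test_constructed_region_count_exact(self):
        rng = np.random.default_rng(1)
        inside = rng.uniform(-2, 2, size=(12, 3))  # within r=8, z in (-5, 5)
        outside = rng.uniform(12, 18, size=(30, 3))
        frames = self._water_frames(np.vstack([inside, outside]))
        counts, mean, sd = pf.cavity_water_count(
            frames, pf.SelectionSpec("name OW"),
            pf.CavityRegion(z_range=(-5.0, 5.0), radius=8.0),
        )
        assert mean == 12.0 and sd == 0.0
        np.testing.assert_array_equal(counts, 12.0)

    def test_ideal_gas_density_expectation(self):
        rng = np.random.default_rng(2)
        rho = 0.01
        box = 40.0
        n = int(rho * box**3)
        frames_list = []
        counts_all = []
        region = pf.CavityRegion(z_range=(-5.0, 5.0), radius=8.0)
        for i in range(30):
            pos = rng.uniform(-box / 2, box / 2, size=(n, 3))
            frames = self._water_frames(pos, n_frames=1, box=box)
            c, _, _ = pf.cavity_water_count(frames,
                                            pf.SelectionSpec("name OW"), region)
            counts_all.append(c[0])
        expected = rho * np.pi * 64 * 10
        se = np.std(counts_all, ddof=1) / np.sqrt(len(counts_all))
        assert abs(np.mean(counts_all) - expected) <= 3 * se

    def test_region_outside_box_warns_and_counts_zero(self):
        frames = self._water_frames(np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="outside the box"):
            counts, mean, _ = pf.cavity_water_count(
                frames, pf.SelectionSpec("name OW"),
                pf.CavityRegion(z_range=(100.0, 110.0), radius=5.0),
            )
        assert mean == 0.0
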