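"""Generators: Brownian pore dynamics, solvation fixtures, gating traces."""

import numpy as np
import pytest

import poreflow as pf
from poreflow.core import R_KCAL
from poreflow.synth import (
    Pmf,
    PoreModel,
    SolvationRdf,
    StepSizeError,
    TwoStateChannelModel,
    make_bulk_solvation,
    make_cylinder_pore,
    make_solvation_fixture,
    make_uniform_solvent_box,
    simulate_langevin_pore,
    simulate_patch_trace,
)


class TestPmf:
    def test_double_well_hits_design_values(self):
        pmf = Pmf.double_well()
        z = np.linspace(-20, 20, 8001)
        u = pmf.u(z)
        assert u.min() == pytest.approx(-3.0, abs=1e-3)
        assert u.max() == pytest.approx(1.0, abs=1e-3)
        assert abs(z[u.argmin()]) == pytest.approx(8.0, abs=0.1)
        assert pmf.u(np.array([-20.0])) == pytest.approx(pmf.u(np.array([20.0])))

    def test_aperiodic_pmf_rejected(self):
        with pytest.raises(pf.ContractError):
            Pmf(np.array([-20.0, 20.0]), np.array([0.0, 1.0]))


class TestLangevin:
    def test_fixed_seed_is_bit_identical(self):
        model = PoreModel(n_ions=2)
        f1, _ = simulate_langevin_pore(model, 2000, 0.2, seed=9)
        f2, _ = simulate_langevin_pore(model, 2000, 0.2, seed=9)
        assert np.array_equal(f1.positions, f2.positions)

    def test_zero_field_has_no_net_drift(self):
        model = PoreModel(pmf=Pmf.flat(40.0))
        frames, gt = simulate_langevin_pore(model, 100_000, 0.2, seed=3,
                                            save_stride=20)
        assert gt.theoretical_mean_flux == 0.0
        events = pf.detect_permeation_events(
            frames, pf.SelectionSpec("resname K"),
            pf.PoreBoundaries(z_top=10, z_bottom=-10, r_max=50),
        )
        net = sum(e.direction for e in events)
        # diffusive net-crossing SD = sqrt(2 n D T) / L
        se = np.sqrt(2 * model.n_ions * 0.2 * frames.times[-1]) / 40.0
        assert abs(net) <= 3 * se + 1

    def test_field_drift_matches_closed_form(self, field_run):
        frames, gt, model = field_run
        events = pf.detect_permeation_events(
            frames, pf.SelectionSpec("resname K"),
            pf.PoreBoundaries(z_top=10, z_bottom=-10, r_max=50),
        )
        net = sum(e.direction for e in events)
        duration_ps = frames.times[-1] - frames.times[0]
        expected = gt.theoretical_mean_flux * duration_ps / 1e6
        se = np.sqrt(2 * model.n_ions * model.diffusion_coefficient
                     * duration_ps) / model.box_length
        assert abs(net - expected) <= 3 * se

    def test_equilibrium_histogram_matches_boltzmann(self):
        """Kolmogorov-Smirnov distance to exp(-U/RT) below 0.02 at 1e6 steps."""
        model = PoreModel(pmf=Pmf.sinusoid(40.0, amplitude=1.0))
        frames, _ = simulate_langevin_pore(model, 1_000_000, 0.2, seed=4,
                                           save_stride=5)
        z = np.sort(frames.positions[:, : model.n_ions, 2].ravel())
        kT = R_KCAL * model.temperature
        zg = np.linspace(-20, 20, 8001)
        w = np.exp(-model.pmf.u(zg) / kT)
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)])
        cdf /= cdf[-1]
        theory = np.interp(z, zg, cdf)
        emp = np.arange(1, len(z) + 1) / len(z)
        assert np.max(np.abs(theory - emp)) < 0.02

    def test_double_well_occupancy_ratio(self, doublewell_run):
        """Well/bulk density ratio approaches the Boltzmann weight exp(3/RT)."""
        frames, _, model = doublewell_run
        z = frames.positions[:, : model.n_ions, 2].ravel()
        kT = R_KCAL * model.temperature
        well = np.sum((np.abs(np.abs(z) - 8.0) < 0.25))
        bulk = np.sum(np.abs(z) > 15.0)
        # per-Å densities: wells span 2 x 0.5 Å windows, bulk spans 2 x 5 Å
        ratio = (well / 1.0) / (bulk / 10.0)
        # Boltzmann oracle: mean weights over the same windows
        zg = np.linspace(-20, 20, 16001)
        w = np.exp(-model.pmf.u(zg) / kT)
        expected = (w[np.abs(np.abs(zg) - 8.0) < 0.25].mean()
                    / w[np.abs(zg) > 15.0].mean())
        assert expected == pytest.approx(np.exp(3.0 / kT), rel=0.05)
        assert ratio == pytest.approx(expected, rel=0.10)

    def test_unstable_step_raises_with_step_index(self):
        steep = Pmf(np.array([-20, -1, 0, 1, 20.0]),
                    np.array([0.0, 0, -30.0, 0, 0.0]))
        model = PoreModel(pmf=steep)
        with pytest.raises(pf.ContractError):
            simulate_langevin_pore(model, 1000, 0.5, seed=0)

    def test_ground_truth_travels_with_h5(self, tmp_path):
        model = PoreModel(n_ions=2)
        frames, gt = simulate_langevin_pore(model, 2000, 0.2, seed=5)
        path = tmp_path / "run.h5"
        pf.save_frames_h5(frames, path)
        back = pf.load_frames_h5(path)
        assert back.ground_truth is not None
        assert back.ground_truth.rng_seed == 5
        np.testing.assert_allclose(back.ground_truth.pmf_u, gt.pmf_u)


class TestSolvationFixtures:
    def test_exact_shell_contents(self):
        s = make_solvation_fixture(5, 2, 100, 3.4, seed=0)
        census = pf.first_shell_census(s, s.positions[0], pf.HydrationParams())
        assert census == (5, 2)

    def test_empty_shell(self):
        s = make_solvation_fixture(0, 0, 100, 3.4, seed=1)
        census = pf.first_shell_census(s, s.positions[0], pf.HydrationParams())
        assert census == (0, 0)

    def test_background_only_contributes_nothing_inside_shell(self):
        # background atoms are placed outside 1.5 r_shell by construction
        totals = []
        for seed in range(200):
            s = make_solvation_fixture(0, 0, 50, 3.4, seed=seed)
            nw, nc = pf.first_shell_census(s, s.positions[0], pf.HydrationParams())
            totals.append(nw + nc)
        assert sum(totals) == 0

    def test_uniform_box_census_matches_sphere_volume(self):
        """Mean census over seeds equals rho (4/3) pi r^3 within 3 SE."""
        rho, r = 0.0334, 3.4
        counts = []
        for seed in range(200):
            s = make_uniform_solvent_box(rho, 24.0, seed=seed)
            nw, _ = pf.first_shell_census(s, s.positions[0], pf.HydrationParams())
            counts.append(nw)
        expected = rho * 4 / 3 * np.pi * r**3
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_rdf_sampler_matches_its_analytic_coordination(self):
        rdf = SolvationRdf()
        structs = make_bulk_solvation(150, seed=6, rdf=rdf)
        cn = pf.bulk_coordination_number(structs)
        expected = rdf.expected_coordination(3.4, 0.0334)
        se = np.sqrt(expected / len(structs))  # Poisson-like per-frame variance
        assert abs(cn - expected) <= 3 * se


class TestCylinderPore:
    def test_cylinder_geometry(self):
        s = make_cylinder_pore(5.0, atom_vdw=1.5, z_extent=30.0, n_rings=31)
        p = pf.pore_radius_profile(s, np.arange(-10, 10.25, 0.5),
                                   pf.ProbeParams(seed=0))
        np.testing.assert_allclose(p.radius_mean, 3.5, atol=0.05)

    def test_ring_spacing_refinement_agrees(self):
        z = np.arange(-10, 10.25, 0.5)
        coarse = make_cylinder_pore(5.0, 1.5, 30.0, n_rings=31)   # 1 Å spacing
        fine = make_cylinder_pore(5.0, 1.5, 30.0, n_rings=61)     # 0.5 Å spacing
        pc = pf.pore_radius_profile(coarse, z, pf.ProbeParams(seed=0))
        pfn = pf.pore_radius_profile(fine, z, pf.ProbeParams(seed=0))
        assert np.max(np.abs(pc.radius_mean - pfn.radius_mean)) <= 0.1

    def test_too_small_ring_radius_rejected(self):
        with pytest.raises(pf.ContractError):
            make_cylinder_pore(1.0, atom_vdw=1.5)


class TestPatchTrace:
    def test_never_opening_channel_sits_at_baseline(self):
        m = TwoStateChannelModel(k_open=0.0, k_close=100.0, noise_sigma=0.05)
        tr = simulate_patch_trace(m, 2.0, seed=0)
        se = 0.05 / np.sqrt(tr.n_samples)
        assert abs(tr.samples.mean()) <= 3 * se

    def test_mean_current_matches_stationary_occupancy(self):
        m = TwoStateChannelModel(k_open=30.0, k_close=70.0, i_open=-0.5,
                                 noise_sigma=0.05)
        tr = simulate_patch_trace(m, 20.0, seed=1)
        expected = m.i_open * m.p_open
        # dwell-time variance dominates: SE from effective event count
        n_dwell = 20.0 * (m.k_open * m.k_close) / (m.k_open + m.k_close)
        se = abs(m.i_open) * np.sqrt(m.p_open * (1 - m.p_open) / n_dwell)
        assert abs(tr.samples.mean() - expected) <= 3 * se

    def test_seed_reproducibility(self):
        m = TwoStateChannelModel()
        t1 = simulate_patch_trace(m, 1.0, seed=7)
        t2 = simulate_patch_trace(m, 1.0, seed=7)
        assert np.array_equal(t1.samples, t2.samples)

    def test_too_short_trace_rejected(self):
        with pytest.raises(pf.ContractError):
            simulate_patch_trace(TwoStateChannelModel(), 0.1, seed=0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(pf.ContractError):
            TwoStateChannelModel(k_open=-1.0)
        with pytest.raises(pf.ContractError):
            TwoStateChannelModel(sampling_rate=1500.0, filter_corner=1000.0)
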