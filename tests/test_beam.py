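"""Tapered-beam FEM: taper geometry, assembly, FRF solve, modal analysis."""

import numpy as np
import pytest
import scipy.integrate

import whiskmech as wm
from whiskmech.beam import BeamModelError, total_mass

from conftest import uniform_cantilever_frequencies


class TestTaperProfile:
    def test_endpoints_and_uniform(self, d2_geometry):
        r0, a0, j0 = wm.taper_profile(d2_geometry, 0.0)
        assert r0 == pytest.approx(d2_geometry.base_radius_rb)
        r1, _, _ = wm.taper_profile(d2_geometry, d2_geometry.length_L)
        assert r1 == pytest.approx(d2_geometry.tip_radius_rt)
        assert a0 == pytest.approx(np.pi * r0**2)
        assert j0 == pytest.approx(np.pi * r0**4 / 4)
        uni = wm.WhiskerGeometry(0.02, 5e-5, 5e-5)
        x = np.linspace(0, 0.02, 7)
        _, area, _ = wm.taper_profile(uni, x)
        assert np.allclose(area, np.pi * 25e-10)

    def test_radius_linear_in_x(self, d2_geometry):
        x = np.linspace(0, d2_geometry.length_L, 11)
        r, _, _ = wm.taper_profile(d2_geometry, x)
        assert np.allclose(np.diff(r, 2), 0, atol=1e-18)

    def test_outside_domain_raises(self, d2_geometry):
        with pytest.raises(BeamModelError):
            wm.taper_profile(d2_geometry, -1e-6)
        with pytest.raises(BeamModelError):
            wm.taper_profile(d2_geometry, d2_geometry.length_L * 1.01)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(BeamModelError):
            wm.WhiskerGeometry(-0.01, 6e-5, 3e-6)
        with pytest.raises(BeamModelError):
            wm.WhiskerGeometry(0.01, 2e-6, 3e-6)  # rb < rt


class TestAssembly:
    def test_symmetry_and_definiteness(self, d2_geometry, d2_material, d2_mesh):
        m, k = wm.assemble_beam_system(d2_geometry, d2_material, d2_mesh)
        assert abs(m - m.T).max() < 1e-18
        assert abs(k - k.T).max() < 1e-9
        assert np.linalg.eigvalsh(m.toarray()).min() > 0

    def test_rigid_translation_costs_no_strain(self, d2_material):
        geom = wm.WhiskerGeometry(0.01, 5e-5, 5e-5)
        mesh = wm.FEMesh(np.linspace(0, 0.01, 5))
        _, k = wm.assemble_beam_system(geom, d2_material, mesh)
        rigid = np.zeros(k.shape[0])
        rigid[::2] = 1.0
        assert np.abs(k @ rigid).max() < 1e-6 * np.abs(k.toarray()).max()

    def test_total_mass_matches_frustum(self, d2_geometry, d2_material, d2_mesh):
        m, _ = wm.assemble_beam_system(d2_geometry, d2_material, d2_mesh)
        rigid = np.zeros(m.shape[0])
        rigid[::2] = 1.0
        fem_mass = rigid @ (m @ rigid)
        closed = total_mass(d2_geometry, d2_material)
        # independent numeric-quadrature oracle over rho*A(x)
        quad, _ = scipy.integrate.quad(
            lambda x: d2_material.density_rho * wm.taper_profile(d2_geometry, x)[1],
            0,
            d2_geometry.length_L,
        )
        assert fem_mass == pytest.approx(closed, rel=1e-10)
        assert closed == pytest.approx(quad, rel=1e-9)

    def test_stiffness_linear_in_youngs_modulus(self, d2_geometry, d2_mesh):
        m1, k1 = wm.assemble_beam_system(
            d2_geometry, wm.MaterialParams(3e9, 1200.0), d2_mesh
        )
        m2, k2 = wm.assemble_beam_system(
            d2_geometry, wm.MaterialParams(6e9, 1200.0), d2_mesh
        )
        assert abs(k2 - 2 * k1).max() < 1e-6 * abs(k1).max()
        assert abs(m2 - m1).max() == 0

    def test_degenerate_mesh_rejected(self):
        with pytest.raises(BeamModelError):
            wm.FEMesh(np.array([0.0, 0.01, 0.01, 0.02, 0.03]))


class TestFRF:
    def test_base_row_is_exactly_unity(self, d2_frf):
        assert np.all(d2_frf.values[0] == 1.0 + 0.0j)

    def test_quasi_static_limit(self, d2_geometry, d2_material, d2_mesh):
        grid = wm.FrequencyGrid(np.array([0.1, 0.2]))
        frf = wm.solve_frf(d2_geometry, d2_material, d2_mesh, grid)
        assert np.abs(np.abs(frf.values) - 1.0).max() < 1e-3

    def test_uniform_beam_first_peak_matches_closed_form(
        self, uniform_geometry, d2_material, default_grid
    ):
        mesh = wm.FEMesh.uniform(uniform_geometry.length_L, 200)
        f_exact = uniform_cantilever_frequencies(uniform_geometry, d2_material, 1)[0]
        lo, hi = 0.5 * f_exact, 2.0 * f_exact
        grid = wm.FrequencyGrid.regular(lo, hi, (hi - lo) / 400)
        frf = wm.solve_frf(uniform_geometry, d2_material, mesh, grid)
        tip = np.abs(frf.values[-1])
        f_peak = grid.frequencies[np.argmax(tip)]
        assert f_peak == pytest.approx(f_exact, rel=5e-3)

    def test_beta_damping_lowers_resonance_peaks(
        self, d2_geometry, d2_mesh, default_grid
    ):
        import scipy.signal

        mats = [
            wm.MaterialParams(3e9, 1200.0, 10.0, beta) for beta in (2e-5, 1e-4)
        ]
        tips = [
            np.abs(wm.solve_frf(d2_geometry, m, d2_mesh, default_grid).values[-1])
            for m in mats
        ]
        peaks, _ = scipy.signal.find_peaks(tips[0], height=1.5)
        assert peaks.size >= 3
        assert np.all(tips[1][peaks] < tips[0][peaks])

    def test_finite_everywhere(self, d2_frf):
        assert np.all(np.isfinite(d2_frf.values))


class TestModal:
    def test_uniform_beam_matches_closed_form(self, uniform_geometry, d2_material):
        mesh = wm.FEMesh.uniform(uniform_geometry.length_L, 200)
        modes = wm.modal_frequencies(uniform_geometry, d2_material, mesh, 3)
        exact = uniform_cantilever_frequencies(uniform_geometry, d2_material, 3)
        assert np.all(np.abs(modes.modal_frequencies / exact - 1) < 1e-3)

    def test_halving_length_quadruples_frequencies(self, d2_material):
        base = wm.WhiskerGeometry(0.03, 60e-6, 60e-6)
        half = wm.WhiskerGeometry(0.015, 60e-6, 60e-6)
        f1 = wm.modal_frequencies(
            base, d2_material, wm.FEMesh.uniform(0.03, 100), 3
        ).modal_frequencies
        f2 = wm.modal_frequencies(
            half, d2_material, wm.FEMesh.uniform(0.015, 100), 3
        ).modal_frequencies
        assert np.allclose(f2, 4 * f1, rtol=1e-5)

    def test_mesh_convergence_100_to_200(self, d2_geometry, d2_material):
        f100 = wm.modal_frequencies(
            d2_geometry, d2_material, wm.FEMesh.uniform(0.03, 100), 3
        ).modal_frequencies
        f200 = wm.modal_frequencies(
            d2_geometry, d2_material, wm.FEMesh.uniform(0.03, 200), 3
        ).modal_frequencies
        assert np.abs(f200 / f100 - 1).max() < 1e-4

    def test_frequencies_align_with_frf_peaks(
        self, d2_geometry, d2_mesh, default_grid
    ):
        # small damping so magnitude peaks sit at the undamped modes
        light = wm.MaterialParams(3e9, 1200.0, 0.5, 1e-6)
        modes = wm.modal_frequencies(d2_geometry, light, d2_mesh, 3)
        frf = wm.solve_frf(d2_geometry, light, d2_mesh, default_grid)
        tip = np.abs(frf.values[-1])
        for f_mode in modes.modal_frequencies:
            k = int(round(f_mode - default_grid.frequencies[0]))
            window = tip[max(k - 3, 0) : k + 4]
            assert window.max() == tip[max(k - 3, 0) : k + 4].max()
            k_peak = default_grid.frequencies[
                max(k - 3, 0) + int(np.argmax(window))
            ]
            assert abs(k_peak - f_mode) <= 2.0

    def test_clamped_base_and_ascending(self, d2_geometry, d2_material, d2_mesh):
        modes = wm.modal_frequencies(d2_geometry, d2_material, d2_mesh, 4)
        assert np.all(np.diff(modes.modal_frequencies) > 0)
        assert np.all(modes.modal_frequencies > 0)
        assert np.allclose(modes.mode_shapes[0], 0.0)

    def test_too_many_modes_rejected(self, d2_geometry, d2_material):
        mesh = wm.FEMesh.uniform(0.03, 4)
        with pytest.raises(BeamModelError):
            wm.modal_frequencies(d2_geometry, d2_material, mesh, 50)
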