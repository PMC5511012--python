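"""mFRF estimation (Welch/H1), trial averaging, and similarity fingerprints."""

import numpy as np
import pytest

import whiskmech as wm
from whiskmech.spectral import SpectralError, magnitude_from_complex


def _field_from_rows(rows, fs=2000.0):
    rows = np.asarray(rows, float)
    return wm.DeflectionField(
        rows, np.linspace(0, 1, rows.shape[0]), fs
    )


@pytest.fixture(scope="module")
def noise_input():
    return wm.gen_stimulus(seed=123).displacement


class TestEstimateMfrf:
    def test_identity_system_gives_unit_gain(self, noise_input):
        field = _field_from_rows([noise_input, noise_input])
        m = wm.estimate_mfrf(field)
        assert np.allclose(m.magnitudes[:, 1], 1.0, atol=1e-9)
        assert np.allclose(m.magnitudes[:, 0], 1.0, atol=1e-9)

    def test_pure_gain_system(self, noise_input):
        field = _field_from_rows([noise_input, 2.0 * noise_input])
        m = wm.estimate_mfrf(field)
        assert np.allclose(m.magnitudes[:, 1], 2.0, atol=1e-9)

    def test_band_restriction(self, noise_input):
        m = wm.estimate_mfrf(_field_from_rows([noise_input, noise_input]))
        assert m.frequencies[0] >= 1.0
        assert m.frequencies[-1] <= 900.0

    def test_short_trial_rejected(self):
        field = _field_from_rows(np.random.default_rng(0).normal(size=(2, 600)))
        with pytest.raises(SpectralError):
            wm.estimate_mfrf(field)

    def test_known_frf_recovered(self, d2_frf):
        per_trial = []
        for t in range(10):
            stim = wm.gen_stimulus(seed=500 + t)
            field = wm.synth_deflection_field(d2_frf, stim, n_positions=25)
            per_trial.append(wm.estimate_mfrf(field))
        avg = wm.average_mfrf(per_trial)
        analytic = magnitude_from_complex(
            d2_frf, frequencies=avg.frequencies, positions=avg.positions
        )
        r2_ten = wm.similarity_r2(avg, analytic)
        r2_one = wm.similarity_r2(per_trial[0], analytic)
        assert r2_ten >= 0.99
        assert r2_ten >= r2_one


class TestAverageMfrf:
    def test_mean_of_equals_is_unchanged(self, noise_input):
        m = wm.estimate_mfrf(_field_from_rows([noise_input, noise_input]))
        avg = wm.average_mfrf([m, m, m])
        assert np.allclose(avg.magnitudes, m.magnitudes)
        assert avg.n_trials_averaged == 3

    def test_arithmetic_mean(self, noise_input):
        from dataclasses import replace

        m = wm.estimate_mfrf(_field_from_rows([noise_input, noise_input]))
        m3 = replace(m, magnitudes=3 * m.magnitudes)
        avg = wm.average_mfrf([m, m3])
        assert np.allclose(avg.magnitudes, 2 * m.magnitudes)

    def test_grid_mismatch_rejected(self, noise_input):
        from dataclasses import replace

        m = wm.estimate_mfrf(_field_from_rows([noise_input, noise_input]))
        other = replace(m, frequencies=m.frequencies + 0.5)
        with pytest.raises(SpectralError):
            wm.average_mfrf([m, other])

    def test_averaging_reduces_standard_error(self, d2_frf):
        # per-bin spread across 10-trial means vs single trials ~ 1/sqrt(10)
        singles = []
        for t in range(20):
            stim = wm.gen_stimulus(seed=900 + t)
            field = wm.synth_deflection_field(d2_frf, stim, n_positions=5)
            singles.append(wm.estimate_mfrf(field).magnitudes)
        singles = np.array(singles)
        sd_single = singles.std(axis=0).mean()
        means = np.array(
            [singles[i : i + 10].mean(axis=0) for i in (0, 10)]
        )
        sd_mean = np.abs(means[0] - means[1]).mean() / np.sqrt(2)
        ratio = sd_mean / sd_single
        assert 0.1 < ratio < 0.7  # consistent with ~1/sqrt(10) = 0.32


@pytest.fixture(scope="module")
def base_mfrf(d2_frf):
    return magnitude_from_complex(
        d2_frf, positions=np.linspace(0, 1, 25), label="D2"
    )


class TestSimilarity:
    def test_self_similarity_is_one(self, base_mfrf):
        assert wm.similarity_r2(base_mfrf, base_mfrf) == pytest.approx(1.0)

    def test_affine_invariance(self, base_mfrf):
        from dataclasses import replace

        scaled = replace(base_mfrf, magnitudes=base_mfrf.magnitudes**2.0 * 10)
        # log10 of (10*m^2) = 1 + 2 log10 m: affine in log space
        assert wm.similarity_r2(base_mfrf, scaled) == pytest.approx(1.0)

    def test_symmetry_and_bounds(self, base_mfrf, d2_frf):
        other = magnitude_from_complex(
            wm.ComplexFRF(
                d2_frf.positions, d2_frf.frequencies, d2_frf.values * (1 + 0.2j)
            ),
            positions=np.linspace(0, 1, 19),
        )
        ab = wm.similarity_r2(base_mfrf, other)
        ba = wm.similarity_r2(other, base_mfrf)
        assert ab == pytest.approx(ba, rel=1e-6)
        assert 0.0 <= ab <= 1.0

    def test_constant_vector_rejected(self, base_mfrf):
        from dataclasses import replace

        flat = replace(base_mfrf, magnitudes=np.ones_like(base_mfrf.magnitudes))
        with pytest.raises(SpectralError):
            wm.similarity_r2(base_mfrf, flat)

    def test_length_similarity_ordering(self, d2_material, default_grid):
        # nearby lengths respond alike; disparate lengths do not
        mags = {}
        for length_mm in (53.0, 56.0, 23.0):
            geom = wm.WhiskerGeometry(length_mm * 1e-3, 2e-6 * length_mm, 3e-6)
            frf = wm.solve_frf(
                geom, d2_material, wm.FEMesh.uniform(geom.length_L, 200), default_grid
            )
            mags[length_mm] = magnitude_from_complex(
                frf, positions=np.linspace(0, 1, 25)
            )
        close = wm.similarity_r2(mags[53.0], mags[56.0])
        far = wm.similarity_r2(mags[53.0], mags[23.0])
        assert close > far


class TestSimilarityMatrix:
    def test_identical_items_give_ones(self, d2_frf):
        m = magnitude_from_complex(d2_frf, positions=np.linspace(0, 1, 25))
        sim = wm.similarity_matrix([m, m], labels=["a", "b"])
        assert np.allclose(sim.r_squared, 1.0)

    def test_symmetric_with_unit_diagonal(self, d2_frf):
        from dataclasses import replace

        m = magnitude_from_complex(d2_frf, positions=np.linspace(0, 1, 25))
        items = [
            replace(m, magnitudes=m.magnitudes ** (1 + 0.2 * i)) for i in range(4)
        ]
        sim = wm.similarity_matrix(items)
        assert np.array_equal(sim.r_squared, sim.r_squared.T)
        assert np.array_equal(np.diag(sim.r_squared), np.ones(4))


class TestBandMeans:
    def test_hand_computed_example(self):
        m = wm.SimilarityMatrix(
            np.array([[1, 0.9, 0.4], [0.9, 1, 0.8], [0.4, 0.8, 1]]),
            ("a", "b", "c"),
        )
        theta = wm.band_means(m).theta
        assert theta == pytest.approx([0.85, 0.4])

    def test_all_ones(self):
        m = wm.SimilarityMatrix(np.ones((4, 4)), tuple("abcd"))
        assert np.allclose(wm.band_means(m).theta, 1.0)

    def test_length_ladder_theta_decreases(self, d2_material, default_grid):
        from whiskmech.synthetic import LENGTH_LADDER_MM

        items = []
        for length_mm in LENGTH_LADDER_MM:
            geom = wm.WhiskerGeometry(length_mm * 1e-3, 2e-6 * length_mm, 3e-6)
            frf = wm.solve_frf(
                geom, d2_material, wm.FEMesh.uniform(geom.length_L, 200), default_grid
            )
            items.append(
                magnitude_from_complex(frf, positions=np.linspace(0, 1, 25))
            )
        theta = wm.band_means(wm.similarity_matrix(items)).theta
        assert np.all(np.diff(theta) < 0)


class TestDyeStability:
    def test_dye_density_bump_preserves_fingerprint(
        self, d2_geometry, d2_material, d2_mesh, default_grid, d2_frf
    ):
        _, dyed = wm.perturb_whisker(d2_geometry, d2_material, "dye", 0.007)
        frf_dyed = wm.solve_frf(d2_geometry, dyed, d2_mesh, default_grid)
        pos = np.linspace(0, 1, 25)
        r2 = wm.similarity_r2(
            magnitude_from_complex(d2_frf, positions=pos),
            magnitude_from_complex(frf_dyed, positions=pos),
        )
        assert r2 >= 0.8
        assert r2 >= 0.99  # expected essentially unchanged
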