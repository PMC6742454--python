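"""Mixture-EM unit and property tests, with independent oracles."""

import math

import numpy as np
import pytest
from hemcyto import hem_core, simgen
from hemcyto.hem_core import (
    BackgroundComponent,
    GaussianComponent,
    MixtureFit,
    e_step,
    estimate_diameter,
    fit_hem,
    gaussian_density,
    initial_fit,
    m_step,
    measure_all_fluorescences,
    measure_fluorescence,
    uniform_density,
)

FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class TestDensities:
    def test_gaussian_mode_identity_covariance(self):
        val = gaussian_density(np.zeros(2), np.zeros(2), np.eye(2))
        assert val == pytest.approx(1.0 / (2 * math.pi), rel=1e-12)

    def test_gaussian_mode_scaled_covariance(self):
        val = gaussian_density(np.zeros(2), np.zeros(2), np.diag([4.0, 4.0]))
        assert val == pytest.approx(1.0 / (8 * math.pi), rel=1e-12)

    def test_gaussian_integrates_to_one(self):
        """Fine-grid quadrature of the density over a 12-sigma box."""
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        lim = 12 * math.sqrt(np.linalg.eigvalsh(cov)[-1])
        step = 0.02
        g = np.arange(-lim, lim, step)
        xs = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1)
        total = gaussian_density(xs, np.zeros(2), cov).sum() * step * step
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_rejects_non_positive_definite(self):
        with pytest.raises(ValueError):
            gaussian_density(np.zeros(2), np.zeros(2), np.diag([1.0, -1.0]))

    @pytest.mark.parametrize("w,h,expected", [(100, 100, 1e-4), (15, 15, 1 / 225)])
    def test_uniform_density_values(self, w, h, expected):
        assert uniform_density(w, h) == pytest.approx(expected, rel=1e-12)

    def test_uniform_normalizes(self):
        assert uniform_density(37.0, 11.0) * 37.0 * 11.0 == pytest.approx(1.0)


def _fit(components, shape, bg_weight):
    bg = BackgroundComponent(weight=bg_weight, domain_height=shape[0], domain_width=shape[1])
    return MixtureFit(components=components, background=bg)


class TestEStep:
    def test_single_gaussian_full_weight(self):
        comp = GaussianComponent(np.array([4.0, 4.0]), np.eye(2), weight=1.0)
        z = e_step(np.ones((9, 9)), _fit([comp], (9, 9), 0.0))
        assert np.allclose(z[0], 1.0)
        assert np.allclose(z[1], 0.0)

    def test_identical_gaussians_share_equally(self):
        mk = lambda: GaussianComponent(np.array([4.0, 4.0]), np.eye(2), weight=0.5)
        z = e_step(np.ones((9, 9)), _fit([mk(), mk()], (9, 9), 0.0))
        assert np.allclose(z[0], 0.5)
        assert np.allclose(z[1], 0.5)

    def test_responsibilities_sum_to_one(self, converged_single_fit, single_spot_field):
        image, _ = single_spot_field
        z = e_step(image.pixels, converged_single_fit)
        assert np.allclose(z.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(z >= 0) and np.all(z <= 1)

    def test_underflow_pixels_go_to_background(self):
        comp = GaussianComponent(np.array([0.0, 0.0]), np.eye(2) * 1e-4, weight=1.0)
        z = e_step(np.ones((30, 30)), _fit([comp], (30, 30), 0.0))
        # far corner: Gaussian underflows entirely, background (weight 0) takes it
        assert z[1, 29, 29] == 1.0


class TestMStep:
    def test_weighted_centroid(self):
        patch = np.zeros((1, 3))
        patch[0, 0] = 5.0
        patch[0, 2] = 5.0
        comp = GaussianComponent(np.array([0.0, 1.0]), np.eye(2), weight=1.0)
        fit = _fit([comp], (1, 3), 0.0)
        z = np.zeros((2, 1, 3))
        z[0] = 1.0
        new = m_step(patch, z, fit)
        assert new.components[0].mean == pytest.approx([0.0, 1.0])

    def test_weights_sum_to_one(self, single_spot_field):
        image, _ = single_spot_field
        fit = initial_fit(image.pixels.shape, [(19.5, 19.5)])
        z = e_step(image.pixels, fit)
        new = m_step(image.pixels, z, fit)
        assert new.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sigma_recovery_on_noise_free_spot(self):
        spec = simgen.FieldSpec(
            image_size=(41, 41),
            background_level=2.0,
            noise_model="none",
            spots=(simgen.SpotTruth(center=(20.0, 20.0), total_photons=50_000.0, sigma=(2.0, 2.0)),),
            seed=3,
        )
        image, _ = simgen.render_field(spec)
        fit = fit_hem(image.pixels, initial_fit(image.pixels.shape, [(20.0, 20.0)]))
        sigma = fit.components[0].sigma_eff_px
        assert sigma == pytest.approx(2.0, rel=0.05)


class TestFitHem:
    def test_flat_image_goes_to_background(self):
        spec = simgen.FieldSpec(image_size=(31, 31), background_level=50.0, noise_model="poisson", seed=5)
        image, _ = simgen.render_field(spec)
        fit = fit_hem(image.pixels, initial_fit(image.pixels.shape, [(15.0, 15.0)]))
        assert fit.background.weight >= 0.9

    def test_likelihood_trace_monotone(self, converged_single_fit):
        trace = np.array(converged_single_fit.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-9 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_requires_gaussian_component(self):
        bg = BackgroundComponent(weight=1.0, domain_height=5, domain_width=5)
        with pytest.raises(ValueError):
            fit_hem(np.ones((5, 5)), MixtureFit(components=[], background=bg))


class TestOracleEquivalence:
    """EM optimum vs exhaustive weighted-likelihood search on 5x5 patches."""

    def test_em_matches_grid_search(self):
        from oracle_utils import grid_search_single_spot, single_spot_patches

        mu_errs, sigma_rel_errs = [], []
        for patch in single_spot_patches(3, seed=29):
            fit = fit_hem(patch, initial_fit(patch.shape, [(2.0, 2.0)], init_diameter_um=6.0), tol=1e-12)
            _, mu_star, sigma_star = grid_search_single_spot(patch)
            mu_em = fit.components[0].mean
            mu_errs.append(float(np.linalg.norm(mu_em - np.array(mu_star))))
            sigma_rel_errs.append(abs(fit.components[0].sigma_eff_px - sigma_star) / sigma_star)
        assert np.mean(mu_errs) <= 0.02
        assert np.mean(sigma_rel_errs) <= 0.02


class TestMeasurements:
    def test_no_background_fluorescence_is_total(self):
        comp = GaussianComponent(np.array([4.0, 4.0]), np.eye(2), weight=1.0)
        patch = np.arange(81, dtype=float).reshape(9, 9)
        fit = _fit([comp], (9, 9), 0.0)
        assert measure_fluorescence(fit, patch, 0) == pytest.approx(patch.sum())

    def test_attribution_conservation_exact(self, converged_single_fit, single_spot_field):
        image, _ = single_spot_field
        fl = measure_all_fluorescences(converged_single_fit, image.pixels)
        assert fl.sum() == pytest.approx(image.pixels.sum(), abs=1e-9 * image.pixels.sum())

    def test_fluorescence_recovery_within_5pct(self):
        """Mean recovered photons over 50 seeds at SNR ~ 20."""
        recovered = []
        rng = np.random.default_rng(77)
        for _ in range(50):
            spec = simgen.FieldSpec(
                image_size=(31, 31),
                background_level=5.0,
                noise_model="poisson",
                spots=(
                    simgen.SpotTruth(
                        center=(15.0 + rng.uniform(-0.5, 0.5), 15.0 + rng.uniform(-0.5, 0.5)),
                        total_photons=10_000.0,
                        sigma=(1.06, 1.06),
                    ),
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, _ = simgen.render_field(spec)
            fit = fit_hem(image.pixels, initial_fit(image.pixels.shape, [(15.0, 15.0)]))
            recovered.append(measure_fluorescence(fit, image.pixels, 0))
        assert np.mean(recovered) == pytest.approx(10_000.0, rel=0.05)

    def test_linearity_in_amplitude(self):
        """Scaling spot photons by k scales recovered fluorescence by k."""
        rec = {}
        for k, photons in ((1, 5000.0), (4, 20_000.0)):
            spec = simgen.FieldSpec(
                image_size=(31, 31),
                background_level=5.0,
                noise_model="none",
                spots=(simgen.SpotTruth(center=(15.2, 14.8), total_photons=photons, sigma=(1.06, 1.06)),),
            )
            image, _ = simgen.render_field(spec)
            fit = fit_hem(image.pixels, initial_fit(image.pixels.shape, [(15.0, 15.0)]))
            rec[k] = measure_fluorescence(fit, image.pixels, 0)
        assert rec[4] / rec[1] == pytest.approx(4.0, rel=0.02)

    def test_diameter_formula_isotropic(self):
        comp = GaussianComponent(np.array([0.0, 0.0]), np.eye(2) * 4.0, weight=0.5)
        fit = _fit([comp], (15, 15), 0.5)
        assert estimate_diameter(fit, 0, 3.0) == pytest.approx(3.0 * FWHM * 2.0, rel=1e-9)

    def test_diameter_formula_anisotropic(self):
        comp = GaussianComponent(np.array([0.0, 0.0]), np.diag([4.0, 1.0]), weight=0.5)
        fit = _fit([comp], (15, 15), 0.5)
        # sigma_eff = |Sigma|^(1/4) = sqrt(2)
        assert estimate_diameter(fit, 0, 3.0) == pytest.approx(9.990655, abs=1e-3)

    def test_bead_diameter_recovery(self):
        """Mean recovered diameter within 5% of 7.5 µm at the bright tier."""
        fields = simgen.bead_series(n_per_level=60, seed=13)
        bright = fields[-1]  # last tier rendered is the brightest
        image, truth = bright
        diams = []
        for t in truth:
            r0, c0 = int(round(t.center[0])), int(round(t.center[1]))
            if not (10 <= r0 < image.pixels.shape[0] - 10 and 10 <= c0 < image.pixels.shape[1] - 10):
                continue
            patch = image.pixels[r0 - 10 : r0 + 11, c0 - 10 : c0 + 11]
            fit = fit_hem(patch, initial_fit(patch.shape, [(10.0, 10.0)]))
            diams.append(estimate_diameter(fit, 0, 3.0))
        assert np.mean(diams) == pytest.approx(7.5, rel=0.05)
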