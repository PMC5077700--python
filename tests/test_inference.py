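"""Posterior inference: contrast grid, conditional Gaussian, marginal moments,
ancestral sampler, and the independent importance-sampling cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1sampling import (
    GSMParams,
    ImagePatch,
    conditional_posterior,
    importance_sampling_oracle,
    marginal_posterior_moments,
    sample_posterior,
    z_posterior,
)
from v1sampling.gsm import InvalidSpecificationError, natural_surrogate_ensemble
from v1sampling.inference import (
    PosteriorSolver,
    cache_key,
    load_posterior_hdf5,
    load_posterior_json,
    save_posterior_hdf5,
    save_posterior_json,
)
from v1sampling.stimuli import StimulusSpec, blank, grating

from conftest import random_small_model


class TestZPosterior:
    def test_masses_normalized(self, tiny_model, tiny_solver):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=0)[0]
        grid = tiny_solver.z_posterior(patch)
        assert np.isclose(grid.masses.sum(), 1.0)
        assert np.all(np.diff(grid.z_values) > 0)

    def test_blank_pulls_contrast_below_prior_mean(self, tiny_model, tiny_solver):
        grid = tiny_solver.z_posterior(blank(tiny_model.patch_side))
        assert grid.mean() < tiny_model.contrast_prior_mean()

    def test_doubled_image_raises_inferred_contrast(self, tiny_model, tiny_solver):
        g = grating(StimulusSpec(contrast=0.5, spatial_frequency=2.0),
                    tiny_model.patch_side)
        z1 = tiny_solver.z_posterior(g).mean()
        z2 = tiny_solver.z_posterior(ImagePatch(2 * g.pixels)).mean()
        assert z2 > z1

    def test_blank_contrast_matches_quadrature_oracle(self, tiny_model, tiny_solver):
        # dense 1-D quadrature over the same integrand, straight from the
        # density definitions (trapezoid on a linear grid)
        from scipy import stats as sps

        x = np.zeros(tiny_model.n_pixels)
        z = np.linspace(1e-4, 40.0, 100_000)
        logp = sps.gamma.logpdf(
            z, tiny_model.contrast_shape, scale=tiny_model.contrast_scale
        ) + tiny_solver.log_evidence_terms(x, z)
        w = np.exp(logp - logp.max())
        oracle_mean = np.trapezoid(w * z, z) / np.trapezoid(w, z)
        assert abs(tiny_solver.z_posterior(x).mean() - oracle_mean) < 0.01

    def test_too_few_points_rejected(self, tiny_model, tiny_solver):
        with pytest.raises(InvalidSpecificationError):
            tiny_solver.z_posterior(
                blank(tiny_model.patch_side), {"n_points": 8}
            )


class TestConditionalPosterior:
    def test_scalar_conjugacy_closed_form(self):
        params = GSMParams(basis=np.array([[1.0]]), prior_cov=np.array([[1.0]]),
                           pixel_noise_var=1.0)
        cond = conditional_posterior(params, np.array([1.0]), z=1.0)
        assert np.isclose(cond.cov[0, 0], 0.5)
        assert np.isclose(cond.mean[0], 0.5)

    def test_small_z_limit_returns_prior(self, tiny_model):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=1)[0]
        cond = conditional_posterior(tiny_model, patch, z=1e-8)
        assert np.allclose(cond.cov, tiny_model.prior_cov, atol=1e-10)
        assert np.allclose(cond.mean, 0.0, atol=1e-6)

    def test_loewner_order_in_z(self, tiny_model):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=2)[0]
        s1 = conditional_posterior(tiny_model, patch, z=1.0).cov
        s2 = conditional_posterior(tiny_model, patch, z=2.0).cov
        assert np.linalg.eigvalsh(s1 - s2).min() > -1e-10

    def test_mean_linear_in_image(self, tiny_model):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=3)[0]
        m1 = conditional_posterior(tiny_model, patch, z=1.5).mean
        m3 = conditional_posterior(
            tiny_model, ImagePatch(3.0 * patch.pixels), z=1.5
        ).mean
        assert np.allclose(m3, 3.0 * m1)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.2, 3.0), st.floats(0.2, 3.0))
    def test_loewner_monotonicity_random_models(self, seed, z_lo, z_gap):
        rng = np.random.default_rng(seed)
        params = random_small_model(rng)
        x = rng.standard_normal(params.n_pixels)
        s_lo = conditional_posterior(params, x, z=z_lo).cov
        s_hi = conditional_posterior(params, x, z=z_lo + z_gap).cov
        assert np.linalg.eigvalsh(s_lo - s_hi).min() > -1e-8


class TestMarginalMoments:
    def test_single_point_grid_equals_conditional(self, tiny_model, tiny_solver):
        from v1sampling.inference import ZGrid

        patch = natural_surrogate_ensemble(tiny_model, 1, seed=4)[0]
        z0 = 1.3
        grid = ZGrid(z_values=np.array([z0]), masses=np.array([1.0]))
        mom = tiny_solver.marginal_posterior_moments(patch, grid)
        cond = tiny_solver.conditional_posterior(patch, z0)
        assert np.allclose(mom.mean, cond.mean)
        assert np.allclose(mom.cov, cond.cov, atol=1e-12)

    def test_matches_importance_sampling_oracle(self, tiny_model, tiny_solver):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=5)[0]
        mom = tiny_solver.marginal_posterior_moments(patch)
        orc = importance_sampling_oracle(tiny_model, patch, 100_000, seed=6)
        assert np.linalg.norm(mom.mean - orc.mean) <= 0.02 * max(
            np.linalg.norm(orc.mean), 1e-3
        )
        assert np.linalg.norm(mom.cov - orc.cov) <= 0.02 * np.linalg.norm(orc.cov)

    def test_blank_moments_prior_dominated(self, tiny_model, tiny_solver):
        mom = tiny_solver.marginal_posterior_moments(blank(tiny_model.patch_side))
        assert np.allclose(mom.mean, 0.0, atol=1e-10)
        # covariance bounded above by the prior and dominated by it
        gap = tiny_model.prior_cov - mom.cov
        assert np.linalg.eigvalsh(gap).min() > -1e-10
        assert np.trace(mom.cov) > 0.5 * np.trace(tiny_model.prior_cov)
        # exact value cross-checked against the independent integrator
        orc = importance_sampling_oracle(
            tiny_model, blank(tiny_model.patch_side), 50_000, seed=12
        )
        assert np.linalg.norm(mom.cov - orc.cov) <= 0.02 * np.linalg.norm(orc.cov)


class TestSampler:
    def test_zero_samples_empty(self, tiny_model, tiny_solver):
        patch = blank(tiny_model.patch_side)
        out = tiny_solver.sample_posterior(patch, 0, seed=0)
        assert out.shape == (0, tiny_model.n_units)

    def test_sampler_moments_match_marginal(self, tiny_model, tiny_solver):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=7)[0]
        grid = tiny_solver.z_posterior(patch)
        samples = tiny_solver.sample_posterior(patch, 100_000, grid, seed=8)
        mom = tiny_solver.marginal_posterior_moments(patch, grid)
        se_mean = np.sqrt(np.diag(mom.cov) / len(samples))
        assert np.all(np.abs(samples.mean(axis=0) - mom.mean) < 6 * se_mean)
        emp_cov = np.cov(samples.T)
        rel = np.linalg.norm(emp_cov - mom.cov) / np.linalg.norm(mom.cov)
        assert rel < 0.03

    def test_seed_determinism(self, tiny_model, tiny_solver):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=9)[0]
        a = sample_posterior(tiny_model, patch, 50, seed=99)
        b = sample_posterior(tiny_model, patch, 50, seed=99)
        assert np.array_equal(a, b)


class TestImportanceSamplingOracle:
    def test_uninformative_image_returns_prior(self):
        rng = np.random.default_rng(0)
        params = random_small_model(rng)
        noisy = GSMParams(
            basis=params.basis, prior_cov=params.prior_cov,
            pixel_noise_var=1e6, contrast_shape=params.contrast_shape,
            contrast_scale=params.contrast_scale,
        )
        x = rng.standard_normal(params.n_pixels)
        orc = importance_sampling_oracle(noisy, x, 20_000, seed=1)
        assert np.allclose(orc.mean, 0.0, atol=0.01)
        rel = np.linalg.norm(orc.cov - params.prior_cov) / np.linalg.norm(
            params.prior_cov
        )
        assert rel < 0.05

    def test_minimum_particles_enforced(self, tiny_model):
        with pytest.raises(InvalidSpecificationError):
            importance_sampling_oracle(
                tiny_model, blank(tiny_model.patch_side), 100, seed=0
            )

    def test_reports_effective_sample_size(self, tiny_model):
        orc = importance_sampling_oracle(
            tiny_model, blank(tiny_model.patch_side), 2000, seed=0
        )
        assert orc.effective_sample_size is not None
        assert 1.0 <= orc.effective_sample_size <= 2000.0


class TestPriorAveragePosteriorMatching:
    def test_average_posterior_converges_to_prior(self, tiny_model, tiny_solver):
        """Mixture over adapted images of P(y|x) has mean 0 and covariance C."""
        patches = natural_surrogate_ensemble(tiny_model, 2000, seed=10)
        n = tiny_model.n_units
        mean_acc = np.zeros(n)
        second_acc = np.zeros((n, n))
        for patch in patches:
            mom = tiny_solver.marginal_posterior_moments(patch)
            mean_acc += mom.mean
            second_acc += mom.cov + np.outer(mom.mean, mom.mean)
        mean_acc /= len(patches)
        total_cov = second_acc / len(patches) - np.outer(mean_acc, mean_acc)
        prior_sd = np.sqrt(np.diag(tiny_model.prior_cov))
        assert np.all(np.abs(mean_acc) < 4 * prior_sd / np.sqrt(len(patches)))
        rel = np.linalg.norm(total_cov - tiny_model.prior_cov) / np.linalg.norm(
            tiny_model.prior_cov
        )
        assert rel < 0.05


class TestCaching:
    def test_cache_key_sensitivity(self, tiny_model):
        x = blank(tiny_model.patch_side)
        k1 = cache_key(tiny_model, x)
        k2 = cache_key(tiny_model, x)
        assert k1 == k2
        x2 = ImagePatch(x.pixels + 1e-6)
        assert cache_key(tiny_model, x2) != k1
        assert cache_key(tiny_model, x, {"n_points": 128}) != k1

    def test_roundtrip_json_and_hdf5(self, tiny_model, tiny_solver, tmp_path):
        patch = natural_surrogate_ensemble(tiny_model, 1, seed=11)[0]
        grid = tiny_solver.z_posterior(patch)
        mom = tiny_solver.marginal_posterior_moments(patch, grid)
        for obj in (grid, mom):
            jp = tmp_path / "obj.json"
            hp = tmp_path / "obj.h5"
            save_posterior_json(jp, obj)
            save_posterior_hdf5(hp, obj)
            for back in (load_posterior_json(jp), load_posterior_hdf5(hp)):
                assert type(back).__name__ == type(obj).__name__
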