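import numpy as np
import pytest

from v1sampling import (
    EncodingParams,
    GSMParams,
    PosteriorSolver,
    build_gabor_basis,
)


def random_small_model(rng: np.random.Generator, n_pixels: int = 16,
                       n_units: int = 5) -> GSMParams:
    """Random well-conditioned GSM instance for oracle cross-checks."""
    basis = rng.standard_normal((n_pixels, n_units))
    basis /= np.linalg.norm(basis, axis=0)
    raw = rng.standard_normal((n_units, n_units + 3))
    cov = raw @ raw.T / (n_units + 3)
    cov += 0.2 * np.eye(n_units)
    return GSMParams(
        basis=basis,
        prior_cov=cov,
        pixel_noise_var=float(rng.uniform(0.3, 1.5)),
        contrast_shape=float(rng.uniform(1.5, 3.0)),
        contrast_scale=float(rng.uniform(1.0, 2.5)),
    )


@pytest.fixture(scope="session")
def tiny_model() -> GSMParams:
    """Small deterministic model: 12x12 patch, 8 central Gabors."""
    basis, meta = build_gabor_basis(
        12, orientations=[0, 45, 90, 135], phases=[0, 90],
        frequencies=[2.0], return_meta=True,
    )
    n = basis.shape[1]
    cov = 0.3 * np.ones((n, n)) + 0.7 * np.eye(n)
    return GSMParams(basis=basis, prior_cov=cov, pixel_noise_var=1.0,
                     patch_side=12, basis_meta=meta)


@pytest.fixture(scope="session")
def tiny_solver(tiny_model) -> PosteriorSolver:
    return PosteriorSolver(tiny_model)


@pytest.fixture(scope="session")
def default_model() -> GSMParams:
    return GSMParams.from_config({})


@pytest.fixture(scope="session")
def default_solver(default_model) -> PosteriorSolver:
    return PosteriorSolver(default_model)


@pytest.fixture(scope="session")
def enc() -> EncodingParams:
    return EncodingParams()
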