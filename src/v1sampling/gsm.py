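"""Gaussian scale mixture (GSM) generative model of image patches.

The model assumes a patch of pixel intensities ``x`` arises as a global
contrast scalar ``z`` times a linear combination of Gabor basis functions
with activations ``y``, plus isotropic Gaussian pixel noise::

    x | y, z  ~  N(z * A @ y, pixel_noise_var * I)
    y         ~  N(0, C)
    z         ~  Gamma(shape=contrast_shape, scale=contrast_scale)

``A`` holds one flattened (row-major) Gabor filter per column, ``C`` is the
prior covariance of activations.  Because the model is its own best-adapted
stimulus ensemble, samples from the generative process serve as the
"natural image" surrogate throughout the package.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GSMParams",
    "ImagePatch",
    "LatentState",
    "build_gabor_basis",
    "default_prior_cov",
    "fit_prior_cov",
    "sample_prior",
    "generate_image",
    "natural_surrogate_ensemble",
    "save_patches_hdf5",
    "load_patches_hdf5",
    "save_patches_csv",
    "load_patches_csv",
]


class InvalidSpecificationError(ValueError):
    """Raised when a model or stimulus specification is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImagePatch:
    """A zero-mean grayscale image patch stored as a flat pixel vector."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).ravel()
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidSpecificationError("patch pixels must be finite")

    @property
    def n_pixels(self) -> int:
        return self.pixels.size

    def as_square(self, patch_side: int | None = None) -> np.ndarray:
        side = patch_side or int(round(np.sqrt(self.n_pixels)))
        return self.pixels.reshape(side, side)


@dataclass
class LatentState:
    """One draw of the latent variables: feature activations and contrast."""

    activations: np.ndarray
    contrast: float

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float).ravel()
        if not np.all(np.isfinite(self.activations)):
            raise InvalidSpecificationError("activations must be finite")
        if not (self.contrast > 0):
            raise InvalidSpecificationError("contrast must be > 0")


@dataclass
class GSMParams:
    """Parameters of the GSM generative model.

    Parameters
    ----------
    basis
        ``(n_pixels, n_units)`` matrix; one unit-norm Gabor filter per column.
    prior_cov
        ``(n_units, n_units)`` symmetric positive-definite prior covariance
        of activations.
    pixel_noise_var
        Variance of the white observation noise added per pixel.
    contrast_shape, contrast_scale
        Shape ``k`` and scale ``theta`` of the Gamma prior on the global
        contrast variable ``z``.
    patch_side
        Side length of the square patch, if the basis came from a square
        geometry (kept for serialization / display).
    """

    basis: np.ndarray
    prior_cov: np.ndarray
    pixel_noise_var: float = 1.0
    contrast_shape: float = 2.0
    contrast_scale: float = 2.0
    patch_side: int | None = None
    basis_meta: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.prior_cov = np.asarray(self.prior_cov, dtype=float)
        if self.basis.ndim != 2:
            raise InvalidSpecificationError("basis must be a 2-D matrix")
        if self.prior_cov.shape != (self.n_units, self.n_units):
            raise InvalidSpecificationError(
                "prior_cov shape %s does not match %d basis columns"
                % (self.prior_cov.shape, self.n_units)
            )
        if not np.all(np.isfinite(self.basis)):
            raise InvalidSpecificationError("basis entries must be finite")
        if not np.all(np.isfinite(self.prior_cov)):
            raise InvalidSpecificationError("prior_cov entries must be finite")
        if np.any(np.linalg.norm(self.basis, axis=0) == 0.0):
            raise InvalidSpecificationError("every basis column needs nonzero norm")
        if not np.allclose(self.prior_cov, self.prior_cov.T, atol=1e-10):
            raise InvalidSpecificationError("prior_cov must be symmetric")
        if not (self.pixel_noise_var > 0):
            raise InvalidSpecificationError("pixel_noise_var must be > 0")
        if not (self.contrast_shape > 0 and self.contrast_scale > 0):
            raise InvalidSpecificationError("Gamma parameters must be > 0")
        try:
            self._prior_chol = np.linalg.cholesky(self.prior_cov)
        except np.linalg.LinAlgError as err:
            raise InvalidSpecificationError(
                "prior_cov must be positive definite"
            ) from err

    @property
    def n_pixels(self) -> int:
        return self.basis.shape[0]

    @property
    def n_units(self) -> int:
        return self.basis.shape[1]

    def prior_cholesky(self) -> np.ndarray:
        return self._prior_chol

    def contrast_prior_mean(self) -> float:
        return self.contrast_shape * self.contrast_scale

    def contrast_second_moment(self) -> float:
        """E[z^2] = k * theta^2 * (k + 1) for a Gamma(k, theta) prior."""
        k, th = self.contrast_shape, self.contrast_scale
        return k * (k + 1.0) * th * th

    def marginal_pixel_cov(self) -> np.ndarray:
        """Closed-form marginal covariance of generated patches.

        Cov[x] = E[z^2] * A C A^T + pixel_noise_var * I.
        """
        acat = self.basis @ self.prior_cov @ self.basis.T
        return self.contrast_second_moment() * acat + self.pixel_noise_var * np.eye(
            self.n_pixels
        )

    # -- serialization ------------------------------------------------------

    def to_config(self) -> dict:
        cfg = {
            "patch_side": self.patch_side,
            "pixel_noise_var": float(self.pixel_noise_var),
            "contrast_shape": float(self.contrast_shape),
            "contrast_scale": float(self.contrast_scale),
        }
        if self.basis_meta is not None:
            cfg["basis"] = dict(self.basis_meta)
            cfg["prior_cov"] = {"mode": "parametric"}
            if "prior_length_scale" in self.basis_meta:
                cfg["prior_cov"]["length_scale"] = self.basis_meta[
                    "prior_length_scale"
                ]
        else:
            cfg["basis"] = {"explicit": self.basis.tolist()}
            cfg["prior_cov"] = {"mode": "explicit", "matrix": self.prior_cov.tolist()}
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "GSMParams":
        cfg = dict(cfg)
        basis_spec = cfg.get("basis", {})
        if "explicit" in basis_spec:
            basis = np.asarray(basis_spec["explicit"], dtype=float)
            meta = None
            patch_side = cfg.get("patch_side")
        else:
            patch_side = int(cfg.get("patch_side", 24))
            meta = dict(basis_spec)
            mid = (patch_side - 1) / 2.0
            off = patch_side / 4.0
            default_centers = [
                (mid, mid), (mid - off, mid - off), (mid + off, mid + off)
            ]
            basis, meta = build_gabor_basis(
                patch_side,
                orientations=meta.get("orientations", [float(v) for v in range(0, 180, 15)]),
                phases=meta.get("phases", [0, 90]),
                frequencies=meta.get("frequencies", [3.0]),
                centers=meta.get("centers", default_centers),
                envelope_factor=float(meta.get("envelope_factor", 0.45)),
                return_meta=True,
            )
        pc_spec = cfg.get("prior_cov", {"mode": "parametric"})
        mode = pc_spec.get("mode", "parametric")
        if mode == "explicit":
            prior_cov = np.asarray(pc_spec["matrix"], dtype=float)
        elif mode == "identity":
            prior_cov = np.eye(basis.shape[1])
        elif mode == "parametric":
            if meta is None:
                raise InvalidSpecificationError(
                    "parametric prior_cov needs a parametric basis spec"
                )
            prior_cov = default_prior_cov(
                meta, length_scale=float(pc_spec.get("length_scale", 0.8))
            )
            meta["prior_length_scale"] = float(pc_spec.get("length_scale", 0.8))
        else:
            raise InvalidSpecificationError("unknown prior_cov mode %r" % mode)
        return cls(
            basis=basis,
            prior_cov=prior_cov,
            pixel_noise_var=float(cfg.get("pixel_noise_var", 1.0)),
            contrast_shape=float(cfg.get("contrast_shape", 2.0)),
            contrast_scale=float(cfg.get("contrast_scale", 2.0)),
            patch_side=patch_side,
            basis_meta=meta,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_config(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GSMParams":
        if hasattr(source, "read"):
            cfg = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    cfg = yaml.safe_load(fh)
            except (OSError, ValueError):
                cfg = yaml.safe_load(_io.StringIO(str(source)))
        return cls.from_config(cfg)


# ---------------------------------------------------------------------------
# Gabor basis construction
# ---------------------------------------------------------------------------

def _gabor_filter(
    patch_side: int,
    orientation_deg: float,
    phase_deg: float,
    frequency: float,
    center: tuple[float, float],
    envelope_factor: float = 0.45,
) -> np.ndarray:
    """One Gabor filter on a square grid, flattened row-major.

    ``frequency`` is in cycles per patch; the Gaussian envelope scales with
    the wavelength (sigma = envelope_factor * wavelength) so filters at
    different frequencies keep a comparable bandwidth in octaves.
    Coordinates are 0-based with origin at the top-left; ``center`` is
    (row, col).
    """
    rows, cols = np.mgrid[0:patch_side, 0:patch_side].astype(float)
    dy = rows - center[0]
    dx = cols - center[1]
    theta = np.deg2rad(orientation_deg)
    xr = dx * np.cos(theta) + dy * np.sin(theta)
    wavelength = patch_side / frequency
    sigma = envelope_factor * wavelength
    envelope = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
    carrier = np.cos(2.0 * np.pi * xr / wavelength + np.deg2rad(phase_deg))
    g = envelope * carrier
    g -= g.mean()  # zero-DC so blank stimuli do not drive filters
    return g.ravel()


def gabor_envelope_sigma(patch_side: int, frequency: float,
                         envelope_factor: float = 0.45) -> float:
    """Gaussian envelope sigma (pixels) used for a given frequency."""
    return envelope_factor * patch_side / frequency


def build_gabor_basis(
    patch_side: int,
    orientations,
    phases,
    frequencies,
    centers=None,
    envelope_factor: float = 0.45,
    return_meta: bool = False,
):
    """Build a unit-norm Gabor filter bank.

    One column per (orientation, phase, frequency, center) combination, in
    lexicographic order over the parameter lists as given.  Each column is
    normalized to unit Euclidean norm.

    Returns the ``(n_pixels, n_columns)`` matrix, and additionally a
    metadata dict (parameter lists plus per-column parameter table) when
    ``return_meta`` is true.
    """
    if patch_side < 4:
        raise InvalidSpecificationError("patch_side must be >= 4")
    if centers is None:
        mid = (patch_side - 1) / 2.0
        centers = [(mid, mid)]
    orientations = list(orientations)
    phases = list(phases)
    frequencies = list(frequencies)
    centers = [tuple(float(v) for v in c) for c in centers]
    for name, lst in (
        ("orientations", orientations),
        ("phases", phases),
        ("frequencies", frequencies),
        ("centers", centers),
    ):
        if len(lst) == 0:
            raise InvalidSpecificationError("empty parameter list: %s" % name)

    columns = []
    table = []
    for ori in orientations:
        for ph in phases:
            for fr in frequencies:
                for ctr in centers:
                    g = _gabor_filter(
                        patch_side, ori, ph, fr, ctr, envelope_factor
                    )
                    nrm = np.linalg.norm(g)
                    if nrm == 0.0:
                        raise InvalidSpecificationError(
                            "degenerate Gabor (zero norm) at "
                            f"ori={ori}, phase={ph}, freq={fr}, center={ctr}"
                        )
                    columns.append(g / nrm)
                    table.append(
                        {
                            "orientation": float(ori),
                            "phase": float(ph),
                            "frequency": float(fr),
                            "center": ctr,
                        }
                    )
    basis = np.column_stack(columns)
    if return_meta:
        meta = {
            "orientations": [float(v) for v in orientations],
            "phases": [float(v) for v in phases],
            "frequencies": [float(v) for v in frequencies],
            "centers": [list(c) for c in centers],
            "envelope_factor": float(envelope_factor),
            "columns": table,
            "patch_side": int(patch_side),
        }
        return basis, meta
    return basis


def default_prior_cov(basis_meta: dict, length_scale: float = 1.0) -> np.ndarray:
    """Parametric prior covariance from Gabor-parameter similarity.

    Unit variances; correlation exp(-d^2 / length_scale^2) where d is a
    normalized distance combining orientation (circular over 180 deg),
    phase (circular over 360 deg), log-frequency and center separation.
    Off-diagonals are shrunk towards zero if needed to keep the matrix
    positive definite.
    """
    cols = basis_meta["columns"]
    patch_side = basis_meta.get("patch_side", 24)
    n = len(cols)
    ori = np.array([c["orientation"] for c in cols])
    ph = np.array([c["phase"] for c in cols])
    fr = np.array([c["frequency"] for c in cols])
    ctr = np.array([c["center"] for c in cols])

    d_ori = np.abs(ori[:, None] - ori[None, :]) % 180.0
    d_ori = np.minimum(d_ori, 180.0 - d_ori) / 45.0
    d_ph = np.abs(ph[:, None] - ph[None, :]) % 360.0
    d_ph = np.minimum(d_ph, 360.0 - d_ph) / 90.0
    d_fr = np.abs(np.log2(fr[:, None]) - np.log2(fr[None, :]))
    d_ctr = np.linalg.norm(ctr[:, None, :] - ctr[None, :, :], axis=-1) / (
        0.25 * patch_side
    )
    d2 = d_ori**2 + d_ph**2 + d_fr**2 + d_ctr**2
    corr = np.exp(-d2 / (length_scale**2))
    np.fill_diagonal(corr, 1.0)

    # shrink off-diagonal mass until comfortably positive definite
    shrink = 1.0
    for _ in range(60):
        cand = shrink * corr + (1.0 - shrink) * np.eye(n)
        if np.linalg.eigvalsh(cand)[0] > 1e-6:
            return cand
        shrink *= 0.9
    raise InvalidSpecificationError("could not construct a PD prior covariance")


def fit_prior_cov(
    basis: np.ndarray,
    patches: np.ndarray,
    pixel_noise_var: float,
    contrast_second_moment: float,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Estimate C by matching filter-response covariances on a patch ensemble.

    Inverts the marginal identity Cov[x] = E[z^2] A C A^T + sigma_x^2 I with
    the basis pseudo-inverse, then projects to the nearest (in the eigenvalue
    sense) positive-definite symmetric matrix.

    Parameters
    ----------
    patches
        ``(n, n_pixels)`` array of zero-mean patches.
    """
    patches = np.atleast_2d(np.asarray(patches, dtype=float))
    emp = patches.T @ patches / patches.shape[0]
    pinv = np.linalg.pinv(basis)
    c_hat = pinv @ (emp - pixel_noise_var * np.eye(basis.shape[0])) @ pinv.T
    c_hat /= contrast_second_moment
    c_hat = 0.5 * (c_hat + c_hat.T)
    w, v = np.linalg.eigh(c_hat)
    w = np.maximum(w, ridge)
    return (v * w) @ v.T


# ---------------------------------------------------------------------------
# Sampling the generative process
# ---------------------------------------------------------------------------

def _sample_prior_arrays(params: GSMParams, n: int, rng: np.random.Generator):
    """Vectorized prior draws: activations (n, n_units) and contrasts (n,)."""
    L = params.prior_cholesky()
    y = rng.standard_normal((n, params.n_units)) @ L.T
    z = rng.gamma(params.contrast_shape, params.contrast_scale, size=n)
    return y, z


def sample_prior(params: GSMParams, n: int, seed: int) -> list[LatentState]:
    """Draw ``n`` i.i.d. latent states from the prior.

    Activations ~ N(0, C); contrast ~ Gamma(k, theta).  Deterministic for a
    fixed seed.
    """
    if n < 0:
        raise InvalidSpecificationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    y, z = _sample_prior_arrays(params, n, rng)
    return [LatentState(activations=y[i], contrast=float(z[i])) for i in range(n)]


def generate_image(params: GSMParams, latent: LatentState, seed: int) -> ImagePatch:
    """Render one patch from a latent state: x = z A y + pixel noise."""
    if latent.activations.size != params.n_units:
        raise InvalidSpecificationError(
            "latent has %d activations, model expects %d"
            % (latent.activations.size, params.n_units)
        )
    rng = np.random.default_rng(seed)
    mean = latent.contrast * (params.basis @ latent.activations)
    noise = rng.normal(0.0, np.sqrt(params.pixel_noise_var), size=params.n_pixels)
    return ImagePatch(pixels=mean + noise)


def _surrogate_arrays(params: GSMParams, n: int, rng: np.random.Generator):
    y, z = _sample_prior_arrays(params, n, rng)
    mean = z[:, None] * (y @ params.basis.T)
    noise = rng.normal(
        0.0, np.sqrt(params.pixel_noise_var), size=(n, params.n_pixels)
    )
    return mean + noise, y, z


def natural_surrogate_ensemble(
    params: GSMParams, n: int, seed: int
) -> list[ImagePatch]:
    """Sample ``n`` patches from the model's own generative process.

    This ensemble plays the role of natural images in every adapted-stimulus
    experiment: by construction the model is perfectly adapted to it, which
    is the condition the prior/average-posterior identity requires.
    """
    if n < 1:
        raise InvalidSpecificationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pix, _, _ = _surrogate_arrays(params, n, rng)
    return [ImagePatch(pixels=pix[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# Patch ensemble I/O
# ---------------------------------------------------------------------------

def _patches_to_array(patches) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        return np.atleast_2d(patches.astype(float))
    return np.array([p.pixels for p in patches], dtype=float)


def save_patches_hdf5(path, patches) -> None:
    import h5py

    arr = _patches_to_array(patches)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("patches", data=arr, dtype="float64")


def load_patches_hdf5(path) -> list[ImagePatch]:
    import h5py

    with h5py.File(path, "r") as fh:
        arr = fh["patches"][...]
    return [ImagePatch(pixels=row) for row in np.atleast_2d(arr)]


def save_patches_csv(path, patches) -> None:
    np.savetxt(path, _patches_to_array(patches), delimiter=",")


def load_patches_csv(path) -> list[ImagePatch]:
    arr = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return [ImagePatch(pixels=row) for row in arr]
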