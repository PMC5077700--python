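"""Parametric visual stimuli: gratings, apertures, block noise, blanks, surrogates.

Contrast is parameterized as the RMS pixel amplitude of the pattern relative
to a configurable maximum (``rms_max``): a contrast-1.0 grating has pixel
standard deviation ``rms_max``.  All patterns are zero-mean, matching the
zero-mean Gaussian pixel likelihood of the generative model.  Aperture
masking zeroes pixels outside a hard disc; the small-aperture condition
emulates stimulation confined to the classical receptive field (CRF), the
full aperture adds the non-classical surround (nCRF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gsm import (
    GSMParams,
    ImagePatch,
    InvalidSpecificationError,
    _surrogate_arrays,
)

__all__ = [
    "StimulusSpec",
    "StimulusSequence",
    "grating",
    "drifting_grating",
    "apply_aperture",
    "block_noise",
    "blank",
    "surrogate_sequence",
    "make_stimulus",
    "DEFAULT_RMS_MAX",
]

#: RMS pixel amplitude of a contrast-1.0 pattern, in model pixel units.
#: Chosen of the same order as the pixel scale of generated patches so that
#: "high contrast" drives the inferred z well above its prior mean.
DEFAULT_RMS_MAX = 1.25

_KINDS = {"grating", "drifting_grating", "block_noise", "blank", "surrogate"}


@dataclass
class StimulusSpec:
    """Declarative description of one parametric stimulus."""

    kind: str = "grating"
    orientation: float = 0.0  # degrees in [0, 180)
    contrast: float = 1.0  # RMS amplitude relative to rms_max, in [0, 1]
    spatial_frequency: float = 3.0  # cycles per patch
    phase: float = 0.0  # degrees
    drift_rate: float = 30.0  # degrees of phase per frame
    aperture_radius: float | str = "full"  # pixels, or "full"
    block_size: int = 4  # pixels
    seed: int = 0
    rms_max: float = DEFAULT_RMS_MAX

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidSpecificationError("unknown stimulus kind %r" % self.kind)
        if not (0.0 <= self.contrast <= 1.0):
            raise InvalidSpecificationError("contrast must lie in [0, 1]")
        if not (self.spatial_frequency > 0):
            raise InvalidSpecificationError("spatial_frequency must be > 0")
        if self.aperture_radius != "full" and self.aperture_radius < 0:
            raise InvalidSpecificationError("aperture_radius must be >= 0")

    def to_config(self) -> dict:
        return {
            "kind": self.kind,
            "orientation": float(self.orientation),
            "contrast": float(self.contrast),
            "spatial_frequency": float(self.spatial_frequency),
            "phase": float(self.phase),
            "drift_rate": float(self.drift_rate),
            "aperture_radius": self.aperture_radius
            if self.aperture_radius == "full"
            else float(self.aperture_radius),
            "block_size": int(self.block_size),
            "seed": int(self.seed),
            "rms_max": float(self.rms_max),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "StimulusSpec":
        return cls(**cfg)


@dataclass
class StimulusSequence:
    """An ordered sequence of frames shown for a fixed duration each."""

    frames: list
    frame_duration: float = 20.0  # ms

    def __post_init__(self) -> None:
        if not (self.frame_duration > 0):
            raise InvalidSpecificationError("frame_duration must be > 0")
        sizes = {f.n_pixels for f in self.frames}
        if len(sizes) > 1:
            raise InvalidSpecificationError("all frames must share dimensions")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def blank(patch_side: int) -> ImagePatch:
    """All-zero patch (zero contrast stimulus)."""
    return ImagePatch(pixels=np.zeros(patch_side * patch_side))


def grating(spec: StimulusSpec, patch_side: int) -> ImagePatch:
    """Static sinusoidal grating, zero-mean, RMS = contrast * rms_max."""
    if spec.contrast == 0.0:
        return blank(patch_side)
    rows, cols = np.mgrid[0:patch_side, 0:patch_side].astype(float)
    mid = (patch_side - 1) / 2.0
    dx, dy = cols - mid, rows - mid
    theta = np.deg2rad(spec.orientation)
    xr = dx * np.cos(theta) + dy * np.sin(theta)
    wavelength = patch_side / spec.spatial_frequency
    pattern = np.cos(2.0 * np.pi * xr / wavelength + np.deg2rad(spec.phase))
    pattern -= pattern.mean()
    rms = np.sqrt(np.mean(pattern**2))
    if rms > 0:
        pattern *= spec.contrast * spec.rms_max / rms
    return ImagePatch(pixels=pattern.ravel())


def drifting_grating(
    spec: StimulusSpec, n_frames: int, patch_side: int,
    frame_duration: float = 20.0,
) -> StimulusSequence:
    """Grating whose phase advances by ``drift_rate`` degrees per frame."""
    if spec.drift_rate == 0:
        raise InvalidSpecificationError("drift_rate must be nonzero")
    frames = []
    for t in range(n_frames):
        f = StimulusSpec(
            kind="grating",
            orientation=spec.orientation,
            contrast=spec.contrast,
            spatial_frequency=spec.spatial_frequency,
            phase=spec.phase + t * spec.drift_rate,
            rms_max=spec.rms_max,
        )
        frames.append(grating(f, patch_side))
    return StimulusSequence(frames=frames, frame_duration=frame_duration)


def apply_aperture(
    patch: ImagePatch, radius, center: tuple[float, float] | None = None,
    taper: float = 0.0,
) -> ImagePatch:
    """Zero pixels outside a disc of the given radius (pixels).

    ``radius="full"`` (or any radius covering the patch) leaves the patch
    unchanged; ``radius=0`` yields a blank.  ``center`` is (row, col),
    defaulting to the patch center.  The edge is hard by default;
    ``taper > 0`` applies a raised-cosine rolloff over that many pixels
    inside the radius, which avoids the sharp edge itself acting as
    broadband contrast.
    """
    side = int(round(np.sqrt(patch.n_pixels)))
    if radius == "full":
        return ImagePatch(pixels=patch.pixels.copy())
    if radius < 0:
        raise InvalidSpecificationError("radius must be >= 0")
    if center is None:
        center = ((side - 1) / 2.0, (side - 1) / 2.0)
    rows, cols = np.mgrid[0:side, 0:side].astype(float)
    dist = np.sqrt((rows - center[0]) ** 2 + (cols - center[1]) ** 2)
    if taper > 0:
        ramp = np.clip((radius - dist) / taper, 0.0, 1.0)
        mask = 0.5 - 0.5 * np.cos(np.pi * ramp)
    else:
        mask = (dist <= radius).astype(float)
    return ImagePatch(pixels=(patch.as_square(side) * mask).ravel())


def block_noise(
    patch_side: int, block_size: int, seed: int,
    amplitude: float = DEFAULT_RMS_MAX,
) -> ImagePatch:
    """Random +/- amplitude values, constant within block_size x block_size blocks."""
    if block_size <= 0 or patch_side % block_size != 0:
        raise InvalidSpecificationError(
            "block_size must divide patch_side (%d %% %d != 0)"
            % (patch_side, block_size)
        )
    rng = np.random.default_rng(seed)
    nb = patch_side // block_size
    blocks = rng.choice([-amplitude, amplitude], size=(nb, nb))
    img = np.kron(blocks, np.ones((block_size, block_size)))
    return ImagePatch(pixels=img.ravel())


def surrogate_sequence(
    params: GSMParams, n_frames: int, seed: int, frame_duration: float = 20.0
) -> StimulusSequence:
    """A movie of fresh samples from the model's own generative process.

    Emulates natural-movie stimulation for an observer whose internal model
    is perfectly adapted to the stimulus statistics.
    """
    if n_frames < 1:
        raise InvalidSpecificationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    pix, _, _ = _surrogate_arrays(params, n_frames, rng)
    return StimulusSequence(
        frames=[ImagePatch(pixels=row) for row in pix],
        frame_duration=frame_duration,
    )


def make_stimulus(spec: StimulusSpec, patch_side: int,
                  params: GSMParams | None = None):
    """Dispatch a StimulusSpec to its generator; applies any aperture."""
    if spec.kind == "grating":
        out = grating(spec, patch_side)
    elif spec.kind == "blank":
        out = blank(patch_side)
    elif spec.kind == "block_noise":
        out = block_noise(patch_side, spec.block_size, spec.seed)
    elif spec.kind == "surrogate":
        if params is None:
            raise InvalidSpecificationError("surrogate stimuli need GSMParams")
        rng = np.random.default_rng(spec.seed)
        pix, _, _ = _surrogate_arrays(params, 1, rng)
        out = ImagePatch(pixels=pix[0])
    elif spec.kind == "drifting_grating":
        raise InvalidSpecificationError(
            "use drifting_grating() for sequences; make_stimulus is per-patch"
        )
    if spec.aperture_radius != "full":
        out = apply_aperture(out, spec.aperture_radius)
    return out
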