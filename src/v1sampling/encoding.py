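"""Neural encoding chain: posterior samples → membrane potentials → rates → spikes.

Each 20 ms bin holds one independent sample from the activation posterior
(the sampling hypothesis: membrane-potential autocorrelations decay on that
timescale, so consecutive bins are modeled as independent draws).  The
sample is mapped through a weak compressive nonlinearity to a dimensionless
membrane potential,

    u_i = sign(y_i) * |y_i|**alpha ,

then through a rectified power law to an instantaneous firing rate in Hz,

    r_i = gain * max(u_i - threshold, 0)**beta .

Spike counts are produced deterministically from rates: the cumulative
expected-spike integral is offset by an independent uniform-[0, 1) phase per
unit and trial, and the count is the number of integer crossings.  All count
variability therefore originates in the posterior samples, not in the
spiking mechanism (sub-Poisson for constant rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gsm import GSMParams, ImagePatch, InvalidSpecificationError
from .inference import PosteriorSolver, ZGrid

__all__ = [
    "EncodingParams",
    "MembraneTrace",
    "RateTrace",
    "SpikeCountMatrix",
    "SimulatedTrials",
    "membrane_from_activations",
    "rate_from_membrane",
    "spikes_from_rate",
    "spike_counts_per_bin",
    "simulate_trials",
    "save_trials_hdf5",
    "load_trials_hdf5",
    "counts_to_csv",
]


@dataclass
class EncodingParams:
    """The four free response parameters plus the timing scheme.

    alpha : exponent of the compressive membrane nonlinearity (< 1 = weak
        compression); gain : rate scale in Hz; threshold : rectification
    threshold in membrane units; beta : rate exponent (2 = standard
    quadratic rectification).  ``sample_interval`` is the independence
    timescale in ms; ``trial_duration`` must be a positive multiple of it.
    """

    alpha: float = 0.8
    gain: float = 40.0
    threshold: float = 0.6
    beta: float = 2.0
    sample_interval: float = 20.0
    trial_duration: float = 400.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise InvalidSpecificationError("alpha must be > 0")
        if self.gain < 0:
            raise InvalidSpecificationError("gain must be >= 0")
        if not (self.beta > 0):
            raise InvalidSpecificationError("beta must be > 0")
        if not (self.sample_interval > 0):
            raise InvalidSpecificationError("sample_interval must be > 0")
        n = self.trial_duration / self.sample_interval
        if not (self.trial_duration > 0 and np.isclose(n, round(n))):
            raise InvalidSpecificationError(
                "trial_duration must be a positive multiple of sample_interval"
            )

    @property
    def n_bins(self) -> int:
        return int(round(self.trial_duration / self.sample_interval))


@dataclass
class MembraneTrace:
    """Membrane potentials, units x bins, dimensionless model units."""

    values: np.ndarray
    sample_interval: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecificationError("membrane values must be finite")


@dataclass
class RateTrace:
    """Instantaneous firing rates, units x bins, Hz."""

    values: np.ndarray
    sample_interval: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise InvalidSpecificationError("rates must be nonnegative")


@dataclass
class SpikeCountMatrix:
    """Integer spike counts, units x trials."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise InvalidSpecificationError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise InvalidSpecificationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Pointwise nonlinearities
# ---------------------------------------------------------------------------

def membrane_from_activations(y, alpha: float):
    """u = sign(y) |y|^alpha, elementwise (odd symmetric)."""
    if not (alpha > 0):
        raise InvalidSpecificationError("alpha must be > 0")
    y = np.asarray(y, dtype=float)
    return np.sign(y) * np.abs(y) ** alpha


def rate_from_membrane(u, params: EncodingParams):
    """r = gain * (u - threshold)_+ ^ beta, in Hz."""
    u = np.asarray(u, dtype=float)
    return params.gain * np.clip(u - params.threshold, 0.0, None) ** params.beta


# ---------------------------------------------------------------------------
# Spike generation
# ---------------------------------------------------------------------------

def _cumulative_expected(rate_values: np.ndarray, sample_interval: float):
    """Cumulative expected spike count at bin edges, units x (bins+1)."""
    dt_s = sample_interval / 1000.0
    inc = np.asarray(rate_values, dtype=float) * dt_s
    c = np.cumsum(inc, axis=-1)
    zero = np.zeros(c.shape[:-1] + (1,))
    return np.concatenate([zero, c], axis=-1)


def spikes_from_rate(rate, seed: int | np.random.Generator = 0,
                     sample_interval: float | None = None) -> np.ndarray:
    """Spike counts for one trial: integer crossings of the phased integral.

    Per unit, the cumulative expected-spike integral is offset by an
    independent uniform-[0, 1) phase; the trial count is the number of
    integers crossed, i.e. floor(total + phase).  Deterministic given the
    phase: a constant 50 Hz rate over 1 s yields exactly 50 spikes for any
    phase.
    """
    if isinstance(rate, RateTrace):
        values = rate.values
        sample_interval = rate.sample_interval
    else:
        values = np.atleast_2d(np.asarray(rate, dtype=float))
        if sample_interval is None:
            sample_interval = 20.0
    if np.any(values < 0):
        raise InvalidSpecificationError("rates must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = _cumulative_expected(values, sample_interval)[..., -1]
    phase = rng.uniform(0.0, 1.0, size=total.shape)
    return np.floor(total + phase).astype(np.int64)


def spike_counts_per_bin(rate, seed: int | np.random.Generator = 0,
                         sample_interval: float | None = None) -> np.ndarray:
    """Per-bin spike counts (units x bins) under the same phase rule."""
    if isinstance(rate, RateTrace):
        values = rate.values
        sample_interval = rate.sample_interval
    else:
        values = np.atleast_2d(np.asarray(rate, dtype=float))
        if sample_interval is None:
            sample_interval = 20.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = _cumulative_expected(values, sample_interval)
    phase = rng.uniform(0.0, 1.0, size=values.shape[:-1] + (1,))
    crossed = np.floor(c + phase)
    return np.diff(crossed, axis=-1).astype(np.int64)


# ---------------------------------------------------------------------------
# Full trial simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrials:
    """Output of :func:`simulate_trials`.

    membrane, rate : arrays of shape (n_trials, n_units, n_bins);
    counts : SpikeCountMatrix (n_units x n_trials) integrating whole trials.
    """

    membrane: np.ndarray
    rate: np.ndarray
    counts: SpikeCountMatrix
    sample_interval: float

    def membrane_traces(self) -> list[MembraneTrace]:
        return [MembraneTrace(m, self.sample_interval) for m in self.membrane]

    def rate_traces(self) -> list[RateTrace]:
        return [RateTrace(r, self.sample_interval) for r in self.rate]

    def counts_per_bin(self, seed: int | np.random.Generator = 0) -> np.ndarray:
        """(n_trials, n_units, n_bins) per-bin counts re-derived from rates."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return np.stack(
            [spike_counts_per_bin(r, rng, self.sample_interval) for r in self.rate]
        )


def save_trials_hdf5(path, trials: "SimulatedTrials") -> None:
    """Write membrane/rate traces (trial x unit x bin) and counts to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("membrane", data=trials.membrane)
        fh.create_dataset("rate", data=trials.rate)
        fh.create_dataset("counts", data=trials.counts.counts)
        fh.attrs["sample_interval"] = trials.sample_interval


def load_trials_hdf5(path) -> "SimulatedTrials":
    import h5py

    with h5py.File(path, "r") as fh:
        return SimulatedTrials(
            membrane=fh["membrane"][...],
            rate=fh["rate"][...],
            counts=SpikeCountMatrix(fh["counts"][...]),
            sample_interval=float(fh.attrs["sample_interval"]),
        )


def counts_to_csv(path, counts: SpikeCountMatrix, stimulus: str = "") -> None:
    """Long-format CSV: unit, stimulus, trial, count."""
    import pandas as pd

    c = counts.counts
    u, t = np.meshgrid(np.arange(c.shape[0]), np.arange(c.shape[1]),
                       indexing="ij")
    pd.DataFrame(
        {"unit": u.ravel(), "stimulus": stimulus, "trial": t.ravel(),
         "count": c.ravel()}
    ).to_csv(path, index=False)


def simulate_trials(
    model: GSMParams,
    enc: EncodingParams,
    x,
    n_trials: int,
    seed: int,
    solver: PosteriorSolver | None = None,
    grid: ZGrid | None = None,
) -> SimulatedTrials:
    """Simulate repeated trials of the full encoding chain for one stimulus.

    ``x`` is a static :class:`~v1sampling.gsm.ImagePatch` (posterior computed
    once) or a :class:`~v1sampling.stimuli.StimulusSequence` (posterior
    recomputed per frame; the frame duration must be a multiple of the
    sample interval).  Each 20 ms bin of each trial holds one fresh
    posterior sample mapped through the membrane and rate nonlinearities;
    spike counts integrate the whole trial.
    """
    if n_trials < 0:
        raise InvalidSpecificationError("n_trials must be >= 0")
    solver = solver or PosteriorSolver(model)
    rng = np.random.default_rng(seed)
    n_units = model.n_units
    n_bins = enc.n_bins

    frames = getattr(x, "frames", None)
    if frames is not None:
        frame_duration = x.frame_duration
        ratio = frame_duration / enc.sample_interval
        if not np.isclose(ratio, round(ratio)) or ratio <= 0:
            raise InvalidSpecificationError(
                "frame_duration must be a positive multiple of sample_interval"
            )
        bins_per_frame = int(round(ratio))
        frame_of_bin = np.repeat(np.arange(len(frames)), bins_per_frame)
        if frame_of_bin.size < n_bins:
            # loop the sequence to fill the trial
            reps = int(np.ceil(n_bins / frame_of_bin.size))
            frame_of_bin = np.tile(frame_of_bin, reps)
        frame_of_bin = frame_of_bin[:n_bins]
        unique_frames = np.unique(frame_of_bin)
        y = np.empty((n_trials, n_units, n_bins))
        for f in unique_frames:
            cols = np.where(frame_of_bin == f)[0]
            g = solver.z_posterior(frames[f]) if grid is None else grid
            samp = solver.sample_posterior(
                frames[f], n_trials * cols.size, grid=g, seed=rng
            )
            y[:, :, cols] = samp.reshape(n_trials, cols.size, n_units).transpose(
                0, 2, 1
            )
    else:
        g = grid if grid is not None else solver.z_posterior(x)
        samp = solver.sample_posterior(x, n_trials * n_bins, grid=g, seed=rng)
        y = samp.reshape(n_trials, n_bins, n_units).transpose(0, 2, 1)

    u = membrane_from_activations(y, enc.alpha)
    r = rate_from_membrane(u, enc)
    total = _cumulative_expected(r, enc.sample_interval)[..., -1]  # trials x units
    phase = rng.uniform(0.0, 1.0, size=total.shape)
    counts = np.floor(total + phase).astype(np.int64).T  # units x trials
    return SimulatedTrials(
        membrane=u,
        rate=r,
        counts=SpikeCountMatrix(counts),
        sample_interval=enc.sample_interval,
    )
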