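"""Variability statistics: tuning, Fano factors, correlations, sparseness,
reliability, population word distributions and KL divergences.

These are the analysis procedures used to compare the sampling model's
simulated responses with the statistics reported for V1 populations:
mean-matched Fano factors, signal/noise/spontaneous correlations, lifetime
sparseness, membrane-potential reliability, separation angles between mean
response vectors, and plug-in KL divergence between binarized population
"word" distributions with shuffle and split-half controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsm import InvalidSpecificationError

__all__ = [
    "TrialEnsemble",
    "CorrelationResult",
    "FanoResult",
    "DivergenceResult",
    "TuningCurveResult",
    "tuning_curve",
    "fano_factor",
    "mean_matched_fano",
    "signal_correlations",
    "noise_correlations",
    "spontaneous_correlations",
    "lifetime_sparseness",
    "response_reliability",
    "separation_angle",
    "word_distribution",
    "kl_divergence",
    "shuffle_across_units",
    "split_half_baseline",
    "bootstrap_mean_ci",
    "paired_bootstrap_pvalue",
]


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TrialEnsemble:
    """Responses organized as units x stimuli x trials plus stimulus labels.

    ``responses`` may hold integer spike counts or real-valued summaries
    (mean membrane potential / rate per trial).  ``stimulus_labels`` is a
    DataFrame with one row per stimulus (attributes such as orientation,
    contrast, condition).
    """

    responses: np.ndarray
    stimulus_labels: pd.DataFrame | None = None
    units: list | None = None
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim == 2:  # unit x trial, single stimulus
            self.responses = self.responses[:, None, :]
        if self.responses.ndim != 3:
            raise InvalidSpecificationError(
                "responses must be units x stimuli x trials"
            )
        if not np.all(np.isfinite(self.responses.astype(float))):
            raise InvalidSpecificationError("responses contain non-finite cells")
        if self.kind == "counts":
            if np.any(self.responses < 0) or not np.allclose(
                self.responses, np.round(self.responses)
            ):
                raise InvalidSpecificationError(
                    "count ensembles need nonnegative integers"
                )
        if self.stimulus_labels is not None and len(self.stimulus_labels) != (
            self.responses.shape[1]
        ):
            raise InvalidSpecificationError("one label row per stimulus required")
        if self.units is None:
            self.units = list(range(self.responses.shape[0]))

    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.responses.shape[1]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[2]

    def trial_means(self) -> np.ndarray:
        """units x stimuli mean over trials."""
        return self.responses.mean(axis=2)

    def to_frame(self) -> pd.DataFrame:
        u, s, t = np.meshgrid(
            np.arange(self.n_units),
            np.arange(self.n_stimuli),
            np.arange(self.n_trials),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "unit": np.asarray(self.units)[u.ravel()],
                "stimulus": s.ravel(),
                "trial": t.ravel(),
                "value": self.responses.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "counts") -> "TrialEnsemble":
        pivot = df.pivot_table(
            index="unit", columns=["stimulus", "trial"], values="value"
        )
        units = list(pivot.index)
        n_stim = df["stimulus"].nunique()
        n_trial = df["trial"].nunique()
        arr = pivot.to_numpy().reshape(len(units), n_stim, n_trial)
        return cls(responses=arr, units=units, kind=kind)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("responses", data=self.responses)
            fh.attrs["kind"] = self.kind
            fh.create_dataset(
                "units", data=np.asarray(self.units, dtype="S32")
            )
            if self.stimulus_labels is not None:
                grp = fh.create_group("stimulus_labels")
                for col in self.stimulus_labels.columns:
                    vals = self.stimulus_labels[col].to_numpy()
                    if vals.dtype.kind in "OU":
                        vals = vals.astype("S64")
                    grp.create_dataset(col, data=vals)

    @classmethod
    def from_hdf5(cls, path) -> "TrialEnsemble":
        import h5py

        with h5py.File(path, "r") as fh:
            responses = fh["responses"][...]
            kind = fh.attrs["kind"]
            units = [u.decode() for u in fh["units"][...]]
            labels = None
            if "stimulus_labels" in fh:
                cols = {}
                for col in fh["stimulus_labels"]:
                    vals = fh["stimulus_labels"][col][...]
                    if vals.dtype.kind == "S":
                        vals = np.char.decode(vals)
                    cols[col] = vals
                labels = pd.DataFrame(cols)
        return cls(responses=responses, stimulus_labels=labels, units=units,
                   kind=str(kind))


@dataclass
class CorrelationResult:
    """Per-pair Pearson correlations (upper triangle, diagonal excluded)."""

    pairs: np.ndarray  # (n_pairs, 2) unit indices, i < j
    values: np.ndarray  # correlation per pair, NaN if undefined
    kind: str = "signal"

    @property
    def defined(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def mean(self) -> float:
        return float(np.mean(self.defined))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_i": self.pairs[:, 0],
                "unit_j": self.pairs[:, 1],
                "r_" + self.kind: self.values,
            }
        )


@dataclass
class FanoResult:
    """Mean-matched Fano factor for one condition with bootstrap bounds."""

    fano: float
    ci_low: float
    ci_high: float
    n_points_retained: float
    condition: str = ""

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "fano": self.fano,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_points_retained": self.n_points_retained,
        }


@dataclass
class DivergenceResult:
    """KL divergence between two population word distributions, in bits."""

    kl_value: float
    baseline: float | None = None
    shuffle_kl: float | None = None
    word_length: int = 0
    n_words_observed: int = 0

    def to_dict(self) -> dict:
        return {
            "kl_bits": self.kl_value,
            "baseline_bits": self.baseline,
            "shuffle_kl_bits": self.shuffle_kl,
            "word_length": self.word_length,
            "n_words_observed": self.n_words_observed,
        }


@dataclass
class TuningCurveResult:
    levels: np.ndarray
    means: np.ndarray  # units x levels
    half_width: np.ndarray  # per-unit HWHH in attribute units, NaN when undefined
    axis: str = "orientation"


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------

def _half_width_at_half_height(
    levels: np.ndarray, curve: np.ndarray, circular_period: float | None = 180.0
) -> float:
    """HWHH by linear interpolation around the peak.

    Half-height is min + (max - min) / 2.  For circular axes the curve is
    unwrapped around the peak.  Returns NaN when the curve is flat or never
    falls to half height on either side.
    """
    levels = np.asarray(levels, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if np.ptp(curve) <= 0:
        return np.nan
    j = int(np.argmax(curve))
    half = curve.min() + 0.5 * (curve.max() - curve.min())
    if circular_period is not None:
        p = circular_period
        rel = ((levels - levels[j] + p / 2.0) % p) - p / 2.0
    else:
        rel = levels - levels[j]
    order = np.argsort(rel)
    xs, ys = rel[order], curve[order]
    peak_pos = int(np.where(xs == 0.0)[0][0])

    def _walk(step: int) -> float:
        px, py = 0.0, ys[peak_pos]
        i = peak_pos + step
        while 0 <= i < xs.size:
            x, y = xs[i], ys[i]
            if y <= half:
                frac = (py - half) / (py - y) if py != y else 1.0
                return abs(px) + frac * abs(x - px)
            px, py = x, y
            i += step
        return np.nan

    widths = [_walk(-1), _walk(+1)]
    if np.all(np.isnan(widths)):
        return np.nan
    return float(np.nanmean(widths))


def tuning_curve(
    ensemble: TrialEnsemble, axis: str = "orientation",
    circular_period: float | None = 180.0,
) -> TuningCurveResult:
    """Trial-mean response per (unit, attribute level) with HWHH per unit."""
    if ensemble.stimulus_labels is None or axis not in ensemble.stimulus_labels:
        raise InvalidSpecificationError("attribute %r missing from labels" % axis)
    vals = ensemble.stimulus_labels[axis].to_numpy()
    levels = np.unique(vals)
    means = np.stack(
        [
            ensemble.responses[:, vals == lv, :].mean(axis=(1, 2))
            for lv in levels
        ],
        axis=1,
    )
    if levels.size < 2:
        hw = np.full(ensemble.n_units, np.nan)
    else:
        hw = np.array(
            [
                _half_width_at_half_height(levels, means[i], circular_period)
                for i in range(ensemble.n_units)
            ]
        )
    return TuningCurveResult(levels=levels, means=means, half_width=hw, axis=axis)


# ---------------------------------------------------------------------------
# Fano factors
# ---------------------------------------------------------------------------

def fano_factor(counts: np.ndarray) -> np.ndarray:
    """Across-trial variance / mean per unit; NaN where the mean is zero."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[1] < 2:
        raise InsufficientDataError("need at least 2 trials")
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    out = np.full(mean.shape, np.nan)
    nz = mean > 0
    out[nz] = var[nz] / mean[nz]
    return out


def _condition_points(ensemble: TrialEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Pool (unit, stimulus) points: mean count and Fano per point."""
    resp = ensemble.responses.astype(float)
    mean = resp.mean(axis=2).ravel()
    var = resp.var(axis=2, ddof=1).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        fano = np.where(mean > 0, var / mean, np.nan)
    keep = np.isfinite(fano)
    return mean[keep], fano[keep]


def mean_matched_fano(
    *ensembles: TrialEnsemble,
    n_mean_bins: int = 10,
    n_resamples: int = 50,
    seed: int = 0,
    conditions: list[str] | None = None,
) -> list[FanoResult]:
    """Mean-matched Fano factors across two or more conditions.

    Greedy histogram equalization: pool the per-(unit, stimulus) mean counts
    of all conditions, bin them into ``n_mean_bins`` common bins, and in
    each bin randomly discard points from every condition down to the
    smallest per-condition occupancy, so the retained mean-count histograms
    are identical across conditions by construction.  The condition Fano is
    the average Fano of retained points; the whole matching is repeated
    ``n_resamples`` times and the spread across repeats gives the bootstrap
    interval.
    """
    if len(ensembles) == 1 and isinstance(ensembles[0], (list, tuple)):
        ensembles = tuple(ensembles[0])
    if len(ensembles) < 2:
        raise InvalidSpecificationError("need at least two conditions")
    pts = [_condition_points(e) for e in ensembles]
    all_means = np.concatenate([m for m, _ in pts])
    if all_means.size == 0:
        raise InsufficientDataError("no defined Fano points in any condition")
    edges = np.histogram_bin_edges(all_means, bins=n_mean_bins)
    edges[-1] += 1e-9
    bins = [np.clip(np.digitize(m, edges) - 1, 0, n_mean_bins - 1) for m, _ in pts]
    occupancy = np.stack(
        [np.bincount(b, minlength=n_mean_bins) for b in bins]
    )  # condition x bin
    target = occupancy.min(axis=0)
    if target.sum() == 0:
        raise InsufficientDataError("mean-count distributions do not overlap")

    rng = np.random.default_rng(seed)
    per_cond = [[] for _ in ensembles]
    retained = [[] for _ in ensembles]
    for _ in range(n_resamples):
        for c, ((m, f), b) in enumerate(zip(pts, bins)):
            keep_vals = []
            kept = 0
            for k in range(n_mean_bins):
                idx = np.where(b == k)[0]
                if target[k] == 0 or idx.size == 0:
                    continue
                sel = rng.choice(idx, size=target[k], replace=False)
                keep_vals.append(f[sel])
                kept += sel.size
            per_cond[c].append(np.mean(np.concatenate(keep_vals)))
            retained[c].append(kept)
    names = conditions or [str(i) for i in range(len(ensembles))]
    results = []
    for c, name in enumerate(names):
        vals = np.array(per_cond[c])
        results.append(
            FanoResult(
                fano=float(vals.mean()),
                ci_low=float(np.percentile(vals, 2.5)),
                ci_high=float(np.percentile(vals, 97.5)),
                n_points_retained=float(np.mean(retained[c])),
                condition=name,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _pairwise_pearson(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle Pearson correlations of rows; NaN for zero-variance rows."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    sd = matrix.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    iu, ju = np.triu_indices(n, k=1)
    return np.column_stack([iu, ju]), corr[iu, ju]


def signal_correlations(ensemble: TrialEnsemble) -> CorrelationResult:
    """Per-pair Pearson correlation of trial-mean responses across stimuli."""
    if ensemble.n_stimuli < 3:
        raise InsufficientDataError("need at least 3 stimuli")
    pairs, values = _pairwise_pearson(ensemble.trial_means())
    return CorrelationResult(pairs=pairs, values=values, kind="sign")


def noise_correlations(ensemble: TrialEnsemble) -> CorrelationResult:
    """Across-trial fluctuation correlations, averaged over stimuli.

    Per stimulus the trial mean is removed, pairwise Pearson correlations
    of the residuals are computed, and the per-pair values are averaged
    over stimuli (ignoring stimuli where a unit has zero residual variance).
    """
    if ensemble.n_trials < 2:
        raise InsufficientDataError("need at least 2 trials per stimulus")
    acc = []
    for s in range(ensemble.n_stimuli):
        resid = ensemble.responses[:, s, :].astype(float)
        resid = resid - resid.mean(axis=1, keepdims=True)
        pairs, values = _pairwise_pearson(resid)
        acc.append(values)
    stacked = np.stack(acc)
    finite = np.isfinite(stacked)
    cnt = finite.sum(axis=0)
    total = np.where(finite, stacked, 0.0).sum(axis=0)
    avg = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    return CorrelationResult(pairs=pairs, values=avg, kind="noise")


def spontaneous_correlations(blank_ensemble: TrialEnsemble) -> CorrelationResult:
    """Noise correlations of blank-stimulus (spontaneous) activity."""
    res = noise_correlations(blank_ensemble)
    return CorrelationResult(pairs=res.pairs, values=res.values, kind="spont")


# ---------------------------------------------------------------------------
# Sparseness, reliability, separation
# ---------------------------------------------------------------------------

def lifetime_sparseness(mean_rates: np.ndarray) -> np.ndarray:
    """Activity-ratio sparseness S = (1 - A) / (1 - 1/n), A = mean^2 / mean-square.

    0 for a unit responding uniformly across stimuli, 1 for a one-hot
    responder; scale-invariant.  NaN for all-zero units.
    """
    r = np.atleast_2d(np.asarray(mean_rates, dtype=float))
    if r.shape[1] < 2:
        raise InsufficientDataError("need at least 2 stimuli")
    if np.any(r < 0):
        raise InvalidSpecificationError("rates must be nonnegative")
    n = r.shape[1]
    sum_r = r.sum(axis=1)
    sum_r2 = (r**2).sum(axis=1)
    out = np.full(r.shape[0], np.nan)
    nz = sum_r2 > 0
    a = (sum_r[nz] / n) ** 2 / (sum_r2[nz] / n)
    out[nz] = (1.0 - a) / (1.0 - 1.0 / n)
    return out


def response_reliability(traces: np.ndarray) -> float:
    """Mean pairwise across-trial Pearson correlation of a trials x time trace."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_trials = traces.shape[0]
    if n_trials < 2:
        raise InsufficientDataError("need at least 2 trials")
    sd = traces.std(axis=1)
    if np.any(sd == 0):
        return np.nan
    corr = np.corrcoef(traces)
    iu, ju = np.triu_indices(n_trials, k=1)
    return float(np.mean(corr[iu, ju]))


def separation_angle(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Angle between two mean response vectors, degrees in [0, 180]."""
    a = np.asarray(vec_a, dtype=float).ravel()
    b = np.asarray(vec_b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Population words and KL divergence
# ---------------------------------------------------------------------------

def word_distribution(
    binary: np.ndarray,
    unit_subset: np.ndarray | list | None = None,
    pseudo_count: float = 1.0,
) -> np.ndarray:
    """Probability table over joint on/off words of a unit subset.

    ``binary`` is units x time-bins (nonzero = "on").  Words are indexed
    with unit_subset[0] as the most significant bit.  ``pseudo_count`` is
    added to every word before normalization.
    """
    binary = (np.atleast_2d(np.asarray(binary)) != 0).astype(np.int64)
    if unit_subset is None:
        unit_subset = np.arange(binary.shape[0])
    unit_subset = np.asarray(unit_subset)
    k = unit_subset.size
    if k > 16:
        raise InvalidSpecificationError("word length > 16 is intractable here")
    sub = binary[unit_subset]
    weights = 1 << np.arange(k - 1, -1, -1)
    words = weights @ sub
    table = np.bincount(words, minlength=1 << k).astype(float) + pseudo_count
    return table / table.sum()


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Sum P log2(P / Q) in bits, with 0 * log(0/q) = 0."""
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.shape != Q.shape:
        raise InvalidSpecificationError("P and Q must share support")
    if np.any((P > 0) & (Q <= 0)):
        raise InvalidSpecificationError("Q must be positive wherever P is")
    nz = P > 0
    return float(np.sum(P[nz] * np.log2(P[nz] / Q[nz])))


def shuffle_across_units(
    spike_trains: np.ndarray, seed: int = 0, mode: str = "shift"
) -> np.ndarray:
    """Destroy cross-unit correlations while preserving per-unit marginals.

    Each unit's time series is independently circularly shifted
    (``mode="shift"``) or permuted (``mode="permute"``) in time.
    """
    trains = np.atleast_2d(np.asarray(spike_trains))
    if trains.shape[1] < 2:
        raise InvalidSpecificationError("need at least 2 time bins")
    rng = np.random.default_rng(seed)
    out = np.empty_like(trains)
    for i in range(trains.shape[0]):
        if mode == "shift":
            out[i] = np.roll(trains[i], rng.integers(1, trains.shape[1]))
        elif mode == "permute":
            out[i] = trains[i, rng.permutation(trains.shape[1])]
        else:
            raise InvalidSpecificationError("mode must be 'shift' or 'permute'")
    return out


def split_half_baseline(
    activity: np.ndarray,
    seed: int = 0,
    unit_subset=None,
    pseudo_count: float = 1.0,
) -> float:
    """KL between word distributions of two random disjoint halves of the bins.

    The finite-sample floor: the divergence one expects between two samples
    of the same process at this data size.
    """
    activity = np.atleast_2d(np.asarray(activity))
    n_bins = activity.shape[1]
    if n_bins < 4:
        raise InsufficientDataError("need at least 4 time bins")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_bins)
    half = n_bins // 2
    a, b = activity[:, perm[:half]], activity[:, perm[half : 2 * half]]
    return kl_divergence(
        word_distribution(a, unit_subset, pseudo_count),
        word_distribution(b, unit_subset, pseudo_count),
    )


# ---------------------------------------------------------------------------
# Bootstrap helpers (significance for directional comparisons)
# ---------------------------------------------------------------------------

def bootstrap_mean_ci(
    values: np.ndarray, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """Percentile bootstrap mean and CI for a 1-D sample (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    rng = np.random.default_rng(seed)
    boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(v.mean()), float(lo), float(hi)


def paired_bootstrap_pvalue(
    a: np.ndarray, b: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> float:
    """One-sided p-value that mean(a - b) <= 0 by percentile bootstrap.

    Resamples paired differences; p is the fraction of bootstrap means that
    are not positive (clipped below at 1 / n_boot).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    d = (a - b)[keep]
    if d.size < 2:
        raise InsufficientDataError("need at least 2 paired observations")
    rng = np.random.default_rng(seed)
    boots = rng.choice(d, size=(n_boot, d.size), replace=True).mean(axis=1)
    p = np.mean(boots <= 0.0)
    return float(max(p, 1.0 / n_boot))
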