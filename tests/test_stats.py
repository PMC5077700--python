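"""Analysis statistics: Fano factors, mean matching, correlations, sparseness,
reliability, word distributions, KL divergence and controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1sampling import stats as vstats
from v1sampling.stats import (
    InsufficientDataError,
    TrialEnsemble,
    fano_factor,
    kl_divergence,
    lifetime_sparseness,
    mean_matched_fano,
    noise_correlations,
    response_reliability,
    separation_angle,
    shuffle_across_units,
    signal_correlations,
    split_half_baseline,
    spontaneous_correlations,
    tuning_curve,
    word_distribution,
)


class TestTuningCurve:
    def _cosine_ensemble(self, preferred, n_trials=40, seed=0):
        rng = np.random.default_rng(seed)
        oris = np.arange(12) * 15.0
        means = 5.0 + 4.0 * np.cos(2 * np.deg2rad(oris[None, :] - preferred[:, None]))
        counts = rng.poisson(means[:, :, None], size=(*means.shape, n_trials))
        import pandas as pd

        labels = pd.DataFrame({"orientation": oris})
        return TrialEnsemble(counts, stimulus_labels=labels), oris

    def test_recovers_generating_preferred_orientation(self):
        preferred = np.array([0.0, 45.0, 90.0, 135.0])
        ens, oris = self._cosine_ensemble(preferred)
        tc = tuning_curve(ens, "orientation")
        peaks = tc.levels[np.argmax(tc.means, axis=1)]
        d = np.abs(peaks - preferred) % 180
        assert np.all(np.minimum(d, 180 - d) <= 15.0)

    def test_means_equal_direct_average(self):
        ens, _ = self._cosine_ensemble(np.array([30.0]))
        tc = tuning_curve(ens, "orientation")
        assert np.allclose(tc.means, ens.responses.mean(axis=2))

    def test_flat_curve_flagged_undefined(self):
        import pandas as pd

        counts = np.full((2, 6, 10), 3)
        labels = pd.DataFrame({"orientation": np.arange(6) * 30.0})
        tc = tuning_curve(TrialEnsemble(counts, stimulus_labels=labels),
                          "orientation")
        assert np.all(np.isnan(tc.half_width))

    def test_missing_attribute_rejected(self):
        ens, _ = self._cosine_ensemble(np.array([0.0]))
        with pytest.raises(Exception):
            tuning_curve(ens, "contrast")


class TestFanoFactor:
    def test_poisson_counts_near_one(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4.0, size=(5, 10_000))
        assert np.all(np.abs(fano_factor(counts) - 1.0) < 0.05)

    def test_identical_counts_zero(self):
        counts = np.full((3, 20), 7)
        assert np.all(fano_factor(counts) == 0.0)

    def test_doubling_counts_doubles_fano(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3.0, size=(4, 500))
        assert np.allclose(fano_factor(2 * counts), 2 * fano_factor(counts))

    def test_zero_mean_flagged_not_zero(self):
        counts = np.zeros((2, 10), dtype=int)
        assert np.all(np.isnan(fano_factor(counts)))

    def test_single_trial_rejected(self):
        with pytest.raises(InsufficientDataError):
            fano_factor(np.ones((3, 1)))


class TestMeanMatchedFano:
    def test_identical_conditions_identical_fano(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=(30, 1, 100))
        a = TrialEnsemble(counts)
        b = TrialEnsemble(counts.copy())
        ra, rb = mean_matched_fano(a, b, seed=0)
        assert np.isclose(ra.fano, rb.fano, rtol=0.02)

    def test_poisson_populations_matched_fano_one(self):
        rng = np.random.default_rng(4)
        rates_a = rng.uniform(1, 6, size=30)
        rates_b = rng.uniform(3, 10, size=30)
        a = TrialEnsemble(rng.poisson(rates_a[:, None, None], (30, 1, 10_000)))
        b = TrialEnsemble(rng.poisson(rates_b[:, None, None], (30, 1, 10_000)))
        ra, rb = mean_matched_fano(a, b, seed=1)
        assert abs(ra.fano - 1.0) < 0.05
        assert abs(rb.fano - 1.0) < 0.05

    def test_out_of_support_point_discarded(self):
        # hand enumeration: A holds points with means {2.5, 3.5} (both in the
        # lowest mean bin), B holds {2.5, 20}.  The bin with mean 20 has no A
        # mass -> B's high point drops; the low bin target is min(2, 1) = 1,
        # so A also retains exactly one point there.
        a_counts = np.array([[2, 3, 2, 3], [3, 4, 3, 4]])[:, None, :]
        b_counts = np.array([[2, 3, 2, 3], [19, 21, 19, 21]])[:, None, :]
        ra, rb = mean_matched_fano(
            TrialEnsemble(a_counts), TrialEnsemble(b_counts),
            n_mean_bins=5, n_resamples=3, seed=0,
        )
        assert ra.n_points_retained == 1.0
        assert rb.n_points_retained == 1.0
        # B's retained point can only be the in-support (mean 2.5) one,
        # whose Fano is var/mean = (1/3)/2.5
        assert np.isclose(rb.fano, (1.0 / 3.0) / 2.5)

    def test_disjoint_supports_rejected(self):
        a = TrialEnsemble(np.array([[1, 2, 1, 2]])[:, None, :])
        b = TrialEnsemble(np.array([[30, 31, 30, 31]])[:, None, :])
        with pytest.raises(InsufficientDataError):
            mean_matched_fano(a, b, n_mean_bins=10, seed=0)


class TestCorrelations:
    def test_duplicated_unit_signal_correlation_one(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(5.0, size=(1, 20, 30))
        ens = TrialEnsemble(np.concatenate([base, base], axis=0))
        res = signal_correlations(ens)
        assert np.isclose(res.values[0], 1.0)

    def test_anticorrelated_units(self):
        means = np.arange(1, 21, dtype=float)
        resp = np.stack([means, means[::-1]])[:, :, None] * np.ones((1, 1, 5))
        ens = TrialEnsemble(resp.astype(int))
        res = signal_correlations(ens)
        assert res.values[0] < -0.99

    def test_independent_units_near_zero(self):
        rng = np.random.default_rng(6)
        ens = TrialEnsemble(rng.poisson(5.0, size=(20, 100, 10)))
        res = signal_correlations(ens)
        assert np.nanmean(np.abs(res.values)) < 0.15

    def test_trial_shuffling_destroys_noise_correlation(self):
        rng = np.random.default_rng(7)
        shared = rng.normal(0, 2.0, size=(1, 5, 400))
        counts = np.clip(np.round(rng.normal(8, 1, (10, 5, 400)) + shared), 0,
                         None).astype(int)
        ens = TrialEnsemble(counts)
        before = np.nanmean(noise_correlations(ens).values)
        shuffled = counts.copy()
        for u in range(10):
            for s in range(5):
                shuffled[u, s] = rng.permutation(shuffled[u, s])
        after = np.nanmean(noise_correlations(TrialEnsemble(shuffled)).values)
        assert before > 0.2
        assert abs(after) < 0.02

    def test_single_stimulus_equals_plain_correlation(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(6.0, size=(4, 1, 200))
        res = noise_correlations(TrialEnsemble(counts))
        direct = np.corrcoef(counts[:, 0, :])
        iu, ju = np.triu_indices(4, k=1)
        assert np.allclose(res.values, direct[iu, ju])

    def test_spontaneous_matches_prior_pushforward(
        self, default_model, default_solver, enc
    ):
        """Blank-stimulus count correlations align with the prior's
        correlation structure pushed through the encoding chain (the
        default model's prior has graded correlations to align with)."""
        from v1sampling import simulate_trials
        from v1sampling.stimuli import blank

        sim = simulate_trials(default_model, enc,
                              blank(default_model.patch_side),
                              1000, seed=9, solver=default_solver)
        res = spontaneous_correlations(TrialEnsemble(sim.counts.counts))
        n = default_model.n_units
        iu, ju = np.triu_indices(n, k=1)
        d = np.sqrt(np.diag(default_model.prior_cov))
        prior_corr = (default_model.prior_cov / np.outer(d, d))[iu, ju]
        keep = np.isfinite(res.values)
        assert np.corrcoef(res.values[keep], prior_corr[keep])[0, 1] > 0.5


class TestSparsenessReliabilityAngle:
    def test_one_hot_sparseness_one(self):
        r = np.zeros((1, 8))
        r[0, 3] = 5.0
        assert np.isclose(lifetime_sparseness(r)[0], 1.0)

    def test_uniform_sparseness_zero(self):
        assert np.isclose(lifetime_sparseness(np.full((1, 8), 2.0))[0], 0.0)

    def test_half_active_closed_form(self):
        s = lifetime_sparseness(np.array([[1.0, 1.0, 0.0, 0.0]]))[0]
        assert np.isclose(s, 2.0 / 3.0)

    def test_scale_invariance(self):
        r = np.array([[0.5, 2.0, 0.0, 4.0]])
        assert np.isclose(lifetime_sparseness(r)[0],
                          lifetime_sparseness(10 * r)[0])

    def test_all_zero_flagged(self):
        assert np.isnan(lifetime_sparseness(np.zeros((1, 5)))[0])

    def test_identical_trials_reliability_one(self):
        trace = np.tile(np.sin(np.linspace(0, 6, 100)), (5, 1))
        assert np.isclose(response_reliability(trace), 1.0)

    def test_negated_trial_reliability_minus_one(self):
        t = np.sin(np.linspace(0, 6, 100))
        assert np.isclose(response_reliability(np.stack([t, -t])), -1.0)

    def test_independent_noise_reliability_near_zero(self):
        rng = np.random.default_rng(10)
        traces = rng.standard_normal((20, 1000))
        assert abs(response_reliability(traces)) < 0.05

    @pytest.mark.parametrize(
        "a, b, expected",
        [([1, 0], [1, 0], 0.0), ([1, 0], [0, 1], 90.0), ([1, 0], [1, 1], 45.0)],
    )
    def test_separation_angle_closed_form(self, a, b, expected):
        assert np.isclose(separation_angle(a, b), expected)

    def test_zero_vector_flagged(self):
        assert np.isnan(separation_angle([0, 0], [1, 0]))


class TestWordsAndKL:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(11)
        binary = rng.integers(0, 2, size=(6, 500))
        assert np.isclose(word_distribution(binary, pseudo_count=1.0).sum(), 1.0)

    def test_all_silent_point_mass(self):
        table = word_distribution(np.zeros((4, 100), int), pseudo_count=0.0)
        assert table[0] == 1.0
        assert np.all(table[1:] == 0.0)

    def test_independent_units_product_law(self):
        rng = np.random.default_rng(12)
        binary = (rng.random((2, 10_000)) < 0.5).astype(int)
        table = word_distribution(binary, pseudo_count=0.0)
        assert np.all(np.abs(table - 0.25) < 0.02)

    def test_kl_zero_iff_equal(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_kl_closed_form(self):
        got = kl_divergence([0.75, 0.25], [0.5, 0.5])
        assert np.isclose(got, 0.18872, atol=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_kl_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8)) + 1e-9
        q /= q.sum()
        assert kl_divergence(p, q) >= 0.0

    def test_mismatched_support_rejected(self):
        with pytest.raises(Exception):
            kl_divergence([0.5, 0.5], [0.2, 0.3, 0.5])


class TestShuffleAndSplitHalf:
    def test_per_unit_marginals_preserved_exactly(self):
        rng = np.random.default_rng(13)
        trains = rng.poisson(1.0, size=(8, 300))
        for mode in ("shift", "permute"):
            shuffled = shuffle_across_units(trains, seed=1, mode=mode)
            assert np.array_equal(np.sort(shuffled, axis=1),
                                  np.sort(trains, axis=1))

    def test_correlated_pair_decorrelated(self):
        rng = np.random.default_rng(14)
        shared = (rng.random(4000) < 0.4).astype(int)
        trains = np.stack([shared, shared])
        shuffled = shuffle_across_units(trains, seed=2, mode="permute")
        assert np.corrcoef(trains)[0, 1] > 0.99
        assert abs(np.corrcoef(shuffled)[0, 1]) < 0.05

    def test_seed_determinism(self):
        rng = np.random.default_rng(15)
        trains = rng.poisson(1.0, size=(4, 100))
        a = shuffle_across_units(trains, seed=3)
        b = shuffle_across_units(trains, seed=3)
        assert np.array_equal(a, b)

    def test_trial_ensemble_roundtrips(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(20)
        labels = pd.DataFrame({"orientation": [0.0, 45.0, 90.0]})
        ens = TrialEnsemble(rng.poisson(3.0, (4, 3, 5)),
                            stimulus_labels=labels)
        back = TrialEnsemble.from_frame(ens.to_frame())
        assert np.array_equal(back.responses, ens.responses)
        path = tmp_path / "ens.h5"
        ens.to_hdf5(path)
        back2 = TrialEnsemble.from_hdf5(path)
        assert np.array_equal(back2.responses, ens.responses)
        assert np.allclose(back2.stimulus_labels["orientation"],
                           labels["orientation"])

    def test_baseline_decreases_with_data(self):
        rng = np.random.default_rng(16)
        small = (rng.random((6, 1000)) < 0.2).astype(int)
        large = (rng.random((6, 100_000)) < 0.2).astype(int)
        b_small = np.median(
            [split_half_baseline(small, seed=s) for s in range(5)]
        )
        b_large = np.median(
            [split_half_baseline(large, seed=s) for s in range(5)]
        )
        assert b_large < b_small
        assert b_large < 0.01
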