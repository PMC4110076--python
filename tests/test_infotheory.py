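"""Mutual information: equipopulated binning, plugin estimator against a
direct-summation oracle, bias corrections and the spectrum wrapper."""

import numpy as np
import pytest

from ctcsim.infotheory import (
    PowerSampleSet,
    bias_correct,
    discretize,
    equipopulated_bins,
    mi_spectrum,
    plugin_mi,
    pt_bias,
)


def mi_from_joint(p_sr):
    """Oracle: direct summation of Eq. I = sum p(s,r) log2 p(s,r)/(p(s)p(r))."""
    p_sr = np.asarray(p_sr, float)
    p_s = p_sr.sum(axis=1, keepdims=True)
    p_r = p_sr.sum(axis=0, keepdims=True)
    out = 0.0
    for s in range(p_sr.shape[0]):
        for r in range(p_sr.shape[1]):
            if p_sr[s, r] > 0:
                out += p_sr[s, r] * np.log2(p_sr[s, r] / (p_s[s, 0] * p_r[0, r]))
    return out


class TestBinning:
    def test_uniform_sample_equal_counts(self):
        rng = np.random.default_rng(0)
        v = rng.random(600)
        edges = equipopulated_bins(v, 6)
        b = discretize(v, edges)
        counts = np.bincount(b, minlength=6)
        assert np.all(np.abs(counts - 100) <= 1)

    def test_single_bin_gives_zero_mi(self):
        rng = np.random.default_rng(1)
        per_stim = [rng.random(30) for _ in range(4)]
        edges = equipopulated_bins(np.concatenate(per_stim), 1)
        assert len(edges) == 0
        binned = [discretize(v, edges) for v in per_stim]
        assert plugin_mi(binned, 1) == 0.0

    def test_all_identical_values_degrade_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            edges = equipopulated_bins(np.ones(100), 6)
        assert len(edges) < 5
        assert "ties" in caplog.text

    def test_monotone_transform_invariance(self):
        """Rank-based binning makes the MI invariant under any monotone map."""
        rng = np.random.default_rng(2)
        per_stim = [rng.lognormal(s * 0.5, 1.0, 40) for s in range(4)]
        pooled = np.concatenate(per_stim)
        b1 = [discretize(v, equipopulated_bins(pooled, 6)) for v in per_stim]
        trans = [np.log(v) * 3 + 2 for v in per_stim]
        b2 = [discretize(v, equipopulated_bins(np.concatenate(trans), 6)) for v in trans]
        assert plugin_mi(b1, 6) == pytest.approx(plugin_mi(b2, 6), abs=1e-12)


class TestPluginMI:
    def test_identical_distributions_zero_information(self):
        b = [np.array([0, 1, 2, 3, 4, 5])] * 7
        assert plugin_mi(b, 6) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_deterministic_channel_log2_s(self):
        b = [np.full(10, s) for s in range(7)]
        assert plugin_mi(b, 7) == pytest.approx(np.log2(7), rel=1e-12)

    def test_matches_direct_summation_oracle(self):
        # a small printed joint table over 3 stimuli x 4 response bins
        joint = np.array(
            [
                [4, 2, 1, 1],
                [1, 5, 1, 1],
                [1, 1, 3, 3],
            ],
            float,
        )
        binned = [np.repeat(np.arange(4), row.astype(int)) for row in joint]
        # plugin_mi uses uniform P(s); the joint oracle gets matching masses
        p_sr = joint / joint.sum(axis=1, keepdims=True) / 3.0
        assert plugin_mi(binned, 4) == pytest.approx(mi_from_joint(p_sr), rel=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            b = [rng.integers(0, 6, 25) for _ in range(7)]
            i = plugin_mi(b, 6)
            assert 0.0 <= i <= np.log2(6) + 1e-12

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            plugin_mi([np.array([0, 1]), np.array([], dtype=int)], 2)


class TestBiasCorrection:
    def test_independent_channel_corrected_to_zero(self):
        rng = np.random.default_rng(4)
        per_stim = [rng.standard_normal(50) for _ in range(7)]
        edges = equipopulated_bins(np.concatenate(per_stim), 6)
        binned = [discretize(v, edges) for v in per_stim]
        res = bias_correct(binned, 6, n_bootstrap=200, seed=0)
        assert res["i_raw"] > 0  # plugin bias is positive
        assert abs(res["i_corrected_signed"]) < 2 * res["null_std"] + 0.02
        assert not res["significant"]

    def test_shuffled_pairing_corrected_to_zero(self):
        rng = np.random.default_rng(5)
        # a genuinely informative channel ...
        per_stim = [rng.normal(0.6 * s, 1.0, 40) for s in range(5)]
        pooled = np.concatenate(per_stim)
        # ... destroyed by shuffling the stimulus assignment
        rng.shuffle(pooled)
        shuffled = np.split(pooled, 5)
        edges = equipopulated_bins(pooled, 6)
        binned = [discretize(v, edges) for v in shuffled]
        res = bias_correct(binned, 6, n_bootstrap=200, seed=1)
        assert abs(res["i_corrected_signed"]) < 3 * res["null_std"] + 0.02

    def test_large_n_converges_to_construction(self):
        """Corrected and raw estimates converge to the analytic MI of a fixed
        discrete channel as the trial count grows."""
        rng = np.random.default_rng(6)
        # binary symmetric-ish channel: 2 stimuli, response bins with overlap
        p_hit = 0.85
        analytic = mi_from_joint(
            np.array([[p_hit / 2, (1 - p_hit) / 2], [(1 - p_hit) / 2, p_hit / 2]])
        )
        for n, tol in ((100, 0.1), (2000, 0.02)):
            b = []
            for s in range(2):
                hits = rng.random(n) < p_hit
                b.append(np.where(hits, s, 1 - s))
            res = bias_correct(b, 2, n_bootstrap=100, seed=2)
            assert res["i_corrected"] == pytest.approx(analytic, abs=tol)

    def test_pt_bias_positive_and_shrinks_with_n(self):
        rng = np.random.default_rng(7)
        small = [rng.integers(0, 6, 20) for _ in range(5)]
        large = [rng.integers(0, 6, 500) for _ in range(5)]
        assert pt_bias(small, 6) > pt_bias(large, 6) > 0

    def test_undersampled_flag(self):
        rng = np.random.default_rng(8)
        b = [rng.integers(0, 6, 5) for _ in range(7)]
        res = bias_correct(b, 6, n_bootstrap=20, seed=0)
        assert res["undersampled"]


class TestMISpectrum:
    def _sample_set(self, effect, n_trials=30, n_freqs=12, seed=9):
        rng = np.random.default_rng(seed)
        samples = []
        for s in range(7):
            base = rng.standard_normal((n_trials, n_freqs))
            base[:, 5] += effect * s  # only frequency index 5 is informative
            samples.append(base)
        return PowerSampleSet(freqs=np.arange(n_freqs, dtype=float), samples=samples)

    def test_frequency_localized_channel(self):
        ps = self._sample_set(effect=1.2)
        mi = mi_spectrum(ps, n_bins=6, n_bootstrap=100, seed=0)
        assert mi.significant[5]
        assert np.argmax(mi.i_corrected) == 5
        others = np.delete(np.arange(12), 5)
        assert mi.i_corrected[5] > 3 * mi.i_corrected[others].max() - 0.05

    def test_null_spectrum_false_positive_rate(self):
        ps = self._sample_set(effect=0.0, n_freqs=40)
        mi = mi_spectrum(ps, n_bins=6, n_bootstrap=100, seed=1)
        assert mi.significant.mean() <= 0.125  # ~5% nominal plus sampling slack

    def test_single_trial_per_stimulus_rejected(self):
        with pytest.raises(ValueError):
            PowerSampleSet(
                freqs=np.arange(3.0), samples=[np.ones((1, 3)), np.ones((4, 3))]
            )

    def test_upper_bound_respected(self):
        ps = self._sample_set(effect=50.0)  # perfectly separable at index 5
        mi = mi_spectrum(ps, n_bins=6, n_bootstrap=50, seed=2)
        assert np.all(mi.i_corrected <= np.log2(6) + 1e-9)
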