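"""Spectral estimators: Welch PSD, phase coherence (with brute-force DFT
oracle), time-shift conversion, thresholding and peak tracking."""

import numpy as np
import pytest

from ctcsim.spectral import (
    CoherenceResult,
    PSDResult,
    chance_level,
    coherence_threshold,
    phase_coherence,
    time_shift,
    track_peaks,
    welch_psd,
)


def brute_force_phase_coherence(xs, ys, nperseg, noverlap):
    """Independent oracle: per-segment DFTs computed by explicit summation
    over the DFT definition, phasors averaged directly."""
    step = nperseg - noverlap
    win = np.hamming(nperseg)
    n_freq = nperseg // 2 + 1
    acc = np.zeros(n_freq, complex)
    count = np.zeros(n_freq)
    t = np.arange(nperseg)
    for x, y in zip(xs, ys):
        n_seg = 1 + (len(x) - nperseg) // step
        for k in range(n_seg):
            sx = x[k * step : k * step + nperseg]
            sy = y[k * step : k * step + nperseg]
            sx = (sx - sx.mean()) * win
            sy = (sy - sy.mean()) * win
            for j in range(n_freq):
                e = np.exp(-2j * np.pi * j * t / nperseg)
                X = np.sum(sx * e)
                Y = np.sum(sy * e)
                s = X * np.conj(Y)
                if abs(s) > 0:
                    acc[j] += s / abs(s)
                    count[j] += 1
    count = np.maximum(count, 1)
    return np.abs(acc / count), np.angle(acc / count)


class TestWelch:
    def test_sinusoid_peak_at_line_frequency(self):
        fs, f0 = 1000.0, 57.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        psd = welch_psd(x, fs=fs, nperseg=1000)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(f0, abs=0.5)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(0)
        trials = [rng.standard_normal(8000) for _ in range(25)]
        psd = welch_psd(trials, fs=1000.0, nperseg=500)
        sel = (psd.freqs > 20) & (psd.freqs < 480)
        p = psd.power[sel]
        # chi^2 averaging over ~375 periodograms: relative s.e. ~ 1/sqrt(n)
        se = p.mean() / np.sqrt(psd.n_segments)
        assert np.all(np.abs(p - p.mean()) < 5 * se)

    def test_parseval_total_power(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20000)
        psd = welch_psd(x, fs=1000.0, nperseg=1000)
        integral = np.trapezoid(psd.power, psd.freqs)
        assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), fs=1000.0, nperseg=1000)


class TestPhaseCoherence:
    def test_identical_signals_unit_coherence(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(3000)
        res = phase_coherence(x, x.copy(), fs=1000.0, nperseg=500)
        power_sel = slice(1, None)  # skip DC
        np.testing.assert_allclose(res.coherence[power_sel], 1.0, atol=1e-12)
        np.testing.assert_allclose(res.phase[power_sel], 0.0, atol=1e-12)

    def test_matches_bruteforce_dft_oracle(self):
        rng = np.random.default_rng(3)
        xs = [rng.standard_normal(700) for _ in range(3)]
        ys = [rng.standard_normal(700) for _ in range(3)]
        res = phase_coherence(xs, ys, fs=1000.0, nperseg=256, overlap=0.5)
        c_bf, ph_bf = brute_force_phase_coherence(xs, ys, 256, 128)
        np.testing.assert_allclose(res.coherence, c_bf, atol=1e-10)
        np.testing.assert_allclose(
            np.exp(1j * res.phase), np.exp(1j * ph_bf), atol=1e-10
        )

    def test_delayed_copy_gives_phase_ramp(self):
        fs, d_ms = 1000.0, 4.0
        rng = np.random.default_rng(4)
        # narrowband signal so the delayed copy stays within the window
        from scipy.signal import butter, filtfilt

        b, a = butter(4, [0.05, 0.25], btype="band")
        x = filtfilt(b, a, rng.standard_normal(12000))
        d = int(d_ms * fs / 1000)
        y = np.roll(x, d)[d:]
        x = x[d:]
        res = phase_coherence(x, y, fs=fs, nperseg=1000)
        sel = (res.freqs >= 40) & (res.freqs <= 100)
        expected = 2 * np.pi * res.freqs[sel] * d_ms / 1000.0
        assert np.all(res.coherence[sel] > 0.9)
        np.testing.assert_allclose(
            np.exp(1j * res.phase[sel]), np.exp(1j * expected), atol=0.05
        )
        # time shift recovers the delay: x leads y by d
        np.testing.assert_allclose(res.time_shift_ms[sel], d_ms, atol=0.2)

    def test_chance_level_for_independent_noise(self):
        rng = np.random.default_rng(5)
        cs = []
        K = 8
        for _ in range(60):
            x = rng.standard_normal(K * 256)
            y = rng.standard_normal(K * 256)
            res = phase_coherence(x, y, fs=1000.0, nperseg=256, overlap=0.0)
            cs.append(res.coherence[5:120])
        mean_c = np.mean(cs)
        assert mean_c == pytest.approx(chance_level(K), rel=0.05)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        r1 = phase_coherence(x, y, fs=1000.0, nperseg=500)
        r2 = phase_coherence(7.3 * x, 0.002 * y, fs=1000.0, nperseg=500)
        np.testing.assert_allclose(r1.coherence, r2.coherence, atol=1e-12)

    def test_needs_two_segments(self):
        with pytest.raises(ValueError):
            phase_coherence(np.zeros(500), np.zeros(500), fs=1000.0, nperseg=500)


class TestTimeShift:
    def test_zero_phase_zero_shift(self):
        assert time_shift(0.0, 40.0) == 0.0

    def test_antiphase_is_half_period(self):
        f = 40.0
        assert time_shift(np.pi, f) == pytest.approx(1000.0 / (2 * f))

    def test_wrap_just_above_pi(self):
        f = 50.0
        dphi = np.pi + 0.1
        shift = time_shift(dphi, f)
        expected = (dphi - 2 * np.pi) / (2 * np.pi * f) * 1000.0
        assert shift == pytest.approx(expected)
        assert shift < 0


class TestThresholdAndPeaks:
    def _coh(self, freqs, c):
        return CoherenceResult(
            freqs=freqs, coherence=c, phase=np.zeros_like(c),
            time_shift_ms=np.zeros_like(c), n_segments=10,
        )

    def test_four_times_baseline_rule(self):
        freqs = np.linspace(0, 100, 101)
        base = self._coh(freqs, np.full(101, 0.025))
        assert coherence_threshold(base, band=(30, 80)) == pytest.approx(0.1)

    def test_identical_signals_everywhere_significant(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(4000)
        res = phase_coherence(x, x.copy(), fs=1000.0, nperseg=500)
        res.threshold = 0.5
        assert np.all(res.significant[1:])

    def test_uncoupled_false_positive_rate(self):
        """With a threshold of 4x chance, independent signals are flagged
        significant in well under 5% of bins."""
        rng = np.random.default_rng(8)
        xs = [rng.standard_normal(4000) for _ in range(10)]
        ys = [rng.standard_normal(4000) for _ in range(10)]
        res = phase_coherence(xs, ys, fs=1000.0, nperseg=500)
        thr = 4 * res.coherence[(res.freqs >= 30) & (res.freqs <= 80)].mean()
        assert np.mean(res.coherence > thr) < 0.05

    def test_single_peak_recovered(self):
        freqs = np.linspace(0, 100, 101)
        power = 1.0 / (freqs + 5.0)
        power += 2.0 * np.exp(-0.5 * ((freqs - 47) / 3.0) ** 2) * power[47]
        psd = PSDResult(freqs=freqs, power=power, n_segments=10, window="hamming")
        c = 0.05 + 0.5 * np.exp(-0.5 * ((freqs - 47) / 3.0) ** 2)
        summary = track_peaks(psd, self._coh(freqs, c), band=(30, 80), threshold=0.2)
        assert summary.f_lfp == pytest.approx(47, abs=1)
        assert summary.f_coherence == [47.0]

    def test_two_bump_coherence_returns_both_in_order(self):
        freqs = np.linspace(0, 100, 101)
        power = np.exp(-0.5 * ((freqs - 50) / 8.0) ** 2) + 0.01
        psd = PSDResult(freqs=freqs, power=power, n_segments=10, window="hamming")
        c = (
            0.05
            + 0.5 * np.exp(-0.5 * ((freqs - 38) / 2.5) ** 2)
            + 0.4 * np.exp(-0.5 * ((freqs - 62) / 2.5) ** 2)
        )
        summary = track_peaks(psd, self._coh(freqs, c), band=(30, 80), threshold=0.2)
        assert summary.f_coherence == [38.0, 62.0]

    def test_subthreshold_coherence_gives_empty_list(self):
        freqs = np.linspace(0, 100, 101)
        psd = PSDResult(freqs=freqs, power=np.ones(101), n_segments=10, window="hamming")
        c = np.full(101, 0.05)
        summary = track_peaks(psd, self._coh(freqs, c), band=(30, 80), threshold=0.3)
        assert summary.f_coherence == []
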