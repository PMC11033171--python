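"""Multitaper engine: detrending, tapers, spectrogram oracle equivalence,
baseline normalization and band extraction."""

import numpy as np
import pytest
from scipy.signal import windows as sw

import sociolfp as sl


def direct_multitaper_window(seg, fs, params):
    """Independent direct implementation of one window's PSD estimate."""
    n = seg.shape[-1]
    t = np.arange(n)
    # least-squares line removal
    A = np.vstack([t, np.ones(n)]).T
    seg = seg - A @ np.linalg.lstsq(A, seg, rcond=None)[0]
    tapers = sw.dpss(n, params.nw, Kmax=params.n_tapers, norm=2)
    nfft = int(np.ceil(fs / params.freq_step_hz))
    psd = np.zeros(nfft // 2 + 1)
    for tap in np.atleast_2d(tapers):
        X = np.fft.rfft(seg * tap, nfft)
        psd += np.abs(X) ** 2 / params.n_tapers
    psd *= 2.0 / fs
    psd[0] /= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    keep = freqs <= params.fmax_hz + 1e-9
    return psd[keep]


class TestDetrend:
    def test_removes_a_line_exactly(self):
        t = np.arange(200.0)
        out = sl.detrend_trial(3.0 * t + 5.0)
        assert np.abs(out).max() < 1e-9

    def test_idempotent_on_detrended_input(self):
        x = sl.detrend_trial(np.random.default_rng(0).standard_normal(500))
        assert np.allclose(sl.detrend_trial(x), x, atol=1e-12)

    def test_post_detrend_slope_vanishes(self):
        x = sl.detrend_trial(np.random.default_rng(1).standard_normal(1000))
        t = np.arange(x.size)
        slope = np.polyfit(t, x, 1)[0]
        assert abs(slope) < 1e-10


class TestDPSS:
    def test_paper_settings_imply_two_tapers(self):
        p = sl.MTParams()
        assert p.nw == pytest.approx(1.5)
        assert p.n_tapers_implied == 2 == p.n_tapers

    def test_orthonormal_and_concentrated(self):
        tap, lam = sl.dpss_tapers(300, 1.5, 2)
        gram = tap @ tap.T
        assert np.abs(gram - np.eye(2)).max() < 1e-8
        assert lam[0] > lam[1] > 0.9

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(sl.ValidationError):
            sl.dpss_tapers(3, 1.5, 5)

    def test_k_above_2nw_minus_1_warns(self):
        with pytest.warns(UserWarning, match="2\\*NW-1"):
            sl.dpss_tapers(300, 1.5, 4)


class TestSpectrogram:
    def test_tone_localized_within_half_bandwidth(self):
        fs = 1000.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.sin(2 * np.pi * 30 * t)[None, None, :]
        ep = sl.EpochSet("target_onset", (0.0, 1.0), x, [0], fs)
        tf = sl.mt_spectrogram(ep, 0)
        peak_f = tf.freqs[tf.power[0].argmax(axis=1)]
        assert np.all(np.abs(peak_f - 30.0) <= 5.0)
        # and the tone's neighborhood carries the bulk of the power
        near = (tf.freqs >= 23) & (tf.freqs <= 37)
        frac = tf.power[0][:, near].sum() / tf.power[0].sum()
        assert frac > 0.95

    def test_every_window_matches_direct_oracle(self):
        fs, params = 1000.0, sl.MTParams()
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 1, 800))
        ep = sl.EpochSet("target_onset", (-0.2, 0.6), x, [0, 1, 2], fs)
        tf = sl.mt_spectrogram(ep, 0, params)
        n_win = int(params.window_s * fs)
        step = int(params.step_s * fs)
        for trial in range(3):
            for w in range(tf.times.size):
                seg = x[trial, 0, w * step:w * step + n_win].astype(float)
                want = direct_multitaper_window(seg, fs, params)
                got = tf.power[trial, w]
                rel = np.abs(got - want) / np.maximum(np.abs(want), 1e-300)
                assert rel.max() < 1e-10

    def test_amplitude_scaling_is_quadratic_in_power(self):
        fs = 1000.0
        x = np.random.default_rng(4).standard_normal((1, 1, 600))
        ep1 = sl.EpochSet("target_onset", (0.0, 0.6), x, [0], fs)
        ep3 = sl.EpochSet("target_onset", (0.0, 0.6), 3.0 * x, [0], fs)
        p1 = sl.mt_spectrogram(ep1, 0).power
        p3 = sl.mt_spectrogram(ep3, 0).power
        assert np.allclose(p3, 9.0 * p1, rtol=1e-10)

    def test_white_noise_psd_flat_across_band(self):
        fs = 1000.0
        x = np.random.default_rng(5).standard_normal((300, 1, 700))
        ep = sl.EpochSet("target_onset", (0.0, 0.7), x.astype(np.float32),
                         list(range(300)), fs)
        tf = sl.mt_spectrogram(ep, 0)
        marg = tf.power.mean(axis=(0, 1))
        band = (tf.freqs >= 10) & (tf.freqs <= 90)
        spread_db = 10 * np.log10(marg[band].max() / marg[band].min())
        assert spread_db < 1.0

    def test_psd_integral_matches_variance(self):
        # Parseval-style scaling check on white noise at full bandwidth
        fs = 1000.0
        x = np.random.default_rng(6).standard_normal((100, 1, 1000))
        ep = sl.EpochSet("target_onset", (0.0, 1.0), x, list(range(100)), fs)
        tf = sl.mt_spectrogram(ep, 0, sl.MTParams(fmax_hz=500.0))
        df = tf.freqs[1] - tf.freqs[0]
        integral = tf.power.sum(axis=2).mean() * df
        assert integral == pytest.approx(1.0, rel=0.05)

    def test_window_longer_than_epoch_rejected(self):
        ep = sl.EpochSet("target_onset", (0.0, 0.1),
                         np.zeros((1, 1, 100)), [0], 1000.0)
        with pytest.raises(sl.ValidationError):
            sl.mt_spectrogram(ep, 0)


class TestBaselineAndRelative:
    def _tf(self, power, times=None, freqs=None, window_s=0.3):
        power = np.asarray(power, dtype=float)
        times = np.arange(power.shape[1]) * 0.01 - 0.65 if times is None else times
        freqs = np.arange(power.shape[2]) * 1.5 if freqs is None else freqs
        return sl.TFGrid(times=times, freqs=freqs, power=power,
                         window_s=window_s)

    def test_constant_power_gives_constant_baseline(self):
        tf = self._tf(np.full((3, 60, 4), 7.0))
        np.testing.assert_allclose(sl.baseline_power(tf), 7.0)

    def test_baseline_is_the_trial_mean(self):
        p = np.ones((2, 60, 4))
        p[1] *= 3.0
        np.testing.assert_allclose(sl.baseline_power(self._tf(p)), 2.0)

    def test_no_qualifying_window_rejected(self):
        tf = self._tf(np.ones((1, 5, 4)), times=np.linspace(0.5, 0.9, 5))
        with pytest.raises(sl.ValidationError):
            sl.baseline_power(tf)

    def test_equal_power_is_zero_db_and_double_is_3db(self):
        tf = self._tf(np.full((2, 60, 4), 5.0))
        b = np.full(4, 5.0)
        rel = sl.relative_spectrogram(tf, b)
        np.testing.assert_allclose(rel.power, 0.0, atol=1e-12)
        rel2 = sl.relative_spectrogram(self._tf(np.full((2, 60, 4), 10.0)), b)
        np.testing.assert_allclose(rel2.power, 10 * np.log10(2), atol=1e-9)

    def test_zero_baseline_bin_names_the_frequency(self):
        tf = self._tf(np.ones((1, 60, 4)))
        b = np.array([1.0, 0.0, 1.0, 1.0])
        with pytest.raises(sl.ValidationError, match="1.5"):
            sl.relative_spectrogram(tf, b)

    def test_band_timecourse_isolates_the_band(self):
        freqs = np.arange(0, 101, 1.5)
        p = np.zeros((2, 10, freqs.size))
        p[:, :, (freqs >= 20) & (freqs <= 30)] = 1.0
        tf = self._tf(p, freqs=freqs)
        tf.units = "dB"
        assert np.allclose(sl.band_timecourse(tf, "beta"), 1.0)
        assert np.allclose(sl.band_timecourse(tf, "gamma"), 0.0)
        per_trial = sl.band_timecourse(tf, "beta", reduce="per-trial")
        assert per_trial.shape == (2, 10)

    def test_band_outside_grid_rejected(self):
        tf = self._tf(np.ones((1, 5, 3)), freqs=np.array([1.5, 3.0, 4.5]))
        with pytest.raises(sl.ValidationError):
            sl.band_timecourse(tf, sl.BandDef("x", 50, 60))
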