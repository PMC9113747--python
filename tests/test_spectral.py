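import numpy as np
import pytest
import scipy.signal

from socioscope import spectral as spc
from socioscope.io_model import EventTable, LfpChannel

from conftest import make_lfp, sine_lfp


def band_freqs(band, points_per_decade=60):
    f = spc.log_freq_grid(points_per_decade=points_per_decade)
    return f[(f >= band[0]) & (f < band[1])]


class TestMorletPower:
    def test_sinusoid_concentrates_in_its_band(self):
        lfp = sine_lfp(5.0, duration_s=30.0)
        tf = spc.morlet_power(lfp, spc.log_freq_grid(1, 100))
        mean = tf.power.mean(axis=0)
        peak = tf.freqs_hz[np.argmax(mean)]
        assert 4.0 <= peak <= 7.0
        p47 = spc.band_power_series(tf, (4, 7)).mean()
        p3060 = spc.band_power_series(tf, (30, 60)).mean()
        assert p3060 < 0.01 * p47

    def test_power_scales_with_amplitude_squared(self):
        tf1 = spc.morlet_power(sine_lfp(5.0, 1.0, 20.0), band_freqs((4, 7)))
        tf2 = spc.morlet_power(sine_lfp(5.0, 2.0, 20.0), band_freqs((4, 7)))
        r = spc.band_power_series(tf2, (4, 7)).mean() / spc.band_power_series(tf1, (4, 7)).mean()
        assert r == pytest.approx(4.0, rel=1e-6)

    def test_amplitude_calibration(self):
        # amplitude A at the wavelet's center frequency -> power A²/2
        lfp = sine_lfp(10.0, 3.0, 20.0)
        tf = spc.morlet_power(lfp, np.array([10.0]))
        center = tf.power[50:-50, 0].mean()  # avoid edge bins
        assert center == pytest.approx(3.0**2 / 2, rel=0.01)

    def test_white_noise_psd_matches_periodogram(self):
        rng = np.random.default_rng(3)
        fs = 1000.0
        x = rng.standard_normal(int(60 * fs))
        lfp = make_lfp(x, fs=fs)
        freqs = spc.log_freq_grid(2, 100)
        tf = spc.morlet_power(lfp, freqs)
        psd = tf.psd()
        f_w, p_w = scipy.signal.welch(x, fs=fs, nperseg=int(8 * fs))
        # oracle: periodogram averaged with the wavelet's frequency response,
        # so both estimators see the same spectral smoothing
        oracle = np.empty_like(psd)
        for j, f0 in enumerate(freqs):
            w = np.exp(-((6.0 * (f_w / f0 - 1.0)) ** 2))
            oracle[j] = np.sum(w * p_w) / np.sum(w)
        assert psd.mean() == pytest.approx(oracle.mean(), rel=0.10)
        assert np.all(np.abs(psd / oracle - 1.0) < 0.10)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            spc.morlet_power(sine_lfp(5.0, fs=400.0, duration_s=5.0), np.array([250.0]))

    def test_agrees_with_pywt_cwt(self):
        # independent route: PyWavelets complex-Morlet CWT (B=2, C=ω0/2π)
        pywt = pytest.importorskip("pywt")
        rng = np.random.default_rng(0)
        fs, f0 = 500.0, 8.0
        x = rng.standard_normal(int(20 * fs))
        lfp = make_lfp(x, fs=fs)
        tf = spc.morlet_power(lfp, np.array([f0]), bin_s=1.0 / fs)
        C = 6.0 / (2 * np.pi)
        scale = C * fs / f0
        coef, _ = pywt.cwt(x, [scale], f"cmor2.0-{C}", sampling_period=1 / fs, method="fft")
        a = tf.power[:, 0]
        b = np.abs(coef[0]) ** 2
        sl = slice(int(fs), -int(fs))  # trim edges
        r = np.corrcoef(a[sl], b[sl])[0, 1]
        assert r > 0.99


class TestBandPower:
    def test_band_selection_and_brute_force_mean(self):
        freqs = np.array([2.0, 5.0, 6.0, 40.0])
        power = np.zeros((4, 4))
        power[:, 1] = 1.0
        power[:, 2] = 3.0
        tf = spc.TimeFrequencyPower(np.arange(4) * 0.01, freqs, power)
        assert np.allclose(spc.band_power_series(tf, (4, 7)), (1.0 + 3.0) / 2)
        assert np.allclose(spc.band_power_series(tf, (30, 60)), 0.0)
        # constant spectrum: band power independent of band
        tf2 = spc.TimeFrequencyPower(np.arange(4) * 0.01, freqs, np.full((4, 4), 2.5))
        assert spc.band_power_series(tf2, (1, 4)).mean() == spc.band_power_series(tf2, (4, 60)).mean()

    def test_empty_band_errors(self):
        tf = spc.TimeFrequencyPower(np.zeros(1), np.array([5.0]), np.ones((1, 1)))
        with pytest.raises(ValueError):
            spc.band_power_series(tf, (100, 200))

    def test_identical_sessions_ratio_100(self):
        tf = spc.morlet_power(sine_lfp(5.0, duration_s=10.0), band_freqs((4, 7)))
        assert spc.session_power_ratio(tf, tf, (4, 7)) == pytest.approx(100.0)


class TestZscore:
    def test_constant_series_is_error(self):
        with pytest.raises(ValueError, match="standard deviation"):
            spc.zscore_power(np.full(10, 2.0))

    def test_one_sd_above_mean_maps_to_one(self):
        base = np.array([0.0, 2.0] * 50)  # mean 1, sd 1
        z = spc.zscore_power(np.array([2.0]), base)
        assert z[0] == pytest.approx(1.0)

    def test_mean_over_baseline_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, 1000)
        assert spc.zscore_power(x).mean() == pytest.approx(0.0, abs=1e-12)


class TestStateMeanPower:
    def test_injected_state_offset_recovered(self):
        n = 20_000
        bins = np.arange(n) * 0.01
        z = np.zeros(n)
        approach = np.array([[10.0, 15.0], [50.0, 55.0]])
        leaving = np.array([[30.0, 35.0]])
        for s, e in approach:
            z[(bins >= s) & (bins < e)] = 1.0
        means = spc.state_mean_power(z, bins, {"approach": approach, "leaving": leaving})
        assert means["approach"] == pytest.approx(1.0)
        assert means["leaving"] == pytest.approx(0.0)

    def test_empty_state_flagged_nan(self):
        with pytest.warns(UserWarning):
            means = spc.state_mean_power(np.zeros(10), np.arange(10) * 0.01, {"s": np.empty((0, 2))})
        assert np.isnan(means["s"])

    def test_label_permutation_permutes_outputs(self):
        z = np.arange(100, dtype=float)
        bins = np.arange(100) * 0.01
        ivs = {"a": np.array([[0.0, 0.3]]), "b": np.array([[0.5, 0.9]])}
        m1 = spc.state_mean_power(z, bins, ivs)
        m2 = spc.state_mean_power(z, bins, {"b": ivs["a"], "a": ivs["b"]})
        assert m1["a"] == m2["b"] and m1["b"] == m2["a"]


class TestCoherence:
    def test_identical_channels_full_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30 * 1000)
        a = make_lfp(x, fs=1000.0)
        b = make_lfp(x.copy(), fs=1000.0, region="BLA", channel_id="BLA_0")
        coh = spc.coherence_spectrum(a, b)
        sel = (coh.freqs_hz >= 1) & (coh.freqs_hz <= 70)
        assert np.all(coh.coherence[sel] > 0.999)

    def test_independent_noise_below_surrogate_bound(self):
        rng = np.random.default_rng(2)
        fs, dur = 1000.0, 150.0
        x = rng.standard_normal(int(dur * fs))
        y = rng.standard_normal(int(dur * fs))
        a = make_lfp(x, fs=fs)
        band = (4.0, 7.0)
        observed = spc.coherence_spectrum(a, make_lfp(y, fs=fs)).band_mean(band)
        null = [
            spc.coherence_spectrum(
                a, make_lfp(np.roll(y, int(rng.integers(int(5 * fs), int(dur * fs - 5 * fs)))), fs=fs)
            ).band_mean(band)
            for _ in range(20)
        ]
        assert observed < np.percentile(null, 95) * 1.5
        assert observed < 0.2  # far from genuine coupling

    def test_invariant_to_channel_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(20 * 1000)
        y = x + rng.standard_normal(20 * 1000)
        a = make_lfp(x, fs=1000.0)
        c1 = spc.coherence_spectrum(a, make_lfp(y, fs=1000.0))
        c2 = spc.coherence_spectrum(a, make_lfp(37.0 * y, fs=1000.0))
        assert np.allclose(c1.coherence, c2.coherence)

    def test_too_short_duration_errors(self):
        a = make_lfp(np.zeros(500), fs=1000.0)
        with pytest.raises(ValueError, match="too short"):
            spc.coherence_spectrum(a, a)


def simulate_var1(rng, n, coupling, ar=0.8):
    burn = 300
    x = np.zeros(n + burn)
    y = np.zeros(n + burn)
    ex = rng.standard_normal(n + burn)
    ey = rng.standard_normal(n + burn)
    for t in range(1, n + burn):
        x[t] = ar * x[t - 1] + ex[t]
        y[t] = ar * y[t - 1] + coupling * x[t - 1] + ey[t]
    return x[burn:], y[burn:]


class TestGranger:
    def test_swapping_channels_swaps_directions(self):
        rng = np.random.default_rng(4)
        x, y = simulate_var1(rng, 5000, 0.5)
        a = make_lfp(x, fs=200.0)
        b = make_lfp(y, fs=200.0, region="BLA", channel_id="BLA_0")
        g1 = spc.granger_spectrum(a, b)
        g2 = spc.granger_spectrum(b, a)
        assert np.allclose(g1.gc_a_to_b, g2.gc_b_to_a)
        assert np.allclose(g1.gc_b_to_a, g2.gc_a_to_b)

    def test_spectral_mean_matches_time_domain_gc(self):
        # Geweke consistency: mean over frequencies ≈ ln(restricted/full
        # residual variance) of the fitted VAR
        from statsmodels.tsa.ar_model import AutoReg
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(5)
        x, y = simulate_var1(rng, 20_000, 0.5)
        a = make_lfp(x, fs=200.0)
        b = make_lfp(y, fs=200.0)
        freqs = np.linspace(0.01, 100.0, 2000)
        g = spc.granger_spectrum(a, b, freqs=freqs)
        spectral_mean = g.gc_a_to_b.mean()

        data = np.column_stack([x, y]) - np.array([x.mean(), y.mean()])
        full = VAR(data).fit(g.var_order, trend="n")
        restricted = AutoReg(data[:, 1], lags=g.var_order, trend="n").fit()
        td_gc = np.log(restricted.sigma2 / full.sigma_u[1, 1])
        assert spectral_mean == pytest.approx(td_gc, rel=0.15)

    def test_unstable_var_rejected(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = np.cumsum(rng.standard_normal(n))  # random walk: unit root
        y = np.cumsum(rng.standard_normal(n))
        with pytest.raises(ValueError, match="unstable"):
            spc.granger_spectrum(make_lfp(x, fs=200.0), make_lfp(y, fs=200.0), max_order=2, ic=None)


class TestPac:
    @staticmethod
    def _signal(depth, seed=0, dur=60.0, fs=1000.0):
        # stochastic slow rhythm so time-shift surrogates form a real null
        from socioscope.synthetic import _narrowband_noise

        rng = np.random.default_rng(seed)
        n = int(dur * fs)
        t = np.arange(n) / fs
        slow = _narrowband_noise(rng, n, fs, (4.0, 7.0))
        phi = np.angle(scipy.signal.hilbert(slow))
        fast = (1 + depth * np.cos(phi)) * np.cos(2 * np.pi * 40 * t)
        return make_lfp(slow + 0.5 * fast + 0.1 * rng.standard_normal(n), fs=fs)

    def test_constructed_coupling_detected(self):
        res = spc.phase_amplitude_coupling(self._signal(0.8), seed=1)
        assert res.percentile > 99.0

    def test_independent_components_within_null(self):
        rng = np.random.default_rng(7)
        t = np.arange(60 * 1000) / 1000.0
        x = np.cos(2 * np.pi * 5 * t) + 0.5 * np.cos(2 * np.pi * 40 * t + 1.1)
        lfp = make_lfp(x + 0.1 * rng.standard_normal(len(t)), fs=1000.0)
        res = spc.phase_amplitude_coupling(lfp, seed=2)
        assert res.p_value > 0.05

    def test_index_increases_with_modulation_depth(self):
        vals = [
            spc.phase_amplitude_coupling(self._signal(d, seed=3), n_surrogate=10, seed=4).index
            for d in (0.0, 0.4, 0.8)
        ]
        assert vals[0] < vals[1] < vals[2]


class TestStimEvoked:
    @staticmethod
    def _stim_lfp(gain, band_hz=40.0, dur=150.0, fs=2000.0):
        t = np.arange(int(dur * fs)) / fs
        onsets = np.arange(30.0, dur - 2.0, 30.0)
        amp = np.ones(len(t))
        for o in onsets:
            amp[(t >= o) & (t < o + 2.0)] = gain
        events = EventTable(
            onsets, np.full(len(onsets), 2.0), ["stim_epoch"] * len(onsets)
        )
        return make_lfp(amp * np.cos(2 * np.pi * band_hz * t), fs=fs), events

    def test_gain_1p5_gives_125_percent(self):
        lfp, events = self._stim_lfp(1.5)
        tf = spc.morlet_power(lfp, band_freqs((30, 60)))
        change = spc.stim_evoked_power_change(tf, events, (30, 60))
        assert change == pytest.approx(125.0, abs=5.0)

    def test_no_change_near_zero(self):
        lfp, events = self._stim_lfp(1.0)
        tf = spc.morlet_power(lfp, band_freqs((30, 60)))
        assert spc.stim_evoked_power_change(tf, events, (30, 60)) == pytest.approx(0.0, abs=1.0)

    def test_amplitude_reduction_at_5hz(self):
        lfp, events = self._stim_lfp(0.9, band_hz=5.0)
        tf = spc.morlet_power(lfp, band_freqs((4, 7)))
        change = spc.stim_evoked_power_change(tf, events, (4, 7))
        assert change == pytest.approx(-19.0, abs=3.0)

    def test_overlapping_baseline_errors(self):
        lfp, _ = self._stim_lfp(1.5)
        # back-to-back epochs: each baseline overlaps the previous epoch
        onsets = np.array([30.0, 32.0])
        events = EventTable(onsets, np.full(2, 2.0), ["stim_epoch"] * 2)
        tf = spc.morlet_power(lfp, band_freqs((30, 60)))
        with pytest.raises(ValueError, match="overlap"):
            spc.stim_evoked_power_change(tf, events, (30, 60))
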