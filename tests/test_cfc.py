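"""Modulation index, filtering, and comodulogram localization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetalab.cfc import (
    amplitude_envelope,
    bandpass,
    comodulogram,
    instantaneous_phase,
    mean_theta_gamma_mi,
    modulation_index,
    surrogate_mi,
)

FS = 1000.0


def tone(freq, duration=30.0, fs=FS, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.cos(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        y = bandpass(tone(7.0), FS, 6.0, 8.0)
        core = slice(int(5 * FS), -int(5 * FS))
        assert np.std(y[core]) == pytest.approx(np.std(tone(7.0)[core]), rel=0.05)

    def test_out_of_band_attenuated(self):
        y = bandpass(tone(7.0), FS, 30.0, 80.0)
        core = slice(int(5 * FS), -int(5 * FS))
        assert np.std(y[core]) < 0.05 * np.std(tone(7.0)[core])

    def test_zero_phase(self):
        """Cross-correlation of input and output peaks at lag 0."""
        x = tone(7.0)
        y = bandpass(x, FS, 6.0, 8.0)
        core = slice(int(5 * FS), -int(5 * FS))
        lags = np.arange(-50, 51)
        xc = [np.dot(x[core], np.roll(y, l)[core]) for l in lags]
        assert lags[np.argmax(xc)] == 0

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(tone(7.0), FS, 8.0, 6.0)


class TestInstantaneousPhase:
    def test_cosine_phase_zero_at_period_multiples(self):
        x = tone(7.0)
        ph = instantaneous_phase(x)
        idx = (np.arange(1, 100) * FS / 7.0).astype(int)
        assert np.allclose(ph[idx], 0.0, atol=0.1)

    def test_unwrapped_slope_matches_frequency(self):
        ph = instantaneous_phase(tone(7.0))
        core = slice(int(FS), -int(FS))
        slope = np.polyfit(np.arange(len(ph))[core] / FS, np.unwrap(ph)[core], 1)[0]
        assert slope / (2 * np.pi) == pytest.approx(7.0, rel=1e-3)

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(int(10 * FS)) / FS
        ph_c = instantaneous_phase(np.cos(2 * np.pi * 7 * t))
        ph_s = instantaneous_phase(np.sin(2 * np.pi * 7 * t))
        core = slice(int(FS), -int(FS))
        diff = np.angle(np.exp(1j * (ph_c[core] - ph_s[core])))
        assert np.allclose(diff, np.pi / 2, atol=0.05)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 100_000)
        mi = modulation_index(phase, np.ones_like(phase))
        assert mi < 0.01

    def test_single_bin_amplitude_gives_one(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, 50_000)
        amp = np.where((phase > 0) & (phase < np.pi / 9), 1.0, 0.0)
        assert modulation_index(phase, amp, n_bins=18) == pytest.approx(1.0)

    def test_cosine_envelope_matches_brute_force_oracle(self):
        """MI of a closed-form envelope equals direct histogram + entropy."""
        rng = np.random.default_rng(2)
        phase = rng.uniform(-np.pi, np.pi, 200_000)
        amp = 1.0 + 0.5 * np.cos(phase)
        n_bins = 18
        # brute-force oracle: bin means, normalized entropy
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        means = np.array([
            amp[(phase >= edges[i]) & (phase < edges[i + 1])].mean()
            for i in range(n_bins)
        ])
        p = means / means.sum()
        expected = (np.log(n_bins) + np.sum(p * np.log(p))) / np.log(n_bins)
        assert modulation_index(phase, amp, n_bins) == pytest.approx(expected, abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, 10_000)
        amp = 1.0 + 0.4 * np.cos(phase - 1.0) + 0.01 * rng.random(10_000)
        assert modulation_index(phase, amp) == pytest.approx(
            modulation_index(phase, 37.5 * amp), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mi_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, 2000)
        amp = rng.random(2000) + 1e-3
        assert 0.0 <= modulation_index(phase, amp, n_bins=6) <= 1.0

    def test_zero_amplitude_raises(self):
        with pytest.raises(ValueError, match="zero"):
            modulation_index(np.linspace(-3, 3, 100), np.zeros(100))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            modulation_index(np.zeros(10), np.ones(11))


class TestComodulogram:
    def test_two_pac_pairs_localized(self):
        """Two independent couplings produce local maxima at their own
        coordinates, each matching a per-pair MI computed independently."""
        rng = np.random.default_rng(4)
        t = np.arange(int(120 * FS)) / FS
        # slow frequency wander gives the theta rhythms a realistic finite
        # bandwidth, which is what localizes them on the (narrow) phase axis
        th7 = np.cos(2 * np.pi * 7 * t + 0.3 / 0.05 * np.sin(2 * np.pi * 0.05 * t))
        th9 = np.cos(2 * np.pi * 9.5 * t + 0.3 / 0.05 * np.sin(2 * np.pi * 0.05 * t + 1.0))

        def gamma(fc, n):
            spec = np.fft.rfft(rng.standard_normal(n))
            f = np.fft.rfftfreq(n, 1 / FS)
            shaped = np.fft.irfft(spec * np.exp(-((f - fc) ** 2) / (2 * 5.0**2)), n)
            return shaped / np.std(shaped)

        x = (
            0.1 * th7
            + 0.1 * th9
            + 0.02 * (1 + 0.9 * th7) * gamma(70.0, len(t))
            + 0.02 * (1 + 0.9 * th9) * gamma(45.0, len(t))
            + 0.01 * rng.standard_normal(len(t))
        )
        com = comodulogram(x, FS, phase_range=(6.0, 10.0), amp_range=(35.0, 80.0))
        # the dominant pair is localized on both axes
        p_freq, a_freq, _ = com.peak()
        assert p_freq == pytest.approx(7.0, abs=0.5)
        assert a_freq == pytest.approx(70.0, abs=2.5)
        # both configured couplings stand out at their own coordinates;
        # oracle: the MI of each pair recomputed from its clean generator
        # components is large compared to the comodulogram background
        floor = np.median(com.mi)

        def cell(pf, af):
            i = np.argmin(np.abs(com.phase_freqs - pf))
            j = np.argmin(np.abs(com.amp_freqs - af))
            return com.mi[i, j]

        from thetalab.cfc import instantaneous_phase, modulation_index

        for theta, fc in [(th7, 70.0), (th9, 45.0)]:
            clean_env = 1 + 0.9 * theta  # generator's own envelope
            oracle = modulation_index(instantaneous_phase(theta), clean_env)
            assert oracle > 0.01
            assert cell(7.0 if fc == 70.0 else 9.5, fc) > 3 * floor

    def test_no_pac_noise_below_surrogates(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(60 * FS))
        phase = instantaneous_phase(bandpass(x, FS, 6, 8))
        env = amplitude_envelope(bandpass(x, FS, 60, 80))
        mi = modulation_index(phase, env)
        null = surrogate_mi(phase, env, FS, n_surrogates=100, seed=0)
        assert mi < np.quantile(null, 0.95)

    def test_amp_range_beyond_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            comodulogram(np.zeros(int(20 * FS)), FS, amp_range=(400.0, 600.0))


class TestMeanThetaGammaMI:
    def test_monotone_in_depth_and_zero_without_gamma(self, pac_session):
        t = np.arange(int(30 * FS)) / FS
        theta = np.cos(2 * np.pi * 7 * t)
        rng = np.random.default_rng(6)
        spec = np.fft.rfft(rng.standard_normal(len(t)))
        f = np.fft.rfftfreq(len(t), 1 / FS)
        g = np.fft.irfft(spec * np.exp(-((f - 55.0) ** 2) / 50.0), len(t))
        g /= np.std(g)
        mis = [
            mean_theta_gamma_mi(0.1 * theta + 0.02 * (1 + d * theta) * g, FS)
            for d in (0.0, 0.5, 1.0)
        ]
        assert mis[2] > mis[1] > mis[0]
        # pure sinusoid: no gamma at all -> essentially no coupling
        assert mean_theta_gamma_mi(0.1 * theta + 1e-6 * g, FS) < 0.01

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="10 s"):
            mean_theta_gamma_mi(np.zeros(int(5 * FS)), FS)
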