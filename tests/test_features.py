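"""Framing, STFT periodogram, Mel filterbank geometry, MelSpectrum /
Log-MelSpectrum and the additive-shift property of the log domain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgmel.features import (FeatureMap, StftConfig, build_mel_filterbank,
                             frame_signal, hz_to_mel, log_mel_spectrum,
                             mel_spectrum, mel_to_hz, stft_power,
                             to_model_input)
from pcgmel.io_preprocess import AudioRecording

FS = 2000.0


def _rec(x):
    return AudioRecording(samples=np.asarray(x, float), fs=FS)


class TestFraming:
    def test_frame_count_5000(self, stft_cfg):
        frames = frame_signal(_rec(np.ones(5000)), stft_cfg)
        assert frames.shape == (80, 240)  # floor((5000-240)/60)+1

    def test_constant_signal_gives_window(self, stft_cfg):
        frames = frame_signal(_rec(np.ones(1000)), stft_cfg)
        win = np.hanning(241)[:-1]
        assert np.allclose(frames, win[None, :])

    def test_single_frame_boundary(self, stft_cfg):
        frames = frame_signal(_rec(np.ones(240)), stft_cfg)
        assert frames.shape[0] == 1

    def test_too_short_rejected(self, stft_cfg):
        with pytest.raises(ValueError):
            frame_signal(_rec(np.ones(100)), stft_cfg)

    @settings(max_examples=50, deadline=None, derandomize=True,
              database=None)
    @given(n=st.integers(64, 2000), w=st.integers(8, 64), h=st.integers(1, 40))
    def test_frame_count_matches_brute_force(self, n, w, h):
        """L = floor((N-W)/H) + 1, vs literally enumerating frame starts."""
        cfg = StftConfig(window_size=w, hop_length=h, n_fft=64)
        x = np.arange(n, dtype=float) + 1.0
        frames = frame_signal(_rec(x), cfg)
        starts = [s for s in range(0, n, h) if s + w <= n and s % h == 0]
        brute = [s for s in range(0, n - w + 1) if s % h == 0]
        assert frames.shape[0] == len(brute) == (n - w) // h + 1
        # frame content: window times the right slice
        win = np.hanning(w + 1)[:-1]
        k = frames.shape[0] - 1
        assert np.allclose(frames[k], x[brute[k]:brute[k] + w] * win)


class TestStftPower:
    def test_zero_frames(self, stft_cfg):
        ps = stft_power(np.zeros((3, 240)), stft_cfg)
        assert ps.values.shape == (3, 257)
        assert np.all(ps.values == 0)

    def test_sinusoid_peak_at_bin(self, stft_cfg):
        k = 30  # exactly bin 30 of the 512-point FFT over 240-sample window
        n = np.arange(240)
        frame = np.sin(2 * np.pi * k * n / 512) * np.hanning(241)[:-1]
        ps = stft_power(frame[None, :], stft_cfg)
        # oracle: direct DFT sum
        dft = np.array([np.abs(np.sum(frame * np.exp(-2j * np.pi * kk * n / 512))) ** 2
                        for kk in range(257)])
        assert np.allclose(ps.values[0], dft, rtol=1e-9, atol=1e-9)
        peak = int(np.argmax(ps.values[0]))
        assert peak == k
        far = np.concatenate([ps.values[0][:k - 3], ps.values[0][k + 4:]])
        assert far.max() < 1e-3 * ps.values[0][peak]

    def test_parseval(self, stft_cfg, rng):
        frame = rng.standard_normal(240) * np.hanning(241)[:-1]
        ps = stft_power(frame[None, :], stft_cfg)
        one_sided = ps.values[0].copy()
        one_sided[1:-1] *= 2.0  # interior-bin doubling
        energy_freq = one_sided.sum() / stft_cfg.n_fft
        energy_time = np.sum(frame ** 2)
        assert math.isclose(energy_freq, energy_time, rel_tol=1e-6)


class TestMelFilterbank:
    def test_closed_form_mel_mapping(self):
        """Vector mel<->Hz agrees with an independent scalar implementation."""
        def mel_scalar(f):
            return 2595.0 * math.log10(1.0 + f / 700.0)

        def hz_scalar(m):
            return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

        for f in (0.0, 25.0, 137.5, 700.0, 950.0, 1000.0):
            assert math.isclose(float(hz_to_mel(f)), mel_scalar(f), abs_tol=1e-9)
            assert math.isclose(float(mel_to_hz(mel_scalar(f))), f, abs_tol=1e-9)
        # filterbank centres: recompute independently to 1e-9 Hz
        fb = build_mel_filterbank(n_mels=8, f_low=25.0, f_high=950.0)
        lo, hi = mel_scalar(25.0), mel_scalar(950.0)
        centers = [hz_scalar(lo + (hi - lo) * (i + 1) / 9.0) for i in range(8)]
        freqs = np.fft.rfftfreq(512, 1 / FS)
        for m, c in enumerate(centers):
            # the row must peak at (one of) the bins nearest the centre
            row = fb.weights[m]
            peak_bin = int(np.argmax(row))
            assert abs(freqs[peak_bin] - c) <= FS / 512  # within one bin

    def test_two_filter_geometry(self):
        fb = build_mel_filterbank(n_mels=2, f_low=0.0, f_high=FS / 2, n_fft=512)
        assert fb.weights.shape == (2, 257)
        assert np.all(fb.weights >= 0)
        for row in fb.weights:
            peak = int(np.argmax(row))
            assert np.all(np.diff(row[:peak + 1]) >= -1e-12)   # rises
            assert np.all(np.diff(row[peak:]) <= 1e-12)        # falls

    def test_rows_unimodal_and_band_covered(self, filterbank):
        freqs = np.fft.rfftfreq(512, 1 / FS)
        for row in filterbank.weights:
            nz = np.flatnonzero(row)
            if nz.size == 0:
                continue
            peak = int(np.argmax(row))
            assert np.all(np.diff(row[nz[0]:peak + 1]) >= -1e-12)
            assert np.all(np.diff(row[peak:nz[-1] + 1]) <= 1e-12)
        in_band = (freqs > filterbank.f_low) & (freqs < filterbank.f_high)
        coverage = filterbank.weights.sum(axis=0)
        assert np.all(coverage[in_band] > 0)

    def test_flat_spectrum_gives_row_sums(self, filterbank, stft_cfg):
        ps = stft_power(np.zeros((2, 240)), stft_cfg)
        flat = type(ps)(values=np.ones_like(ps.values),
                        frame_times=ps.frame_times, bin_freqs=ps.bin_freqs)
        out = mel_spectrum(flat, filterbank)
        expect = filterbank.weights.sum(axis=1)
        assert np.allclose(out.values, expect[:, None])

    def test_too_many_filters_warns(self):
        with pytest.warns(UserWarning, match="bin resolution"):
            build_mel_filterbank(n_mels=400, f_low=25.0, f_high=950.0)


class TestMelSpectrum:
    def test_zero_in_zero_out(self, filterbank, stft_cfg):
        ps = stft_power(np.zeros((4, 240)), stft_cfg)
        assert np.all(mel_spectrum(ps, filterbank).values == 0)

    def test_matches_double_loop_oracle(self, rng):
        from pcgmel.features import MelFilterbank, PowerSpectrogram
        weights = rng.uniform(0, 1, size=(3, 5))
        power = rng.uniform(0, 2, size=(4, 5))  # 4 frames, 5 bins
        fb = MelFilterbank(weights=weights, n_mels=3, f_low=0, f_high=1000)
        ps = PowerSpectrogram(values=power, frame_times=np.zeros(4),
                              bin_freqs=np.zeros(5))
        out = mel_spectrum(ps, fb).values
        brute = np.zeros((3, 4))
        for m in range(3):
            for l in range(4):
                for k in range(5):
                    brute[m, l] += weights[m, k] * power[l, k]
        assert np.allclose(out, brute, atol=1e-12)

    def test_homogeneity(self, filterbank, stft_cfg, rng):
        frames = rng.standard_normal((3, 240))
        ps = stft_power(frames, stft_cfg)
        doubled = type(ps)(values=2 * ps.values, frame_times=ps.frame_times,
                           bin_freqs=ps.bin_freqs)
        a = mel_spectrum(ps, filterbank).values
        b = mel_spectrum(doubled, filterbank).values
        assert np.allclose(b, 2 * a)

    def test_shape_mismatch_rejected(self, filterbank):
        from pcgmel.features import PowerSpectrogram
        ps = PowerSpectrogram(values=np.ones((2, 100)),
                              frame_times=np.zeros(2), bin_freqs=np.zeros(100))
        with pytest.raises(ValueError):
            mel_spectrum(ps, filterbank)

    def test_energy_conserved_with_column_normalization(self, stft_cfg, rng):
        fb = build_mel_filterbank(norm="column")
        frames = rng.standard_normal((5, 240)) * np.hanning(241)[:-1]
        ps = stft_power(frames, stft_cfg)
        freqs = ps.bin_freqs
        in_band = (freqs >= fb.f_low) & (freqs <= fb.f_high) \
            & (fb.weights.sum(axis=0) > 0)
        mel_total = mel_spectrum(ps, fb).values.sum()
        band_total = ps.values[:, in_band].sum()
        assert math.isclose(mel_total, band_total, rel_tol=1e-6)


class TestLogMel:
    def test_zero_maps_to_log_epsilon(self):
        mel = FeatureMap(values=np.array([[0.0, 1.0]]), flavor="mel")
        out = log_mel_spectrum(mel, epsilon=1e-6)
        assert np.isclose(out.values[0, 0], np.log(1e-6))

    def test_closed_form_values(self):
        mel = FeatureMap(values=np.array([[1.0, np.e, np.e ** 2]]), flavor="mel")
        out = log_mel_spectrum(mel, epsilon=1e-300)
        assert np.allclose(out.values, [[0.0, 1.0, 2.0]], atol=1e-9)

    def test_monotonicity(self, rng):
        vals = rng.uniform(0, 10, size=(6, 7))
        out = log_mel_spectrum(FeatureMap(values=vals, flavor="mel")).values
        i, j = np.unravel_index(np.argsort(vals, axis=None), vals.shape)
        assert np.all(np.diff(out[i, j]) >= 0)

    def test_requires_mel_flavor(self):
        lm = FeatureMap(values=np.zeros((2, 2)), flavor="log_mel")
        with pytest.raises(ValueError):
            log_mel_spectrum(lm)


class TestToModelInput:
    def test_identity_before_standardization(self, rng):
        vals = rng.uniform(0, 1, size=(128, 128))
        fm = FeatureMap(values=vals, flavor="mel")
        out = to_model_input(fm, standardize=False)
        assert np.array_equal(out.values, vals)

    def test_constant_map_standardizes_to_zero(self):
        fm = FeatureMap(values=np.full((128, 80), 3.0), flavor="mel")
        out = to_model_input(fm)
        assert out.values.shape == (128, 128)
        assert np.all(out.values == 0.0)

    def test_linear_ramp_stays_monotone(self):
        ramp = np.tile(np.linspace(0, 1, 80), (128, 1))
        out = to_model_input(FeatureMap(values=ramp, flavor="mel"),
                             standardize=False)
        # oracle: direct linear interpolation of the ramp is still a ramp
        expected = np.tile(np.interp(np.linspace(0, 1, 128),
                                     np.linspace(0, 1, 80),
                                     np.linspace(0, 1, 80)), (128, 1))
        assert np.allclose(out.values, expected, atol=1e-12)
        assert np.all(np.diff(out.values, axis=1) >= -1e-12)

    def test_standardized_moments(self, rng):
        vals = rng.uniform(0, 5, size=(128, 80))
        out = to_model_input(FeatureMap(values=vals, flavor="mel"))
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std() - 1.0) < 1e-9


class TestAdditiveShiftProperty:
    """Core claim: an LTI channel is a frame-constant per-band offset in the
    log-Mel domain, but not in the Mel domain."""

    @staticmethod
    def _melmap(x, cfg, fb):
        frames = frame_signal(_rec(x), cfg)
        return mel_spectrum(stft_power(frames, cfg), fb).values

    def test_channel_is_additive_in_log_domain(self, murmur_pcg, stft_cfg,
                                               filterbank):
        s = murmur_pcg.samples
        # first-order smooth test channel, gain bounded away from unity so the
        # per-band shift never crosses zero
        h = 0.25 * 0.7 ** np.arange(16)
        y = np.convolve(s, h, mode="full")[: s.size]
        m0 = self._melmap(s, stft_cfg, filterbank)[:, 2:-2]
        m1 = self._melmap(y, stft_cfg, filterbank)[:, 2:-2]
        shift = np.log(m1) - np.log(m0)
        diff = m1 - m0
        rel_sd_log, rel_sd_mel = [], []
        for m in range(m0.shape[0]):
            active = m0[m] >= 0.05 * m0[m].max()  # non-silent frames, band m
            if active.sum() < 8:
                continue
            sh, df = shift[m][active], diff[m][active]
            rel_sd_log.append(sh.std() / abs(sh.mean()))
            rel_sd_mel.append(df.std() / abs(df.mean()))
        rel_sd_log = np.array(rel_sd_log)
        rel_sd_mel = np.array(rel_sd_mel)
        assert rel_sd_log.size >= 100
        # log-Mel: frame-constant shift (SD < 10% of mean |shift|)
        assert np.median(rel_sd_log) < 0.10
        assert np.percentile(rel_sd_log, 90) < 0.10
        # Mel: the difference is NOT frame-constant for a non-stationary source
        assert np.median(rel_sd_mel) > 0.30
        assert np.median(rel_sd_mel) > 5 * np.median(rel_sd_log)


def test_full_chain_determinism(murmur_pcg, pre_cfg, stft_cfg):
    from pcgmel.features import extract_feature_map
    from pcgmel.io_preprocess import preprocess
    seg = preprocess(murmur_pcg, pre_cfg)[0]
    a = extract_feature_map(seg, "log_mel", stft_cfg=stft_cfg)
    b = extract_feature_map(seg, "log_mel", stft_cfg=stft_cfg)
    assert np.array_equal(a.values, b.values)
    assert a.values.shape == (128, 128)
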