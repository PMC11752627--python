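import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from afwave.errors import InputError, ParameterError
from afwave.timefreq import (
    CoefficientMatrix,
    MorseParams,
    cwt,
    cwt_direct,
    design_filter_bank,
    hamming_window,
    morse_wavelet_freq,
    ridge_frequency,
    scalogram,
    stft,
)

FS = 128.0


class TestHammingWindow:
    def test_length_three_values(self):
        np.testing.assert_allclose(hamming_window(3), [0.08, 1.0, 0.08], atol=1e-12)

    @pytest.mark.parametrize("length", [2, 5, 16, 257])
    def test_symmetry(self, length):
        w = hamming_window(length)
        np.testing.assert_allclose(w, w[::-1], atol=1e-15)

    def test_degenerate_length_one(self):
        np.testing.assert_array_equal(hamming_window(1), [1.0])

    def test_invalid_length(self):
        with pytest.raises(ParameterError):
            hamming_window(0)


class TestStft:
    def test_zero_signal_gives_zero_spectrogram(self):
        spec = stft(np.zeros(1024), FS)
        assert np.all(spec.values == 0)

    def test_frame_count_formula(self):
        spec = stft(np.zeros(3840), FS)
        assert spec.values.shape == (129, 29)

    def test_sinusoid_argmax_matches_windowed_dft_oracle(self):
        t = np.arange(3840) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        spec = stft(x, FS)
        target_bin = int(np.argmin(np.abs(spec.bin_freqs - 10.0)))
        mags = np.abs(spec.values)
        assert np.all(np.argmax(mags, axis=0) == target_bin)
        # oracle: direct DFT of one explicitly windowed frame
        frame = x[128 * 5 : 128 * 5 + 256] * hamming_window(256)
        k = np.arange(129)
        dft = np.array([np.sum(frame * np.exp(-2j * np.pi * kk * np.arange(256) / 256)) for kk in k])
        np.testing.assert_allclose(spec.values[:, 5], dft, atol=1e-9)

    def test_parseval_per_frame(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=1000)
        spec = stft(x, FS)
        w = hamming_window(256)
        for f in range(spec.values.shape[1]):
            frame = x[128 * f : 128 * f + 256] * w
            X = spec.values[:, f]
            one_sided = np.abs(X[0]) ** 2 + np.abs(X[-1]) ** 2 + 2 * np.sum(np.abs(X[1:-1]) ** 2)
            assert one_sided == pytest.approx(256 * np.sum(frame**2), rel=1e-6)

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            stft(np.zeros(100), FS)


class TestMorseWavelet:
    def test_zero_and_negative_frequency_vanish(self):
        p = MorseParams()
        assert morse_wavelet_freq(0.0, p) == 0.0
        assert morse_wavelet_freq(-1.0, p) == 0.0

    def test_peak_frequency_closed_form(self):
        p = MorseParams()  # gamma 3, beta 20
        res = minimize_scalar(
            lambda w: -morse_wavelet_freq(w, p), bounds=(0.1, 10.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(res.x - (20.0 / 3.0) ** (1.0 / 3.0)) < 1e-6

    def test_positive_response_above_zero(self):
        p = MorseParams()
        w = np.linspace(0.01, 5, 100)
        assert np.all(morse_wavelet_freq(w, p) > 0)

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            MorseParams(gamma=0.0)
        with pytest.raises(ParameterError):
            MorseParams(normalization="l3")


class TestFilterBank:
    def test_geometric_center_frequencies(self):
        bank = design_filter_bank(3840, FS)
        ratios = bank.center_freqs[1:] / bank.center_freqs[:-1]
        np.testing.assert_allclose(ratios, 2.0 ** (-1.0 / 10.0), rtol=1e-12)

    def test_highest_center_frequency_near_nyquist(self):
        bank = design_filter_bank(3840, FS)
        assert bank.center_freqs[0] <= FS / 2 * 1.0000001
        assert bank.center_freqs[0] >= FS / 2 * 2.0 ** (-1.0 / 10.0)

    def test_admissibility_zero_at_dc(self):
        bank = design_filter_bank(512, FS)
        assert np.all(bank.filters[:, 0] == 0.0)

    def test_scale_to_frequency_mapping(self):
        bank = design_filter_bank(1024, FS)
        wp = bank.params.peak_omega
        np.testing.assert_allclose(bank.center_freqs, wp * FS / (2 * np.pi * bank.scales))

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputError):
            design_filter_bank(6, FS)


class TestCwt:
    def test_zero_signal_gives_zero_matrix(self):
        c = cwt(np.zeros(512), FS)
        assert np.all(c.values == 0)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        c1 = cwt(x, FS)
        c3 = cwt(3.5 * x, FS)
        np.testing.assert_allclose(c3.values, 3.5 * c1.values, atol=1e-12)

    def test_sinusoid_ridge_and_unit_l1_magnitude(self):
        bank = design_filter_bank(int(8 * FS), FS)
        f0 = bank.center_freqs[35]  # away from both scale edges
        t = np.arange(int(8 * FS)) / FS
        c = cwt(np.cos(2 * np.pi * f0 * t), FS)
        assert ridge_frequency(c) == pytest.approx(f0)
        mid = np.abs(c.values[35, c.values.shape[1] // 2])
        assert 0.9 <= mid <= 1.1

    def test_l2_normalization_follows_sqrt_scale(self):
        # the 1/sqrt(a) convention boosts a unit sinusoid's ridge magnitude
        # by sqrt(scale) relative to the unit-amplitude l1 form
        n = int(8 * FS)
        t = np.arange(n) / FS
        bank = design_filter_bank(n, FS)
        f0 = bank.center_freqs[30]
        x = np.cos(2 * np.pi * f0 * t)
        c1 = cwt(x, FS, MorseParams(normalization="l1"))
        c2 = cwt(x, FS, MorseParams(normalization="l2"))
        mid = c1.values.shape[1] // 2
        measured = np.abs(c2.values[30, mid]) / np.abs(c1.values[30, mid])
        from afwave.timefreq import _morse_l2_amplitude

        expected = np.sqrt(c1.scales[30]) * _morse_l2_amplitude(20.0, 3.0) / (
            2.0 / ((20 / 3) ** (20 / 3) * np.exp(-20 / 3))
        )
        assert measured == pytest.approx(expected, rel=1e-6)

    def test_matches_direct_integration_outside_coi(self):
        # fast variant of the full oracle check: 3 scales, 256 samples
        n = 256
        t = np.arange(n) / FS
        x = np.cos(2 * np.pi * 8.0 * t) + 0.4 * np.sin(2 * np.pi * 16.0 * t)
        c = cwt(x, FS)
        # 4 Hz and below have no out-of-cone samples in a 2 s signal
        sel = [int(np.argmin(np.abs(c.center_freqs - f))) for f in (8.0, 16.0, 32.0)]
        direct = cwt_direct(x, FS, c.scales[sel])
        ref = np.abs(direct).max()
        for row, j in enumerate(sel):
            mask = c.center_freqs[j] >= c.coi
            assert mask.any()
            err = np.abs(c.values[j, mask] - direct[row, mask]).max() / ref
            assert err < 1e-3

    def test_ridge_recovery_within_one_voice(self):
        t = np.arange(int(10 * FS)) / FS
        for f0 in (1.0, 5.0, 10.0, 20.0, 40.0):
            c = cwt(np.cos(2 * np.pi * f0 * t), FS)
            assert abs(np.log2(ridge_frequency(c) / f0)) <= 1.0 / 10.0

    def test_more_voices_never_hurt_ridge_accuracy(self):
        t = np.arange(int(10 * FS)) / FS
        freqs = (1.0, 5.0, 10.0, 20.0, 40.0)
        max_err = []
        for voices in (4, 8, 16):
            params = MorseParams(voices_per_octave=voices)
            err = max(
                abs(np.log2(ridge_frequency(cwt(np.cos(2 * np.pi * f * t), FS, params)) / f))
                for f in freqs
            )
            max_err.append(err * voices)  # error in units of voices
        assert max_err[0] >= max_err[1] >= max_err[2] or max(max_err) < 0.5

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InputError):
            cwt(np.array([1.0, np.nan, 0.0, 1.0]), FS)


class TestScalogram:
    def test_modulus(self):
        c = CoefficientMatrix(
            values=np.array([[3 + 4j, -2 + 0j]]),
            scales=np.array([1.0]),
            center_freqs=np.array([10.0]),
            times=np.array([0.0, 1.0]),
            coi=np.array([64.0, 64.0]),
        )
        np.testing.assert_allclose(scalogram(c), [[5.0, 2.0]])

    def test_real_coefficients_equal_absolute_value(self):
        vals = np.array([[1.5, -2.5, 0.0]])
        c = CoefficientMatrix(
            values=vals.astype(complex),
            scales=np.array([1.0]),
            center_freqs=np.array([10.0]),
            times=np.arange(3.0),
            coi=np.full(3, 64.0),
        )
        np.testing.assert_array_equal(scalogram(c), np.abs(vals))
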