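"""Signal-toolbox tests: spectral oracles for filtering and downsampling,
closed forms for TKEO, normalization identities for the Morlet envelope
and band powers, and montage algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from somnevent import (
    BandSet,
    FilterSpec,
    Recording,
    apply_filter,
    demean_detrend,
    downsample,
    morlet,
    normalized_band_powers,
    rereference,
    spectrogram,
    tkeo,
)


def _dft_amp(x, rate, freq):
    """Single-frequency discrete Fourier amplitude."""
    t = np.arange(x.size) / rate
    return 2.0 * np.abs(np.mean(x * np.exp(-2j * np.pi * freq * t)))


class TestApplyFilter:
    def test_bandpass_keeps_inband_rejects_outofband(self):
        rate = 100.0
        t = np.arange(3000) / rate
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 13 * t)
        y = apply_filter(x, rate, FilterSpec("butterworth", "bandpass", (12, 14), 3))
        assert _dft_amp(y, rate, 13.0) > 10 ** (-1 / 20)  # within 1 dB
        assert _dft_amp(y, rate, 5.0) < 10 ** (-20 / 20)  # >= 20 dB down

    def test_zero_signal_stays_zero(self):
        y = apply_filter(np.zeros(500), 100.0, FilterSpec())
        assert np.allclose(y, 0.0)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            apply_filter(np.ones(500), 100.0, FilterSpec("butterworth", "lowpass", (50.0,), 3))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            apply_filter(np.ones(5), 100.0, FilterSpec(order=4))

    def test_bessel_family_supported(self):
        y = apply_filter(np.random.default_rng(0).standard_normal(1000), 100.0,
                         FilterSpec("bessel", "lowpass", (10.0,), 4))
        assert y.shape == (1000,)

    def test_linearity(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        spec = FilterSpec("butterworth", "bandpass", (8, 16), 3)
        lhs = apply_filter(2.5 * x - 1.5 * y, 100.0, spec)
        rhs = 2.5 * apply_filter(x, 100.0, spec) - 1.5 * apply_filter(y, 100.0, spec)
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)

    def test_input_untouched(self, rng):
        x = rng.standard_normal(1000)
        before = x.copy()
        apply_filter(x, 100.0, FilterSpec())
        np.testing.assert_array_equal(x, before)


class TestDemeanDetrend:
    def test_constant_demeans_to_zero(self):
        assert np.allclose(demean_detrend(np.full(100, 7.0), "demean"), 0.0)

    def test_ramp_detrends_to_zero(self):
        resid = demean_detrend(np.arange(200.0), "linear-detrend")
        assert np.max(np.abs(resid)) < 1e-9

    def test_offset_sine_keeps_sine(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 2 * t)
        # full periods: the mean is the offset, so demeaning recovers the sine
        out = demean_detrend(x + 5.0, "demean")
        assert np.allclose(out, x, atol=1e-9)


class TestMorlet:
    def test_zero_in_zero_out(self):
        assert np.allclose(np.abs(morlet(np.zeros(1000), 100.0, 13.0)), 0.0)

    def test_unit_sine_has_unit_envelope(self):
        rate, f = 100.0, 13.0
        t = np.arange(4000) / rate
        amp = np.abs(morlet(np.sin(2 * np.pi * f * t), rate, f))
        mid = amp[1000:3000]  # middle 50 %
        assert np.all(np.abs(mid - 1.0) < 0.05)

    def test_cosine_phase_zero_at_maxima(self):
        rate, f = 100.0, 10.0
        t = np.arange(3000) / rate
        phase = np.angle(morlet(np.cos(2 * np.pi * f * t), rate, f))
        maxima = np.arange(10, 290) * 10  # t = k/f, away from edges
        wrapped = np.angle(np.exp(1j * phase[maxima]))
        assert np.all(np.abs(wrapped) < 0.1)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            morlet(np.zeros(100), 100.0, 60.0)


class TestTkeo:
    def test_constant_is_zero(self):
        assert np.allclose(tkeo(np.full(50, 3.7)), 0.0)

    def test_cosine_closed_form(self):
        # psi[A cos(w n)] = A^2 sin^2(w), constant over interior samples
        a, w = 2.5, 0.3
        x = a * np.cos(w * np.arange(500))
        psi = tkeo(x)
        assert np.max(np.abs(psi - a**2 * np.sin(w) ** 2)) < 1e-9

    def test_impulse_signature(self):
        # direct expansion: an isolated impulse gives psi = 1 at the
        # impulse and 0 elsewhere (its neighbors' products all vanish)
        x = np.zeros(21)
        x[10] = 1.0
        psi = tkeo(x)
        assert psi[10] == 1.0
        assert np.all(psi[np.arange(21) != 10] == 0.0)
        # negativity needs a positive neighbor product: a gap between two
        # impulses is pushed negative
        y = np.zeros(21)
        y[9] = y[11] = 1.0
        assert tkeo(y)[10] == -1.0

    @given(arrays(np.float64, st.integers(3, 200),
                  elements=st.floats(-100, 100, allow_nan=False)))
    def test_matches_definition(self, x):
        psi = tkeo(x)
        for n in range(1, x.size - 1):
            assert psi[n] == pytest.approx(x[n] ** 2 - x[n - 1] * x[n + 1])
        assert psi[0] == psi[1] and psi[-1] == psi[-2]


class TestNormalizedBandPowers:
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one(self, seed):
        x = np.random.default_rng(seed).standard_normal(500)
        p = normalized_band_powers(x, 100.0)
        assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-9
        assert np.all(p >= 0)

    def test_sigma_dominates_for_13hz(self):
        t = np.arange(3000) / 100.0
        p = normalized_band_powers(np.sin(2 * np.pi * 13 * t), 100.0)
        mid = p[750:2250]
        assert np.all(mid.argmax(axis=1) == 3)

    def test_delta_dominates_for_2hz(self):
        t = np.arange(3000) / 100.0
        p = normalized_band_powers(np.sin(2 * np.pi * 2 * t), 100.0)
        mid = p[750:2250]
        assert np.all(mid.argmax(axis=1) == 0)

    def test_zero_signal_uniform_sentinel(self):
        p = normalized_band_powers(np.zeros(200), 100.0)
        assert np.allclose(p, 0.25)

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            normalized_band_powers(np.zeros(100), 20.0)


class TestSpectrogram:
    def test_pure_tone_peaks_at_its_bin(self):
        rate = 100.0
        t = np.arange(6000) / rate
        freqs, _, mag = spectrogram(np.sin(2 * np.pi * 10 * t), rate, window_s=5.0,
                                    overlap_frac=0.5)
        peak_freqs = freqs[mag.argmax(axis=0)]
        assert np.all(np.abs(peak_freqs - 10.0) < freqs[1] - freqs[0] + 1e-9)

    def test_zero_signal_zero_matrix(self):
        _, _, mag = spectrogram(np.zeros(3000), 100.0, window_s=5.0)
        assert np.allclose(mag, 0.0)

    def test_column_count_formula(self):
        _, times, mag = spectrogram(np.zeros(3000), 100.0, window_s=5.0,
                                    overlap_frac=0.5)
        assert mag.shape[1] == len(times) == 11  # floor((3000-500)/250)+1

    def test_band_restriction(self):
        freqs, _, _ = spectrogram(np.zeros(3000), 100.0, window_s=5.0,
                                  fmin=5.0, fmax=20.0)
        assert freqs.min() >= 5.0 and freqs.max() <= 20.0

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(3000), 100.0, fmin=20.0, fmax=10.0)


class TestRereference:
    def test_common_average_zero_mean(self, recording):
        out = rereference(recording, "common-average")
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-9

    def test_common_average_idempotent(self, recording):
        once = rereference(recording, "common-average")
        twice = rereference(once, "common-average")
        assert np.max(np.abs(twice.data - once.data)) < 1e-9

    def test_single_reference_zeroes_reference_row(self, recording):
        out = rereference(recording, "single", reference="Cz")
        assert np.allclose(out.channel("Cz"), 0.0)
        assert np.allclose(out.channel("C3"),
                           recording.channel("C3") - recording.channel("Cz"))

    def test_bipolar_consecutive_differences(self, rng):
        data = rng.standard_normal((5, 200))
        rec = Recording(data, 100.0, ("a", "b", "c", "d", "e"))
        out = rereference(rec, "bipolar")
        assert out.channels == ("a-b", "b-c", "c-d", "d-e")
        for i in range(4):
            assert np.allclose(out.data[i], data[i] - data[i + 1])

    def test_bipolar_needs_two_channels(self):
        rec = Recording(np.zeros((1, 100)), 100.0, ("only",))
        with pytest.raises(ValueError, match="bipolar"):
            rereference(rec, "bipolar")

    def test_unknown_reference_rejected(self, recording):
        with pytest.raises(KeyError):
            rereference(recording, "single", reference="Pz")

    def test_nondestructive(self, recording):
        before = recording.data.copy()
        rereference(recording, "common-average")
        np.testing.assert_array_equal(recording.data, before)


class TestDownsample:
    def test_halving_length(self):
        y, new_rate = downsample(np.zeros(6000), 200.0, 100.0)
        assert y.size == 3000 and new_rate == 100.0

    def test_tone_amplitude_preserved(self):
        rate = 200.0
        t = np.arange(8000) / rate
        y, _ = downsample(np.sin(2 * np.pi * 10 * t), rate, 100.0)
        assert abs(_dft_amp(y[400:-400], 100.0, 10.0) - 1.0) < 0.02

    def test_identity_when_target_equals_rate(self, rng):
        x = rng.standard_normal(500)
        y, new_rate = downsample(x, 100.0, 100.0)
        np.testing.assert_array_equal(y, x)
        assert new_rate == 100.0

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros(100), 100.0, 200.0)


class TestBandSetAndFilterSpec:
    def test_default_bands(self):
        bands = dict(BandSet().items())
        assert bands["delta"] == (0.5, 4.0) and bands["sigma"] == (12.0, 16.0)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            BandSet(delta=(4.0, 0.5))

    def test_bandpass_needs_two_cutoffs(self):
        with pytest.raises(ValueError):
            FilterSpec("butterworth", "bandpass", (10.0,), 3)
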