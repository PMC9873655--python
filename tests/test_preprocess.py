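"""Audio-to-spectrum chain: loading, lead removal, squaring, decimation,
transform, band selection."""
import numpy as np
import pytest

import fractalvoc as fv
from fractalvoc.errors import (
    DomainError,
    IneligibleRecordingError,
    InputError,
)
from fractalvoc.preprocess import (
    AmplitudeSignal,
    PowerSignal,
    band_select,
    check_eligible,
    compute_spectrum,
    decimate_chain,
    load_recording,
    preprocess_recording,
    spectrum_from_csv,
    spectrum_to_csv,
    square_signal,
    strip_lead,
)


class TestLoadRecording:
    def test_digital_silence_identity(self, silence_wav):
        sig, meta = load_recording(silence_wav)
        assert sig.samples.shape == (44000,)
        assert np.all(sig.samples == 0)
        assert sig.rate == 44000
        assert meta.sample_rate == 44000
        assert meta.duration == pytest.approx(1.0)

    def test_stereo_averages_channels(self, stereo_wav):
        path, c1, c2 = stereo_wav
        sig, _ = load_recording(path)
        np.testing.assert_allclose(sig.samples, (c1.astype(float) + c2) / 2)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            load_recording(str(tmp_path / "nope.wav"))

    def test_corrupt_file(self, tmp_path):
        bad = tmp_path / "bad.wav"
        bad.write_text("this is not audio")
        with pytest.raises(InputError):
            load_recording(str(bad))

    def test_resamples_other_rates(self, tmp_path):
        from scipy.io import wavfile

        path = tmp_path / "f22k.wav"
        wavfile.write(str(path), 22000, np.zeros(22000, dtype=np.int16))
        sig, meta = load_recording(str(path))
        assert sig.rate == 44000
        assert sig.samples.size == 44000

    def test_short_recording_flagged_ineligible(self, tmp_path):
        from scipy.io import wavfile

        path = tmp_path / "short.wav"
        # 50 s: below the 100 s minimum after 5 s lead removal
        wavfile.write(str(path), 44000, np.zeros(44000 * 50, dtype=np.int16))
        sig, meta = load_recording(str(path))
        with pytest.raises(IneligibleRecordingError):
            check_eligible(sig, lead=5.0, min_length=100.0, recording_id=meta.recording_id)


class TestStripLead:
    def test_105s_becomes_100s(self):
        sig = AmplitudeSignal(np.zeros(105 * 1000), 1000.0)
        out = strip_lead(sig, 5.0)
        assert out.duration == pytest.approx(100.0)

    def test_zero_lead_is_identity(self):
        sig = AmplitudeSignal(np.arange(500.0), 100.0)
        out = strip_lead(sig, 0.0)
        np.testing.assert_array_equal(out.samples, sig.samples)

    def test_drops_exactly_lead_times_rate_samples(self):
        sig = AmplitudeSignal(np.zeros(44000 * 6), 44000.0)
        out = strip_lead(sig, 5.0)
        assert sig.samples.size - out.samples.size == 220_000

    def test_too_short_raises(self):
        sig = AmplitudeSignal(np.zeros(100), 100.0)
        with pytest.raises(IneligibleRecordingError):
            strip_lead(sig, 5.0)


class TestSquare:
    def test_elementwise_square_and_nonnegative(self):
        sig = AmplitudeSignal(np.array([-2.0, 3.0]), 10.0)
        out = square_signal(sig)
        np.testing.assert_array_equal(out.samples, [4.0, 9.0])
        rng = np.random.default_rng(1)
        out2 = square_signal(AmplitudeSignal(rng.normal(size=256), 10.0))
        assert np.all(out2.samples >= 0)


class TestDecimateChain:
    def test_rate_bookkeeping_exact(self):
        sig = PowerSignal(np.ones(44000), 44000.0)
        out = decimate_chain(sig, (10, 10, 2))
        assert out.rate == 220.0
        assert out.rate / 2 == 110.0

    def test_constant_passthrough(self):
        sig = PowerSignal(np.full(44000 * 2, 3.7), 44000.0)
        out = decimate_chain(sig)
        assert np.max(np.abs(out.samples - 3.7)) < 1e-3 * 3.7

    def test_in_band_sinusoid_amplitude_preserved(self):
        t = np.arange(44000 * 4) / 44000.0
        sig = PowerSignal(2.0 + np.sin(2 * np.pi * 1.0 * t), 44000.0)
        out = decimate_chain(sig)
        amp = (out.samples.max() - out.samples.min()) / 2
        assert abs(amp - 1.0) < 0.01

    def test_too_short_raises(self):
        with pytest.raises(IneligibleRecordingError):
            decimate_chain(PowerSignal(np.ones(5), 44000.0))


class TestComputeSpectrum:
    def test_pure_tone_concentrates_in_one_bin(self):
        rate, dur = 220.0, 1000
        t = np.arange(int(rate * dur)) / rate
        sig = PowerSignal(1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t), rate)
        spec = compute_spectrum(sig)
        k = np.argmax(spec.powers)
        assert spec.frequencies[k] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(spec.powers, k)
        assert others.max() <= 1e-6 * spec.powers[k]

    def test_parseval(self):
        rng = np.random.default_rng(3)
        for n in (1024, 1023):
            x = rng.normal(size=n)
            spec = compute_spectrum(PowerSignal(x**2, 220.0))
            time_sum = np.sum((x**2 - np.mean(x**2)) ** 2)
            assert np.sum(spec.powers) == pytest.approx(time_sum, rel=1e-8)

    def test_degenerate_length_raises(self):
        with pytest.raises(InputError):
            compute_spectrum(PowerSignal(np.array([1.0]), 220.0))

    def test_magnitude_option(self):
        x = np.random.default_rng(0).normal(size=511) ** 2
        sq = compute_spectrum(PowerSignal(x, 220.0), quantity="magnitude_squared")
        mag = compute_spectrum(PowerSignal(x, 220.0), quantity="magnitude")
        # same grid; squared quantity proportional to magnitude squared
        np.testing.assert_allclose(sq.powers, 2.0 / 511 * mag.powers**2, rtol=1e-10)


class TestBandSelect:
    def test_default_band_limits(self, small_fractal_spectrum):
        f = small_fractal_spectrum.frequencies
        assert f.min() >= 0.01 - 1e-12
        assert f.max() <= 10.0 + 1e-9

    def test_bin_count_closed_interval(self):
        # 1000 s at 220 Hz: grid step 0.001 Hz, indices 10..10000 inclusive
        n = 220_000
        freqs = np.arange(1, n // 2 + 1) * 220.0 / n
        spec = fv.Spectrum(freqs, np.ones_like(freqs))
        out = band_select(spec, 0.01, 10.0)
        assert len(out) == 9991

    def test_empty_band_raises(self):
        spec = fv.Spectrum(np.array([20.0, 30.0]), np.array([1.0, 1.0]))
        with pytest.raises(IneligibleRecordingError):
            band_select(spec, 0.01, 10.0)

    def test_invalid_edges_raise(self):
        spec = fv.Spectrum(np.array([1.0]), np.array([1.0]))
        with pytest.raises(DomainError):
            band_select(spec, 5.0, 1.0)


class TestPipelineProperties:
    def test_band_top_below_decimated_nyquist(self):
        sig = AmplitudeSignal(np.random.default_rng(0).normal(size=44000 * 106), 44000.0)
        with pytest.raises(DomainError):
            preprocess_recording(sig, f_hi=150.0)

    def test_square_before_decimate_matters(self):
        # squaring a tone creates the 2f harmonic and a DC shift; reversing
        # the order loses that structure
        t = np.arange(44000 * 8) / 44000.0
        x = 1.0 + 0.5 * np.sin(2 * np.pi * 3.0 * t)
        sq_then_dec = decimate_chain(PowerSignal(x**2, 44000.0))
        dec_then_sq = decimate_chain(PowerSignal(x, 44000.0))
        spec_a = compute_spectrum(sq_then_dec)
        spec_b = compute_spectrum(PowerSignal(dec_then_sq.samples**2, 220.0))
        ka = np.argmax(spec_a.powers)
        kb = np.argmax(spec_b.powers)
        # 6 Hz line present in the squared-first spectrum
        fa = spec_a.frequencies[np.argsort(spec_a.powers)[-2:]]
        assert np.any(np.isclose(fa, 6.0, atol=1e-6))
        assert not np.allclose(spec_a.powers, spec_b.powers)

    def test_end_to_end_slope_recovers_beta(self):
        spec = fv.SynthSpec(
            "fractal", fv.FractalParams(1.0, 1.0, 0.0, 1e-5), 600.0, 220.0, seed=4
        )
        sig = fv.gen_fractal_power_signal(spec)
        sp = band_select(compute_spectrum(sig), 0.01, 10.0)
        slope = np.polyfit(np.log(sp.frequencies), np.log(sp.powers), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)


def test_spectrum_csv_roundtrip(tmp_path, small_fractal_spectrum):
    path = str(tmp_path / "spec.csv")
    spectrum_to_csv(small_fractal_spectrum, path)
    back = spectrum_from_csv(path)
    np.testing.assert_allclose(back.frequencies, small_fractal_spectrum.frequencies)
    np.testing.assert_allclose(back.powers, small_fractal_spectrum.powers)
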