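import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consonance.spectra import (
    ChordSpec,
    EnvelopeParams,
    TimbreParams,
    ToneSpectrum,
    adsr_envelope,
    beat_rate,
    chord_spectrum,
    estimate_instrument_spectrum,
    freq_to_midi,
    make_tone,
    midi_to_freq,
    render_audio,
)


class TestMidiToFreq:
    def test_concert_a(self):
        assert midi_to_freq(69) == pytest.approx(440.0, abs=1e-12)

    def test_octave_doubling(self):
        assert midi_to_freq(81) == pytest.approx(880.0, abs=1e-9)

    def test_middle_c(self):
        # 440 * 2**(-9/12), evaluated independently
        assert midi_to_freq(60) == pytest.approx(261.6255653005986, abs=1e-9)

    def test_strictly_increasing(self):
        p = np.linspace(0, 127, 500)
        f = midi_to_freq(p)
        assert np.all(np.diff(f) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            midi_to_freq(float("nan"))
        with pytest.raises(ValueError):
            midi_to_freq(float("inf"))

    @given(st.floats(min_value=0.0, max_value=127.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, p):
        assert abs(freq_to_midi(midi_to_freq(p)) - p) < 1e-9


class TestMakeTone:
    def test_type_i_weights(self):
        tone = make_tone(TimbreParams.harmonic(roll_off=3.0), 200.0)
        # second partial: 10**(-3*log2(2)/20) = 10**(-0.15)
        assert tone.amplitudes[1] == pytest.approx(10 ** (-3 / 20), rel=1e-12)
        assert tone.frequencies[1] == pytest.approx(400.0)
        assert len(tone) == 10

    def test_type_ii_partial_positions(self):
        tone = make_tone(TimbreParams.stretched(2.1), 200.0)
        assert tone.frequencies[1] == pytest.approx(420.0)  # gamma**log2(2) * f0
        assert tone.frequencies[3] == pytest.approx(200.0 * 2.1**2)

    def test_type_ii_gamma2_equals_type_i(self):
        a = make_tone(TimbreParams.harmonic(n_harmonics=8, roll_off=5.0), 130.0)
        b = make_tone(TimbreParams.stretched(2.0, n_harmonics=8, roll_off=5.0), 130.0)
        np.testing.assert_allclose(a.frequencies, b.frequencies, rtol=1e-12)
        np.testing.assert_allclose(a.amplitudes, b.amplitudes, rtol=1e-12)

    def test_type_iii_pure(self):
        tone = make_tone(TimbreParams.pure(), 333.0)
        assert len(tone) == 1
        assert tone.frequencies[0] == 333.0
        assert tone.amplitudes[0] == 1.0

    def test_type_iv_third_deleted(self):
        full = make_tone(TimbreParams.five_equal(), 100.0)
        no3 = make_tone(TimbreParams.five_equal(include_third=False), 100.0)
        assert len(full) == 5
        assert len(no3) == 4
        assert 300.0 not in no3.frequencies
        assert np.all(full.amplitudes == 1.0)

    def test_type_v_bonang(self):
        tone = make_tone(TimbreParams.bonang(), 100.0)
        np.testing.assert_allclose(tone.frequencies, [100.0, 152.0, 346.0, 392.0])
        assert np.all(tone.amplitudes == 1.0)

    def test_custom_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TimbreParams.custom([1.0, 2.0], [1.0])

    def test_bad_f0(self):
        with pytest.raises(ValueError):
            make_tone(TimbreParams.pure(), 0.0)

    def test_gamma_bounds(self):
        with pytest.raises(ValueError):
            TimbreParams.stretched(3.0)


class TestChordSpectrum:
    def test_unison_pure_dyad_keeps_both_partials(self):
        spec = chord_spectrum(ChordSpec(60, (0.0,)), TimbreParams.pure())
        assert len(spec) == 2
        assert spec.frequencies[0] == spec.frequencies[1]

    def test_octave_alignment(self):
        spec = chord_spectrum(ChordSpec(60, (12.0,)), TimbreParams.harmonic())
        f = np.sort(spec.frequencies)
        # upper tone partial 1 == lower tone partial 2
        assert np.sum(np.isclose(spec.frequencies, 2 * midi_to_freq(60))) == 2
        assert len(spec) == 20

    def test_mixed_timbre_study2c_partial_count(self):
        # four equally weighted harmonics (lower) + idealized bonang (upper)
        spec = chord_spectrum(
            ChordSpec(60, (7.0,)),
            [
                TimbreParams.custom([1, 2, 3, 4], [1, 1, 1, 1]),
                TimbreParams.bonang(),
            ],
        )
        assert len(spec) == 8

    def test_partial_count_additive(self):
        spec = chord_spectrum(
            ChordSpec(48, (4.0, 3.0)),
            [TimbreParams.harmonic(6), TimbreParams.pure(), TimbreParams.bonang()],
        )
        assert len(spec) == 6 + 1 + 4

    def test_timbre_count_mismatch(self):
        with pytest.raises(ValueError):
            chord_spectrum(ChordSpec(60, (7.0,)), [TimbreParams.pure()] * 3)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            ChordSpec(60, (-1.0,))


class TestRenderAudio:
    def test_empty_spectrum_is_silence(self):
        env = EnvelopeParams()
        samples = render_audio(ToneSpectrum(np.empty(0), np.empty(0)), env, 8000)
        assert samples.shape == (int(round(1.33 * 8000)),)
        assert np.all(samples == 0)

    def test_default_duration(self):
        assert EnvelopeParams().duration == pytest.approx(1.33)

    def test_single_partial_spectral_peak(self):
        sr = 8000
        env = EnvelopeParams(attack=0, decay=0, sustain=1.0, release=0, decay_level=1.0)
        samples = render_audio(ToneSpectrum([440.0], [1.0]), env, sr)
        mags = np.abs(np.fft.rfft(samples))
        peak_hz = np.fft.rfftfreq(samples.size, 1 / sr)[np.argmax(mags)]
        assert peak_hz == pytest.approx(440.0, abs=2.0)

    def test_peak_bounded(self):
        spec = chord_spectrum(ChordSpec(60, (7.0,)), TimbreParams.harmonic())
        samples = render_audio(spec, EnvelopeParams(), 16000)
        assert np.max(np.abs(samples)) <= 1.0 + 1e-12

    def test_nyquist_partials_dropped(self):
        with pytest.warns(UserWarning):
            samples = render_audio(
                ToneSpectrum([100.0, 5000.0], [1.0, 1.0]), EnvelopeParams(), 8000
            )
        assert np.max(np.abs(samples)) > 0  # the 100 Hz partial survived

    def test_envelope_attack_is_linear(self):
        env = EnvelopeParams()
        e = adsr_envelope(env, 1000)
        attack = e[:200]
        assert np.allclose(np.diff(attack), np.diff(attack)[0], atol=1e-9)
        assert attack[-1] <= 1.0


class TestBeatRate:
    def test_major_third_fast_beats(self):
        c4, e4 = midi_to_freq(60), midi_to_freq(64)
        assert round(beat_rate(5 * c4, 4 * e4), 2) == 10.38

    def test_perfect_fifth_slow_beats(self):
        c4, g4 = midi_to_freq(60), midi_to_freq(67)
        assert round(beat_rate(3 * c4, 2 * g4), 2) == 0.89

    def test_identical(self):
        assert beat_rate(440.0, 440.0) == 0.0

    def test_positive_required(self):
        with pytest.raises(ValueError):
            beat_rate(-1.0, 440.0)


class TestEstimateInstrumentSpectrum:
    SR = 22050

    def _render_flat(self, timbre, f0, dur=0.6):
        env = EnvelopeParams(attack=0, decay=0, sustain=dur, release=0, decay_level=1.0)
        tone = make_tone(timbre, f0)
        return render_audio(tone, env, self.SR)

    def test_pure_tone_concentrates_at_first_harmonic(self):
        f0 = midi_to_freq(60)
        wav = self._render_flat(TimbreParams.pure(), f0)
        est = estimate_instrument_spectrum(wav, self.SR, f0, n_harmonics=5)
        amps = dict(zip(np.round(est.frequencies / f0).astype(int), est.amplitudes))
        a1 = amps.get(1, 0.0)
        assert a1 > 0
        for h in range(2, 6):
            assert amps.get(h, 0.0) < 0.05 * a1

    def test_type_i_rolloff_recovered(self):
        f0 = midi_to_freq(60)
        wav = self._render_flat(TimbreParams.harmonic(roll_off=3.0), f0)
        est = estimate_instrument_spectrum(wav, self.SR, f0, n_harmonics=5)
        recovered = np.zeros(5)
        for f, a in zip(est.frequencies, est.amplitudes):
            recovered[int(round(f / f0)) - 1] = a
        expected = 10 ** (-3.0 * np.log2(np.arange(1, 6)) / 20.0)
        rel = recovered / recovered[0]
        assert np.all(np.abs(rel - expected) / expected < 0.10)

    def test_monotone_decreasing_weights(self):
        f0 = midi_to_freq(62)
        wav = self._render_flat(TimbreParams.harmonic(roll_off=6.0, n_harmonics=6), f0)
        est = estimate_instrument_spectrum(wav, self.SR, f0, n_harmonics=6)
        order = np.argsort(est.frequencies)
        assert np.all(np.diff(est.amplitudes[order]) < 0)

    def test_zero_waveform(self):
        est = estimate_instrument_spectrum(np.zeros(4096), self.SR, 261.6)
        assert len(est) == 0

    def test_f0_out_of_span(self):
        with pytest.raises(ValueError):
            estimate_instrument_spectrum(np.zeros(1024), self.SR, 5.0)
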