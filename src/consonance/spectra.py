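"""Additive-synthesis tone spectra, pitch/frequency mapping, and audio rendering.

A tone is represented as a bag of partials (frequency in Hz, linear
amplitude).  Chords are specified intervallically: a bass pitch on the MIDI
scale plus a list of semitone intervals, each measured from the tone
immediately below.  Five parametric tone families are supported:

* ``harmonic``   -- n integer harmonics with a dB/octave roll-off
* ``stretched``  -- harmonics repositioned as f0 * gamma**log2(i+1)
* ``pure``       -- a single sinusoid
* ``five_equal`` -- five unit-weight harmonics, optionally without the 3rd
* ``bonang``     -- inharmonic gong partials at ratios 1 : 1.52 : 3.46 : 3.92
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ToneSpectrum",
    "ToneType",
    "TimbreParams",
    "ChordSpec",
    "EnvelopeParams",
    "midi_to_freq",
    "freq_to_midi",
    "make_tone",
    "chord_spectrum",
    "render_audio",
    "adsr_envelope",
    "write_wav",
    "beat_rate",
    "estimate_instrument_spectrum",
]

BONANG_RATIOS = (1.0, 1.52, 3.46, 3.92)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToneSpectrum:
    """A set of partials: parallel arrays of frequencies (Hz) and amplitudes.

    Frequencies and amplitudes must be strictly positive.  Ordering carries
    no meaning; coincident partials are kept as separate entries.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        freqs = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if freqs.shape != amps.shape:
            raise ValueError("frequencies and amplitudes must have equal length")
        if freqs.size and (not np.all(np.isfinite(freqs)) or np.any(freqs <= 0)):
            raise ValueError("partial frequencies must be finite and > 0")
        if amps.size and (not np.all(np.isfinite(amps)) or np.any(amps <= 0)):
            raise ValueError("partial amplitudes must be finite and > 0")
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "amplitudes", amps)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def partials(self) -> list[tuple[float, float]]:
        return list(zip(self.frequencies.tolist(), self.amplitudes.tolist()))

    def scaled(self, factor: float) -> "ToneSpectrum":
        return ToneSpectrum(self.frequencies, self.amplitudes * factor)

    @staticmethod
    def concat(spectra: Sequence["ToneSpectrum"]) -> "ToneSpectrum":
        return ToneSpectrum(
            np.concatenate([s.frequencies for s in spectra]),
            np.concatenate([s.amplitudes for s in spectra]),
        )


class ToneType(str, Enum):
    HARMONIC = "harmonic"
    STRETCHED = "stretched"
    PURE = "pure"
    FIVE_EQUAL = "five_equal"
    BONANG = "bonang"
    CUSTOM = "custom"


@dataclass(frozen=True)
class TimbreParams:
    """Parameters generating a tone spectrum from a fundamental frequency."""

    tone_type: ToneType = ToneType.HARMONIC
    n_harmonics: int = 10
    roll_off: float = 3.0  # dB/octave
    gamma: float = 2.0  # partial-spacing stretch factor
    include_third: bool = True  # five_equal only
    custom_ratios: tuple[float, ...] | None = None
    custom_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.roll_off < 0:
            raise ValueError("roll_off must be >= 0")
        if self.tone_type is ToneType.STRETCHED and not (1.5 <= self.gamma <= 2.5):
            raise ValueError("gamma must lie in [1.5, 2.5]")
        if self.tone_type is ToneType.CUSTOM:
            if self.custom_ratios is None or self.custom_weights is None:
                raise ValueError("custom timbre requires ratios and weights")
            if len(self.custom_ratios) != len(self.custom_weights):
                raise ValueError("custom ratios/weights length mismatch")

    # Convenience constructors -------------------------------------------

    @classmethod
    def harmonic(cls, n_harmonics: int = 10, roll_off: float = 3.0) -> "TimbreParams":
        return cls(ToneType.HARMONIC, n_harmonics=n_harmonics, roll_off=roll_off)

    @classmethod
    def stretched(
        cls, gamma: float, n_harmonics: int = 10, roll_off: float = 3.0
    ) -> "TimbreParams":
        return cls(
            ToneType.STRETCHED, n_harmonics=n_harmonics, roll_off=roll_off, gamma=gamma
        )

    @classmethod
    def pure(cls) -> "TimbreParams":
        return cls(ToneType.PURE, n_harmonics=1)

    @classmethod
    def five_equal(cls, include_third: bool = True) -> "TimbreParams":
        return cls(ToneType.FIVE_EQUAL, n_harmonics=5, include_third=include_third)

    @classmethod
    def bonang(cls) -> "TimbreParams":
        return cls(ToneType.BONANG, n_harmonics=4)

    @classmethod
    def custom(
        cls, ratios: Sequence[float], weights: Sequence[float]
    ) -> "TimbreParams":
        return cls(
            ToneType.CUSTOM,
            n_harmonics=len(tuple(ratios)),
            custom_ratios=tuple(ratios),
            custom_weights=tuple(weights),
        )


@dataclass(frozen=True)
class ChordSpec:
    """Intervallic chord: bass MIDI pitch plus cumulative semitone intervals."""

    bass_pitch: float
    intervals: tuple[float, ...] = ()

    def __post_init__(self):
        intervals = tuple(float(i) for i in np.atleast_1d(self.intervals))
        if any(i < 0 for i in intervals):
            raise ValueError("intervals must be >= 0")
        object.__setattr__(self, "intervals", intervals)

    @property
    def pitches(self) -> np.ndarray:
        """Absolute MIDI pitches: bass, bass+i1, bass+i1+i2, ..."""
        return self.bass_pitch + np.concatenate(([0.0], np.cumsum(self.intervals)))

    @property
    def n_tones(self) -> int:
        return len(self.intervals) + 1


@dataclass(frozen=True)
class EnvelopeParams:
    """ADSR envelope: 200 ms linear attack to 1.0, 100 ms exponential decay
    to 0.8, 30 ms sustain, 1 s exponential release."""

    attack: float = 0.200
    attack_level: float = 1.0
    decay: float = 0.100
    decay_level: float = 0.8
    sustain: float = 0.030
    release: float = 1.0

    def __post_init__(self):
        for name in ("attack", "decay", "sustain", "release"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} duration must be >= 0")

    @property
    def duration(self) -> float:
        return self.attack + self.decay + self.sustain + self.release


# ---------------------------------------------------------------------------
# Pitch <-> frequency
# ---------------------------------------------------------------------------


def midi_to_freq(p: float | np.ndarray) -> float | np.ndarray:
    """Frequency in Hz of MIDI pitch ``p`` (A4 = 69 = 440 Hz).

    Accepts real-valued (non-integer) pitches and arrays.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("MIDI pitch must be finite")
    f = 440.0 * 2.0 ** ((p - 69.0) / 12.0)
    return float(f) if f.ndim == 0 else f


def freq_to_midi(f: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`midi_to_freq`."""
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("frequency must be finite and > 0")
    p = 69.0 + 12.0 * np.log2(f / 440.0)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------


def _rolloff_weights(n: int, roll_off: float) -> np.ndarray:
    # w_i = 10**(-omega_i/20), omega_i = roll_off * log2(i+1), i = 0..n-1
    i = np.arange(n, dtype=float)
    return 10.0 ** (-(roll_off * np.log2(i + 1.0)) / 20.0)


def make_tone(timbre: TimbreParams, f0: float) -> ToneSpectrum:
    """Generate the partials of a single tone with fundamental ``f0``."""
    if not np.isfinite(f0) or f0 <= 0:
        raise ValueError("f0 must be finite and > 0")
    t = timbre.tone_type
    if t is ToneType.HARMONIC:
        i = np.arange(timbre.n_harmonics, dtype=float)
        freqs = f0 * (i + 1.0)
        weights = _rolloff_weights(timbre.n_harmonics, timbre.roll_off)
    elif t is ToneType.STRETCHED:
        i = np.arange(timbre.n_harmonics, dtype=float)
        freqs = f0 * timbre.gamma ** np.log2(i + 1.0)
        weights = _rolloff_weights(timbre.n_harmonics, timbre.roll_off)
    elif t is ToneType.PURE:
        freqs = np.array([f0])
        weights = np.array([1.0])
    elif t is ToneType.FIVE_EQUAL:
        i = np.arange(5, dtype=float)
        freqs = f0 * (i + 1.0)
        weights = np.ones(5)
        if not timbre.include_third:
            keep = i != 2  # zero-weight partials are dropped outright
            freqs, weights = freqs[keep], weights[keep]
    elif t is ToneType.BONANG:
        freqs = f0 * np.asarray(BONANG_RATIOS)
        weights = np.ones(len(BONANG_RATIOS))
    elif t is ToneType.CUSTOM:
        freqs = f0 * np.asarray(timbre.custom_ratios, dtype=float)
        weights = np.asarray(timbre.custom_weights, dtype=float)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown tone type: {t}")
    return ToneSpectrum(freqs, weights)


def chord_spectrum(
    chord: ChordSpec,
    timbres: TimbreParams | Sequence[TimbreParams],
) -> ToneSpectrum:
    """Union of per-tone partials for an intervallic chord.

    ``timbres`` is either one TimbreParams (broadcast to all tones) or one
    per chord tone.  Coincident partials are retained as separate entries.
    """
    if isinstance(timbres, TimbreParams):
        timbres = [timbres] * chord.n_tones
    timbres = list(timbres)
    if len(timbres) != chord.n_tones:
        raise ValueError(
            f"expected {chord.n_tones} timbres (or one to broadcast), "
            f"got {len(timbres)}"
        )
    tones = [
        make_tone(tb, midi_to_freq(p)) for tb, p in zip(timbres, chord.pitches)
    ]
    return ToneSpectrum.concat(tones)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def adsr_envelope(env: EnvelopeParams, sample_rate: float) -> np.ndarray:
    """Sampled ADSR envelope.

    Attack is linear; decay and release are exponential approaches with a
    time constant of one fifth of the segment duration.
    """
    n = int(round(env.duration * sample_rate))
    out = np.zeros(n)
    t = np.arange(n) / sample_rate
    a, d, s = env.attack, env.decay, env.sustain
    seg = t < a
    if a > 0:
        out[seg] = env.attack_level * t[seg] / a
    seg = (t >= a) & (t < a + d)
    if np.any(seg):
        tau = d / 5.0 if d > 0 else 1.0
        out[seg] = env.decay_level + (env.attack_level - env.decay_level) * np.exp(
            -(t[seg] - a) / tau
        )
    seg = (t >= a + d) & (t < a + d + s)
    out[seg] = env.decay_level
    seg = t >= a + d + s
    if np.any(seg) and env.release > 0:
        tau = env.release / 5.0
        out[seg] = env.decay_level * np.exp(-(t[seg] - (a + d + s)) / tau)
    return out


def render_audio(
    spectrum: ToneSpectrum | None,
    env: EnvelopeParams | None = None,
    sample_rate: float = 44100.0,
) -> np.ndarray:
    """Render a spectrum to mono samples: sum of sinusoids times the ADSR
    envelope, scaled so the peak absolute sample does not exceed 1.

    Partials at or above the Nyquist frequency are dropped with a warning.
    An empty spectrum yields silence of the correct length.
    """
    env = env or EnvelopeParams()
    n = int(round(env.duration * sample_rate))
    if spectrum is None or len(spectrum) == 0:
        return np.zeros(n)
    nyquist = sample_rate / 2.0
    keep = spectrum.frequencies < nyquist
    if not np.all(keep):
        dropped = int(np.sum(~keep))
        warnings.warn(
            f"dropping {dropped} partial(s) at/above Nyquist ({nyquist:.0f} Hz)"
        )
        logger.warning("dropped %d aliasing partial(s)", dropped)
    freqs = spectrum.frequencies[keep]
    amps = spectrum.amplitudes[keep]
    if freqs.size == 0:
        return np.zeros(n)
    t = np.arange(n) / sample_rate
    signal = np.sin(2.0 * np.pi * np.outer(t, freqs)) @ amps
    signal *= adsr_envelope(env, sample_rate)
    peak = np.max(np.abs(signal))
    if peak > 1.0:
        signal /= peak
    return signal


def write_wav(
    path,
    samples: np.ndarray,
    sample_rate: int = 44100,
    dtype: str = "float32",
) -> None:
    """Write mono samples to a WAV file (float32 or int16 PCM)."""
    from scipy.io import wavfile

    samples = np.asarray(samples)
    if dtype == "float32":
        data = samples.astype(np.float32)
    elif dtype == "int16":
        data = np.round(np.clip(samples, -1.0, 1.0) * 32767).astype(np.int16)
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")
    wavfile.write(path, int(sample_rate), data)


# ---------------------------------------------------------------------------
# Beats
# ---------------------------------------------------------------------------


def beat_rate(f_a: float, f_b: float) -> float:
    """Beat rate |f_a - f_b| in Hz between two partials."""
    if f_a <= 0 or f_b <= 0:
        raise ValueError("frequencies must be > 0")
    return abs(float(f_a) - float(f_b))


# ---------------------------------------------------------------------------
# Spectrum estimation from recorded audio
# ---------------------------------------------------------------------------

FILTERBANK_LOW_MIDI = 15.0
FILTERBANK_HIGH_MIDI = 119.0
FILTERBANK_SPACING = 0.5  # semitones between centers; 50% overlap
ENVELOPE_COMPRESSION = 0.3
ENVELOPE_RATE = 400.0  # Hz
SMOOTHER_SIGMA_HZ = 1.598


def _cosine_filterbank(freqs_hz: np.ndarray, centers_midi: np.ndarray) -> np.ndarray:
    """Cosine filters on the MIDI scale: full width one semitone so that
    0.5-semitone spacing gives 50% overlap. Returns (n_filters, n_freqs)."""
    with np.errstate(divide="ignore"):
        midi = np.where(
            freqs_hz > 0, 69.0 + 12.0 * np.log2(np.maximum(freqs_hz, 1e-12) / 440.0), -np.inf
        )
    d = midi[None, :] - centers_midi[:, None]
    resp = np.zeros_like(d)
    inside = np.abs(d) <= FILTERBANK_SPACING  # excludes the -inf DC bin
    resp[inside] = np.cos(np.pi * d[inside] / (2.0 * FILTERBANK_SPACING))
    return resp


def estimate_instrument_spectrum(
    waveform: np.ndarray,
    sample_rate: float,
    f0: float,
    n_harmonics: int = 20,
) -> ToneSpectrum:
    """Estimate harmonic amplitudes of a recorded instrument tone.

    The signal is passed through an array of cosine filters equally spaced
    on the MIDI scale (0.5-semitone spacing, 50% overlap, spanning 15-119
    semitones).  Each filter's temporal envelope is the modulus of its
    analytic signal, compressed by s**0.3, resampled to 400 Hz, and
    expanded back by s**(1/0.3).  Amplitudes at the harmonic frequencies
    f0, 2*f0, ..., n*f0 are read off with a Gaussian kernel smoother
    (sigma = 1.598 Hz) over the filter center frequencies, time-averaging
    each envelope to a single value.

    Harmonics whose amplitude comes out nonpositive are omitted from the
    returned spectrum; an all-zero waveform yields an empty partial list
    represented as amplitudes of exactly zero via an empty ToneSpectrum.
    """
    from scipy import signal as sps

    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    f0_midi = freq_to_midi(f0)
    if not (FILTERBANK_LOW_MIDI <= f0_midi <= FILTERBANK_HIGH_MIDI):
        raise ValueError("f0 outside the 15-119 MIDI filterbank span")

    centers_midi = np.arange(
        FILTERBANK_LOW_MIDI, FILTERBANK_HIGH_MIDI + 1e-9, FILTERBANK_SPACING
    )
    centers_hz = midi_to_freq(centers_midi)

    n = waveform.size
    spec = np.fft.rfft(waveform)
    fft_freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)

    harmonic_freqs = f0 * np.arange(1, n_harmonics + 1, dtype=float)

    # Restrict to filters with meaningful smoother weight for some harmonic,
    # to avoid filtering the signal 209 times when ~40 filters matter.
    w = np.exp(
        -0.5
        * ((centers_hz[:, None] - harmonic_freqs[None, :]) / SMOOTHER_SIGMA_HZ) ** 2
    )
    active = np.where(w.max(axis=1) > 1e-12)[0]
    if active.size == 0:
        active = np.arange(centers_hz.size)

    responses = _cosine_filterbank(fft_freqs, centers_midi[active])

    up, down = 400, int(round(sample_rate))
    g = math.gcd(up, down)
    up //= g
    down //= g

    mean_env = np.zeros(centers_hz.size)
    for row, idx in enumerate(active):
        band = spec * responses[row]
        envelope = np.abs(sps.hilbert(np.fft.irfft(band, n=n)))
        compressed = envelope ** ENVELOPE_COMPRESSION
        resampled = sps.resample_poly(compressed, up, down)
        expanded = np.maximum(resampled, 0.0) ** (1.0 / ENVELOPE_COMPRESSION)
        mean_env[idx] = float(np.mean(expanded))

    # Gaussian kernel smoother over filter center frequencies (Hz)
    amps = np.zeros(n_harmonics)
    for k, hf in enumerate(harmonic_freqs):
        weights = np.exp(-0.5 * ((centers_hz - hf) / SMOOTHER_SIGMA_HZ) ** 2)
        total = weights.sum()
        if total > 1e-300:
            amps[k] = float(weights @ mean_env / total)

    keep = amps > 0
    if not np.any(keep):
        # all-zero waveform: represent as empty spectrum
        return ToneSpectrum(np.empty(0), np.empty(0))
    return ToneSpectrum(harmonic_freqs[keep], amps[keep])
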