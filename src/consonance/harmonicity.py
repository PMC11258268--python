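"""Template-matching harmonicity models in pitch-class space.

A chord spectrum is folded into the octave as a circular pitch-class
spectrum (Gaussian smearing of each partial, weighted by its amplitude).
Cosine similarity against every circular transposition of an idealized
harmonic template yields a virtual-pitch-strength profile.  Two summary
scores are provided:

* ``harmonicity_hp`` -- Kullback-Leibler divergence of the normalized
  profile from a uniform distribution (high divergence = clear pitch =
  high harmonicity);
* ``harmonicity_milne`` -- the height of the profile's highest peak.

The smear width (6.83 cents), template harmonic count (12) and template
roll-off (3 dB/octave) are conventional defaults and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import TimbreParams, ToneSpectrum, freq_to_midi, make_tone

__all__ = [
    "PitchClassSpectrum",
    "VirtualPitchProfile",
    "DEFAULT_RESOLUTION",
    "DEFAULT_SMEAR_SD",
    "pc_spectrum",
    "harmonic_template",
    "virtual_pitch_profile",
    "harmonicity_hp",
    "harmonicity_milne",
    "harmonicity_score",
]

DEFAULT_RESOLUTION = 1200  # bins per octave (1-cent bins)
DEFAULT_SMEAR_SD = 6.83  # cents
TEMPLATE_N_HARMONICS = 12
TEMPLATE_ROLL_OFF = 3.0
_TRUNCATE_SD = 6.0


@dataclass(frozen=True)
class PitchClassSpectrum:
    """Nonnegative weights over [0, 12) semitones on a circular grid."""

    weights: np.ndarray
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != self.resolution:
            raise ValueError("weights must be a vector of length `resolution`")
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        object.__setattr__(self, "weights", w)

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centers in semitones on [0, 12)."""
        return np.arange(self.resolution) * (12.0 / self.resolution)


@dataclass(frozen=True)
class VirtualPitchProfile:
    """Virtual pitch strength per candidate pitch-class transposition."""

    strengths: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        s = np.asarray(self.strengths, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("strengths must be a nonempty vector")
        if np.any(s < -1e-12):
            raise ValueError("strengths must be >= 0")
        object.__setattr__(self, "strengths", np.maximum(s, 0.0))

    def as_distribution(self) -> np.ndarray:
        total = self.strengths.sum()
        if total <= 0:
            raise ValueError("profile has zero total mass")
        return self.strengths / total


def _circular_gaussian_deposit(
    positions_st: np.ndarray,
    amplitudes: np.ndarray,
    sd_st: float,
    resolution: int,
) -> np.ndarray:
    bins = np.arange(resolution) * (12.0 / resolution)
    d = np.abs(bins[None, :] - positions_st[:, None])
    d = np.minimum(d, 12.0 - d)  # wrap around the octave
    bump = np.exp(-0.5 * (d / sd_st) ** 2)
    bump[d > _TRUNCATE_SD * sd_st] = 0.0
    return amplitudes @ bump


def pc_spectrum(
    spectrum: ToneSpectrum,
    smear_sd: float = DEFAULT_SMEAR_SD,
    resolution: int = DEFAULT_RESOLUTION,
) -> PitchClassSpectrum:
    """Fold a spectrum into pitch-class space.

    Each partial maps to pitch class (MIDI pitch mod 12) and deposits a
    circular Gaussian of sd ``smear_sd`` cents, scaled by its amplitude;
    contributions add.
    """
    if len(spectrum) == 0:
        raise ValueError("spectrum must contain at least one partial")
    if smear_sd <= 0:
        raise ValueError("smear_sd must be > 0")
    pcs = np.mod(freq_to_midi(spectrum.frequencies), 12.0)
    weights = _circular_gaussian_deposit(
        np.atleast_1d(pcs), spectrum.amplitudes, smear_sd / 100.0, resolution
    )
    return PitchClassSpectrum(weights, resolution)


def harmonic_template(
    n_harmonics: int = TEMPLATE_N_HARMONICS,
    roll_off: float = TEMPLATE_ROLL_OFF,
    smear_sd: float = DEFAULT_SMEAR_SD,
    resolution: int = DEFAULT_RESOLUTION,
) -> PitchClassSpectrum:
    """Pitch-class spectrum of an idealized harmonic complex tone with its
    fundamental at pitch class 0."""
    tone = make_tone(
        TimbreParams.harmonic(n_harmonics=n_harmonics, roll_off=roll_off),
        440.0 * 2.0 ** (3.0 / 12.0),  # any pitch-class-0 fundamental (C)
    )
    return pc_spectrum(tone, smear_sd=smear_sd, resolution=resolution)


def virtual_pitch_profile(
    chord_pc: PitchClassSpectrum, template: PitchClassSpectrum
) -> VirtualPitchProfile:
    """Cosine similarity of the chord spectrum with every circular
    transposition of the template; computed via FFT cross-correlation."""
    if chord_pc.resolution != template.resolution:
        raise ValueError("resolution mismatch between chord and template")
    c = chord_pc.weights
    t = template.weights
    nc = np.linalg.norm(c)
    nt = np.linalg.norm(t)
    if nc == 0 or nt == 0:
        raise ValueError("chord or template spectrum has zero mass")
    # dot(c, roll(t, k)) for all k
    dots = np.fft.irfft(
        np.fft.rfft(c) * np.conj(np.fft.rfft(t)), n=c.size
    )
    return VirtualPitchProfile(np.clip(dots / (nc * nt), 0.0, 1.0))


def harmonicity_hp(profile: VirtualPitchProfile) -> float:
    """KL divergence (nats) of the normalized profile from uniform:
    log(n) - H(P).  Zero iff uniform; log(n) for a one-hot profile."""
    p = profile.as_distribution()
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    return float(np.log(p.size) - entropy)


def harmonicity_milne(profile: VirtualPitchProfile) -> float:
    """Height of the highest peak of the virtual-pitch profile."""
    return float(np.max(profile.strengths))


def harmonicity_hp_batch(
    freqs: np.ndarray,
    amps: np.ndarray,
    template: PitchClassSpectrum,
    smear_sd: float = DEFAULT_SMEAR_SD,
    chunk: int = 128,
) -> np.ndarray:
    """Vectorized KL-harmonicity for a batch of spectra sharing one
    amplitude vector: ``freqs`` is (B, N), ``amps`` is (N,).

    Equivalent to the spectrum-at-a-time pipeline (asserted in the test
    suite); used on dense profile grids and GSP utility grids.
    """
    freqs = np.asarray(freqs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    res = template.resolution
    bin_step = 12.0 / res
    sd_st = smear_sd / 100.0
    half = int(np.ceil(_TRUNCATE_SD * sd_st / bin_step))
    offsets = np.arange(-half, half + 1)
    t = template.weights
    t_fft = np.conj(np.fft.rfft(t))
    nt = np.linalg.norm(t)
    out = np.empty(freqs.shape[0])
    logn = np.log(res)
    n_partials = freqs.shape[1]
    for lo in range(0, freqs.shape[0], chunk):
        fb = freqs[lo : lo + chunk]
        b = fb.shape[0]
        pcs = np.mod(freq_to_midi(fb), 12.0)  # (b, N)
        # deposit only the +/-6 sd window around each partial
        center = np.rint(pcs / bin_step).astype(int)  # (b, N)
        idx = np.mod(center[:, :, None] + offsets[None, None, :], res)
        d = np.abs(
            (center[:, :, None] + offsets[None, None, :]) * bin_step - pcs[:, :, None]
        )
        d = np.minimum(d, 12.0 - d)
        bump = np.exp(-0.5 * (d / sd_st) ** 2)
        bump[d > _TRUNCATE_SD * sd_st] = 0.0
        bump *= amps[None, :, None]
        rows = np.broadcast_to(
            np.arange(b)[:, None, None], idx.shape
        )
        weights = np.bincount(
            (rows * res + idx).ravel(), weights=bump.ravel(), minlength=b * res
        ).reshape(b, res)
        dots = np.fft.irfft(np.fft.rfft(weights, axis=1) * t_fft[None, :], n=res, axis=1)
        norms = np.linalg.norm(weights, axis=1)
        strengths = np.clip(dots / (norms[:, None] * nt), 0.0, 1.0)
        totals = strengths.sum(axis=1)
        p = strengths / totals[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        out[lo : lo + chunk] = logn + plogp.sum(axis=1)
    return out


def harmonicity_score(
    spectrum: ToneSpectrum,
    kind: str = "hp",
    template: PitchClassSpectrum | None = None,
    smear_sd: float = DEFAULT_SMEAR_SD,
    resolution: int = DEFAULT_RESOLUTION,
) -> float:
    """Convenience wrapper: spectrum -> pitch-class fold -> template match
    -> summary score (``kind`` in {'hp', 'milne'})."""
    if template is None:
        template = harmonic_template(smear_sd=smear_sd, resolution=resolution)
    chord_pc = pc_spectrum(spectrum, smear_sd=smear_sd, resolution=template.resolution)
    profile = virtual_pitch_profile(chord_pc, template)
    if kind == "hp":
        return harmonicity_hp(profile)
    if kind == "milne":
        return harmonicity_milne(profile)
    raise ValueError("kind must be 'hp' or 'milne'")
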