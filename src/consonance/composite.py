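"""Composite consonance model: weighted sum of the revised interference
model and the KL-uncertainty harmonicity model.

Weights default to -1 (interference) and +0.837 (harmonicity), applied to
the raw component outputs; profiles are median-normalized afterwards so
that scores are comparable within an experiment.  Higher = more consonant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import harmonicity as hm
from .interference import DissonanceParams, dissonance_revised, dissonance_revised_batch
from .spectra import ChordSpec, TimbreParams, ToneSpectrum, chord_spectrum, make_tone, midi_to_freq

__all__ = [
    "CompositeParams",
    "DEFAULT_COMPOSITE_PARAMS",
    "composite_score",
    "composite_scores_batch",
    "normalize_profile",
    "dyad_profile",
    "composite_profile",
]


@dataclass(frozen=True)
class CompositeParams:
    w_interference: float = -1.0
    w_harmonicity: float = 0.837
    dissonance_params: DissonanceParams = field(default_factory=DissonanceParams)

    def __post_init__(self):
        if not (np.isfinite(self.w_interference) and np.isfinite(self.w_harmonicity)):
            raise ValueError("weights must be finite")


DEFAULT_COMPOSITE_PARAMS = CompositeParams()


def composite_score(
    spectrum: ToneSpectrum,
    params: CompositeParams = DEFAULT_COMPOSITE_PARAMS,
    template: hm.PitchClassSpectrum | None = None,
) -> float:
    """w_i * revised dissonance + w_h * KL harmonicity for one spectrum.

    Pass a precomputed ``template`` when scoring many chords to avoid
    rebuilding the harmonic template each call.
    """
    score = 0.0
    if params.w_interference != 0.0:
        score += params.w_interference * dissonance_revised(
            spectrum, params.dissonance_params
        )
    if params.w_harmonicity != 0.0:
        score += params.w_harmonicity * hm.harmonicity_score(
            spectrum, kind="hp", template=template
        )
    return score


def normalize_profile(values: np.ndarray) -> np.ndarray:
    """Median-normalize: subtract the median so the output median is 0."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty profile")
    return values - np.median(values)


def dyad_profile(
    score_fn: Callable[[ToneSpectrum], float],
    intervals: np.ndarray,
    timbres: TimbreParams | Sequence[TimbreParams],
    bass: float = 60.0,
) -> np.ndarray:
    """Evaluate any spectrum-scoring function over a grid of dyad intervals
    above a fixed bass pitch."""
    intervals = np.asarray(intervals, dtype=float)
    out = np.empty(intervals.size)
    for k, iv in enumerate(intervals.ravel()):
        spec = chord_spectrum(ChordSpec(bass, (iv,)), timbres)
        out[k] = score_fn(spec)
    return out.reshape(intervals.shape)


def composite_scores_batch(
    pitch_matrix: np.ndarray,
    timbres: TimbreParams | Sequence[TimbreParams],
    params: CompositeParams = DEFAULT_COMPOSITE_PARAMS,
    template: hm.PitchClassSpectrum | None = None,
) -> np.ndarray:
    """Composite scores for a batch of chords sharing a timbre layout.

    ``pitch_matrix`` is (B, T) absolute MIDI pitches; ``timbres`` is one
    TimbreParams (broadcast) or one per tone.  All chords share the same
    per-tone partial ratios and weights, so amplitudes are constant across
    the batch and the heavy work vectorizes.  Row-by-row equivalent to
    :func:`composite_score` on the corresponding spectra.
    """
    pitch_matrix = np.atleast_2d(np.asarray(pitch_matrix, dtype=float))
    n_tones = pitch_matrix.shape[1]
    if isinstance(timbres, TimbreParams):
        timbres = [timbres] * n_tones
    if len(timbres) != n_tones:
        raise ValueError("one timbre per chord tone (or a single broadcast)")
    # unit-f0 tones give the frequency ratios / weights of each voice
    unit_tones = [make_tone(tb, 1.0) for tb in timbres]
    f0s = midi_to_freq(pitch_matrix)  # (B, T)
    freqs = np.concatenate(
        [f0s[:, t : t + 1] * unit_tones[t].frequencies[None, :] for t in range(n_tones)],
        axis=1,
    )
    amps = np.concatenate([tone.amplitudes for tone in unit_tones])
    if template is None:
        template = hm.harmonic_template()
    scores = np.zeros(pitch_matrix.shape[0])
    if params.w_interference != 0.0:
        scores += params.w_interference * dissonance_revised_batch(
            freqs, amps, params.dissonance_params
        )
    if params.w_harmonicity != 0.0:
        scores += params.w_harmonicity * hm.harmonicity_hp_batch(
            freqs, amps, template
        )
    return scores


def composite_profile(
    intervals: np.ndarray,
    timbres: TimbreParams | Sequence[TimbreParams],
    bass: float = 60.0,
    params: CompositeParams = DEFAULT_COMPOSITE_PARAMS,
    normalize: bool = True,
) -> np.ndarray:
    """Composite-model scores over a dyad interval grid (optionally
    median-normalized)."""
    intervals = np.asarray(intervals, dtype=float)
    pitches = np.column_stack([np.full(intervals.size, bass), bass + intervals.ravel()])
    values = composite_scores_batch(pitches, timbres, params).reshape(intervals.shape)
    return normalize_profile(values) if normalize else values
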