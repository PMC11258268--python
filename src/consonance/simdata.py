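"""Synthetic dense-rating datasets with the structure the analysis expects.

A simulated rater carries a Gaussian participant intercept around a latent
consonance surface; each trial draws coordinates uniformly from the
stimulus range and a bass pitch uniformly from MIDI 55-65, adds trial
noise, and maps the latent value onto the 1-7 scale by clipping the latent
z to [-2.5, 2.5], rescaling affinely to [1, 7], and rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .composite import CompositeParams, composite_profile
from .spectra import TimbreParams

__all__ = [
    "RaterModel",
    "likert_map",
    "surface_from_profile",
    "composite_surface",
    "simulate_dense_ratings",
    "simulate_tuning_study",
]

BASS_RANGE = (55.0, 65.0)
LIKERT_CLIP = 2.5


def likert_map(latent: np.ndarray) -> np.ndarray:
    """Monotone map from latent z to integer ratings in {1..7}."""
    z = np.clip(np.asarray(latent, dtype=float), -LIKERT_CLIP, LIKERT_CLIP)
    scaled = 1.0 + (z + LIKERT_CLIP) * (6.0 / (2.0 * LIKERT_CLIP))
    return np.clip(np.round(scaled), 1, 7).astype(int)


@dataclass(frozen=True)
class RaterModel:
    """Data-generating model for simulated dense-rating participants."""

    latent_surface: Callable[[np.ndarray], np.ndarray]
    participant_sd: float = 0.3
    noise_sd: float = 1.0
    n_participants: int = 200
    trials_per_participant: int = 40
    bass_range: tuple[float, float] = BASS_RANGE
    likert: Callable[[np.ndarray], np.ndarray] = likert_map

    def __post_init__(self):
        if self.participant_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_participants < 1 or self.trials_per_participant < 1:
            raise ValueError("need at least one participant and one trial")


def surface_from_profile(grid: np.ndarray, values: np.ndarray) -> Callable:
    """Latent surface by linear interpolation of a precomputed profile."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)

    def surface(coords: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(coords, dtype=float), grid, values)

    return surface


def composite_surface(
    coord_range: tuple[float, float],
    timbres: TimbreParams | Sequence[TimbreParams],
    bass: float = 60.0,
    params: CompositeParams | None = None,
    n_grid: int = 1000,
    scale: float = 1.0,
) -> Callable:
    """Median-normalized composite-model surface over an interval range,
    interpolated from an n_grid evaluation (fast enough to act as the
    latent surface for thousands of simulated trials)."""
    grid = np.linspace(*coord_range, n_grid)
    values = composite_profile(
        grid, timbres, bass=bass, params=params or CompositeParams()
    )
    return surface_from_profile(grid, scale * values)


def simulate_dense_ratings(
    model: RaterModel,
    coord_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulated trial-level ratings over a 1D interval range.

    Returns the ratings CSV schema the analysis module reads:
    participant_id, interval_1, bass_midi, rating.
    """
    lo, hi = coord_range
    if not lo < hi:
        raise ValueError("coord_range must be nonempty (low < high)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_p, n_t = model.n_participants, model.trials_per_participant
    intercepts = rng.normal(0.0, model.participant_sd, size=n_p)
    coords = rng.uniform(lo, hi, size=(n_p, n_t))
    bass = rng.uniform(*model.bass_range, size=(n_p, n_t))
    noise = rng.normal(0.0, model.noise_sd, size=(n_p, n_t))
    latent = model.latent_surface(coords) + intercepts[:, None] + noise
    ratings = model.likert(latent)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_p), n_t),
            "interval_1": coords.ravel(),
            "bass_midi": bass.ravel(),
            "rating": ratings.ravel(),
        }
    )


def simulate_tuning_study(
    model: RaterModel,
    center: float,
    halfwidth: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Dense ratings on a narrow tuning window [center - hw, center + hw]
    (downstream smoothing bandwidth: 0.035 semitones)."""
    if center <= halfwidth:
        raise ValueError("center must exceed halfwidth")
    return simulate_dense_ratings(
        model, (center - halfwidth, center + halfwidth), seed=seed
    )
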