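"""Peak-Jaccard model fit and gradient-free parameter optimization.

Model fit for one experiment is the Jaccard similarity between behavioral
profile peaks and composite-model profile peaks, where two peaks match if
they are separated by less than 2.67% of the experiment's interval range
(0.4 semitones on a 15-semitone range).  Matching is greedy one-to-one by
increasing distance.  The overall objective is the mean Jaccard across
experiments, maximized over (p, q, r, w_harmonicity) with a gradient-free
optimizer (Nelder-Mead restarts; the objective is piecewise constant, so
multi-start matters more than local polish).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .analysis import SmoothingConfig, model_profile
from .composite import CompositeParams, composite_profile
from .interference import DissonanceParams
from .peaks import PeakPickConfig, find_peaks
from .spectra import TimbreParams

__all__ = [
    "FitConfig",
    "Experiment",
    "DEFAULT_BOUNDS",
    "peak_jaccard",
    "fit_objective",
    "optimize",
]

OVERLAP_FRAC = 0.0267  # of the interval range
MODEL_BETA = 0.05  # sharpness beta for (deterministic) model profiles

# (low, high) per parameter; the published table is not reproduced here,
# these are configurable working bounds
DEFAULT_BOUNDS = {
    "p": (0.01, 0.5),
    "q": (0.0, 5.0),
    "r": (0.5, 3.0),
    "w_harmonicity": (0.0, 3.0),
}


@dataclass(frozen=True)
class FitConfig:
    overlap_frac: float = OVERLAP_FRAC
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    max_iter: int = 200
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.overlap_frac <= 0:
            raise ValueError("overlap_frac must be > 0")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}")


@dataclass(frozen=True)
class Experiment:
    """One dyad experiment: precomputed behavioral peak locations plus the
    stimulus configuration needed to regenerate model profiles."""

    behavioral_peaks: tuple[float, ...]
    timbres: TimbreParams | tuple[TimbreParams, ...]
    interval_range: tuple[float, float]
    bass: float = 60.0
    n_grid: int = 1000
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    @property
    def range_width(self) -> float:
        return self.interval_range[1] - self.interval_range[0]

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(*self.interval_range, self.n_grid)


def peak_jaccard(
    peaks_a: Sequence[float], peaks_b: Sequence[float], tol: float
) -> float:
    """Jaccard similarity of two peak-location sets under greedy one-to-one
    matching at distance < tol.

    J = m / (|A| + |B| - m); two empty sets agree perfectly (J = 1).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    a = np.asarray(list(peaks_a), dtype=float)
    b = np.asarray(list(peaks_b), dtype=float)
    if a.size == 0 and b.size == 0:
        return 1.0
    if a.size == 0 or b.size == 0:
        return 0.0
    pairs = [
        (abs(a[i] - b[j]), i, j)
        for i in range(a.size)
        for j in range(b.size)
        if abs(a[i] - b[j]) < tol
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    m = 0
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            m += 1
    return m / (a.size + b.size - m)


def model_peaks_for_experiment(
    experiment: Experiment,
    params: CompositeParams,
    peak_config: PeakPickConfig | None = None,
) -> np.ndarray:
    """Composite-model profile peaks for one experiment at candidate params.

    Model peaks use a raised sharpness beta (0.05) in place of the
    bootstrap filtering applied to behavioral peaks.  The +/-0.5-semitone
    sharpness window is kept fixed across interval ranges (pass a
    ``peak_config`` built with ``PeakPickConfig.scaled_to_range`` to
    rescale it for narrow tuning windows instead).
    """
    config = peak_config or PeakPickConfig(sharpness_beta=MODEL_BETA)
    grid = experiment.grid
    raw = composite_profile(
        grid, experiment.timbres, bass=experiment.bass, params=params
    )
    profile = model_profile(raw, grid, experiment.smoothing)
    return find_peaks(profile, config).locations


def _params_from_vector(theta: np.ndarray) -> CompositeParams:
    p, q, r, w_h = (float(v) for v in theta)
    return CompositeParams(
        w_interference=-1.0,
        w_harmonicity=w_h,
        dissonance_params=DissonanceParams(p=p, q=q, r=r),
    )


def fit_objective(
    theta: Sequence[float],
    experiments: Sequence[Experiment],
    config: FitConfig = FitConfig(),
    peak_config: PeakPickConfig | None = None,
) -> float:
    """Mean peak-Jaccard across experiments for candidate (p, q, r, w_h)."""
    if len(experiments) == 0:
        raise ValueError("need at least one experiment")
    params = _params_from_vector(np.asarray(theta, dtype=float))
    scores = []
    for exp in experiments:
        mp = model_peaks_for_experiment(exp, params, peak_config)
        tol = config.overlap_frac * exp.range_width
        scores.append(peak_jaccard(exp.behavioral_peaks, mp, tol))
    return float(np.mean(scores))


def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: FitConfig = FitConfig(),
    x0: np.ndarray | None = None,
) -> dict:
    """Maximize a gradient-free objective with seeded multi-start
    Nelder-Mead inside box bounds.

    Returns {'x', 'value', 'n_eval', 'trace'}; the trace records the
    best-so-far objective after each evaluation (non-decreasing).
    Deterministic given the config seed and starting point.
    """
    from scipy.optimize import minimize

    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(config.seed)

    trace: list[float] = []
    state = {"best": -np.inf, "x": None, "n": 0}

    def neg(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        value = objective(xc)
        if not np.isfinite(value):
            raise RuntimeError(f"objective returned non-finite value at {xc}")
        state["n"] += 1
        if value > state["best"]:
            state["best"] = value
            state["x"] = xc.copy()
        trace.append(state["best"])
        return -value

    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), lo, hi))
    while len(starts) < config.n_starts:
        starts.append(lo + (hi - lo) * rng.random(lo.size))

    for start in starts:
        minimize(
            neg,
            start,
            method="Nelder-Mead",
            options={
                "maxfev": config.max_iter,
                "xatol": 1e-4,
                "fatol": 1e-6,
                "initial_simplex": _initial_simplex(start, lo, hi),
            },
        )
    return {
        "x": state["x"],
        "value": state["best"],
        "n_eval": state["n"],
        "trace": np.asarray(trace),
    }


def _initial_simplex(x0: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Simplex spanning ~10% of each bound width, kept inside the box."""
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    step = 0.1 * (hi - lo)
    for d in range(n):
        moved = x0[d] + step[d]
        simplex[d + 1, d] = moved if moved <= hi[d] else x0[d] - step[d]
    return simplex
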