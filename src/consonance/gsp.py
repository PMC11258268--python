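"""Gibbs-Sampling-with-People simulation over a 2D triad space.

Each chain starts uniformly at random in the (interval_1, interval_2)
plane; at every iteration an idealized responder replaces the active
coordinate with the value (from a dense slider grid) that maximizes a
utility function -- either exactly (argmax) or noisily (softmax with
temperature tau).  Dimensions alternate between iterations.  Chains are
pooled and summarized with a fixed-bandwidth Gaussian kernel density
estimate on a dense grid; per-panel values are rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "GSPConfig",
    "GSPChain",
    "run_chains",
    "chains_to_frame",
    "aggregate_kde",
    "octave_diagonal_location",
    "make_composite_utility",
]


@dataclass(frozen=True)
class GSPConfig:
    dim_ranges: tuple[tuple[float, float], ...] = ((0.5, 8.5), (0.5, 8.5))
    n_chains: int = 200
    chain_length: int = 40
    slider_grid: int = 400
    responder: str = "argmax"  # or "softmax"
    tau: float = 0.05
    kde_bandwidth: float = 0.375
    model_kde_bandwidth: float = 0.1875
    out_grid: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if any(lo >= hi for lo, hi in self.dim_ranges):
            raise ValueError("each dim range must have low < high")
        if self.kde_bandwidth <= 0:
            raise ValueError("kde_bandwidth must be > 0")
        if self.responder not in ("argmax", "softmax"):
            raise ValueError("responder must be 'argmax' or 'softmax'")


@dataclass
class GSPChain:
    """Start point plus the sequence of accepted iterations.

    ``iterations`` rows are (i1, i2); ``active_dims[t]`` is the coordinate
    replaced at iteration t.  The random start itself is not an iteration.
    """

    start: np.ndarray
    iterations: np.ndarray  # (chain_length, 2)
    active_dims: np.ndarray  # (chain_length,)


def run_chains(
    utility: Callable[[np.ndarray], np.ndarray],
    config: GSPConfig = GSPConfig(),
) -> list[GSPChain]:
    """Simulate GSP chains against a utility function on the 2D space.

    ``utility`` receives an (n, 2) array of candidate coordinates and must
    return n finite scores.  Argmax ties break to the lowest slider index.
    Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([r[0] for r in config.dim_ranges])
    hi = np.array([r[1] for r in config.dim_ranges])
    n_dims = lo.size
    sliders = [
        np.linspace(lo[d], hi[d], config.slider_grid) for d in range(n_dims)
    ]
    chains = []
    for _ in range(config.n_chains):
        pos = lo + (hi - lo) * rng.random(n_dims)
        start = pos.copy()
        first_dim = int(rng.integers(n_dims))
        iterations = np.empty((config.chain_length, n_dims))
        active_dims = np.empty(config.chain_length, dtype=int)
        for t in range(config.chain_length):
            d = (first_dim + t) % n_dims
            candidates = np.tile(pos, (config.slider_grid, 1))
            candidates[:, d] = sliders[d]
            u = np.asarray(utility(candidates), dtype=float)
            if u.shape != (config.slider_grid,) or not np.all(np.isfinite(u)):
                bad = None if u.shape != (config.slider_grid,) else candidates[
                    ~np.isfinite(u)
                ][0]
                raise RuntimeError(f"non-finite or misshaped utility at {bad}")
            if config.responder == "argmax":
                choice = int(np.argmax(u))
            else:
                z = (u - u.max()) / config.tau
                prob = np.exp(z)
                prob /= prob.sum()
                choice = int(rng.choice(config.slider_grid, p=prob))
            pos = candidates[choice]
            iterations[t] = pos
            active_dims[t] = d
        chains.append(GSPChain(start=start, iterations=iterations, active_dims=active_dims))
    return chains


def chains_to_frame(chains: list[GSPChain]) -> pd.DataFrame:
    rows = []
    for cid, chain in enumerate(chains):
        for t in range(chain.iterations.shape[0]):
            rows.append(
                {
                    "chain_id": cid,
                    "iteration": t,
                    "active_dim": int(chain.active_dims[t]),
                    "i1": chain.iterations[t, 0],
                    "i2": chain.iterations[t, 1],
                }
            )
    return pd.DataFrame(rows)


def aggregate_kde(
    chains: list[GSPChain] | np.ndarray,
    config: GSPConfig = GSPConfig(),
    rescale: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Isotropic Gaussian KDE over pooled iteration coordinates.

    Accepts chains or an (n, 2) point array.  Returns (density, grid_x,
    grid_y) with density of shape (out_grid, out_grid) indexed
    [ix, iy].  With ``rescale`` the panel is mapped to [0, 1]; otherwise
    the density integrates to ~1 over the plane.
    """
    if isinstance(chains, np.ndarray):
        points = np.asarray(chains, dtype=float)
    else:
        if not chains:
            raise ValueError("no chains provided")
        points = np.concatenate([c.iterations for c in chains], axis=0)
    if points.size == 0:
        raise ValueError("no iterations to aggregate")
    (x_lo, x_hi), (y_lo, y_hi) = config.dim_ranges
    gx = np.linspace(x_lo, x_hi, config.out_grid)
    gy = np.linspace(y_lo, y_hi, config.out_grid)
    h = config.kde_bandwidth
    kx = np.exp(-0.5 * ((gx[:, None] - points[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - points[None, :, 1]) / h) ** 2)
    density = (kx @ ky.T) / (2.0 * np.pi * h * h * points.shape[0])
    if rescale:
        dmin, dmax = density.min(), density.max()
        if dmax > dmin:
            density = (density - dmin) / (dmax - dmin)
        else:
            density = np.zeros_like(density)
    return density, gx, gy


def make_composite_utility(
    timbres,
    config: GSPConfig = GSPConfig(),
    bass: float = 60.0,
    n_grid: int = 121,
    params=None,
):
    """Composite-model utility on the triad plane, precomputed on an
    ``n_grid``-squared lattice and bilinearly interpolated (each GSP
    iteration queries hundreds of slider candidates, so direct evaluation
    would dominate the run time)."""
    from scipy.interpolate import RegularGridInterpolator

    from .composite import CompositeParams, composite_scores_batch, normalize_profile
    from .harmonicity import harmonic_template

    (x_lo, x_hi), (y_lo, y_hi) = config.dim_ranges
    gx = np.linspace(x_lo, x_hi, n_grid)
    gy = np.linspace(y_lo, y_hi, n_grid)
    i1, i2 = np.meshgrid(gx, gy, indexing="ij")
    pitches = np.column_stack(
        [
            np.full(i1.size, bass),
            bass + i1.ravel(),
            bass + i1.ravel() + i2.ravel(),
        ]
    )
    template = harmonic_template()
    values = composite_scores_batch(
        pitches, timbres, params or CompositeParams(), template
    )
    values = normalize_profile(values).reshape(n_grid, n_grid)
    interp = RegularGridInterpolator((gx, gy), values, bounds_error=False, fill_value=None)
    return lambda coords: interp(np.asarray(coords, dtype=float))


def octave_diagonal_location(
    density: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    band: tuple[float, float] = (10.0, 14.0),
    n_bins: int = 400,
) -> float:
    """Location of the octave diagonal: the anti-diagonal coordinate
    s = i1 + i2 at which the mean density is maximal within ``band``.

    The projection averages density per s-bin (so a uniform density maps
    to a flat projection); a projection without a distinguished maximum
    raises ValueError.
    """
    s = grid_x[:, None] + grid_y[None, :]
    lo, hi = band
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(s.ravel(), edges) - 1
    inside = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[inside], weights=density.ravel()[inside], minlength=n_bins)
    counts = np.bincount(idx[inside], minlength=n_bins)
    valid = counts > 0
    if not np.any(valid):
        raise ValueError("no density mass inside the requested band")
    proj = np.full(n_bins, -np.inf)
    proj[valid] = sums[valid] / counts[valid]
    finite = proj[np.isfinite(proj)]
    if finite.max() - finite.min() <= 1e-9 * max(abs(finite.max()), 1.0):
        raise ValueError("projection is flat: no distinguished diagonal band")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # mass-weighted centroid of the near-maximal neighborhood
    k = int(np.argmax(proj))
    near = np.isfinite(proj) & (proj >= 0.5 * (proj[k] + finite.min()))
    # restrict to the contiguous run containing the argmax
    run_lo, run_hi = k, k
    while run_lo > 0 and near[run_lo - 1]:
        run_lo -= 1
    while run_hi < n_bins - 1 and near[run_hi + 1]:
        run_hi += 1
    sel = slice(run_lo, run_hi + 1)
    weights = proj[sel] - finite.min()
    if weights.sum() <= 0:
        return float(centers[k])
    return float(np.sum(centers[sel] * weights) / weights.sum())
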