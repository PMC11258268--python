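"""Peak picking on smoothed consonance profiles.

The detector follows an eight-step recipe: fit a cubic spline to the
(already kernel-smoothed) profile, take first and second derivatives on
the grid, mark peaks where the first derivative changes sign from
positive to negative with second derivative below -range/20 (troughs
symmetric), merge adjacent peaks separated by troughs shallower than
alpha * range (keeping the taller), and discard peaks lacking a
beta * range drop within a fixed window on *both* sides.

Bootstrap peak reliability counts, for each reference peak, the fraction
of bootstrap-replicate profiles with a detected peak within a +/-0.5
semitone neighborhood; peaks above the reliability threshold get location
confidence intervals of mean +/- 1.96 sd of the matched bootstrap
locations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .analysis import ConsonanceProfile

__all__ = ["PeakPickConfig", "Peak", "PeakSet", "find_peaks", "peak_reliability"]


@dataclass(frozen=True)
class PeakPickConfig:
    merge_depth_alpha: float = 0.01  # trough-depth fraction of range
    sharpness_beta: float = 0.01  # 0.01 behavioral, 0.05 model profiles
    curvature_frac: float = 1.0 / 20.0  # |f''| threshold as fraction of range
    sharpness_window: float = 0.5  # semitones, each side
    reliability_window: float = 0.5  # semitones
    reliability_threshold: float = 0.95

    def __post_init__(self):
        if min(
            self.merge_depth_alpha,
            self.sharpness_beta,
            self.curvature_frac,
            self.sharpness_window,
            self.reliability_window,
        ) <= 0:
            raise ValueError("all peak-picking parameters must be > 0")
        if self.sharpness_beta > 1:
            raise ValueError("beta must be <= 1")

    def scaled_to_range(self, profile_range: float, reference_range: float = 15.0):
        """Rescale the semitone windows for narrow (e.g. 0.5-st) profiles."""
        factor = profile_range / reference_range
        return replace(
            self,
            sharpness_window=self.sharpness_window * factor,
            reliability_window=self.reliability_window * factor,
        )


@dataclass(frozen=True)
class Peak:
    location: float
    height: float
    ci_low: float | None = None
    ci_high: float | None = None
    reliability: float | None = None


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.location))
        )

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def locations(self) -> np.ndarray:
        return np.array([p.location for p in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks])


def _spline(profile: ConsonanceProfile) -> tuple[CubicSpline, np.ndarray, np.ndarray]:
    grid = np.asarray(profile.grid, dtype=float)
    values = np.asarray(profile.mean, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 10:
        raise ValueError("profile must have >= 10 defined points")
    # interpolating cubic spline: the recipe's near-zero smoothing limit
    return CubicSpline(grid[ok], values[ok]), grid[ok], values[ok]


def find_peaks(
    profile: ConsonanceProfile, config: PeakPickConfig = PeakPickConfig()
) -> PeakSet:
    """Detect peaks of a smoothed profile (no reliabilities/CIs).

    A degenerate (constant) profile returns an empty PeakSet.  All
    thresholds are relative to the profile's value range, so output is
    invariant under affine rescaling of the values.
    """
    f, grid, values = _spline(profile)
    frange = float(values.max() - values.min())
    if frange <= 0:
        return PeakSet()
    d1 = f(grid, 1)
    d2 = f(grid, 2)
    curv = config.curvature_frac * frange

    peak_idx = np.where((d1[:-1] > 0) & (d1[1:] < 0) & (d2[:-1] < -curv))[0]
    trough_idx = np.where((d1[:-1] < 0) & (d1[1:] > 0) & (d2[:-1] > curv))[0]

    def _refine(i: int) -> float:
        # root of f' within the bracketing grid cell
        from scipy.optimize import brentq

        a, b = grid[i], grid[i + 1]
        try:
            return float(brentq(lambda x: f(x, 1), a, b))
        except ValueError:
            return float(a)

    peaks = [_refine(i) for i in peak_idx]
    troughs = [_refine(i) for i in trough_idx]
    if not peaks:
        return PeakSet()

    # merge peaks not separated by deep-enough troughs, keeping the taller
    peaks = sorted(peaks)
    merged = True
    while merged and len(peaks) > 1:
        merged = False
        for k in range(len(peaks) - 1):
            lo, hi = peaks[k], peaks[k + 1]
            between = [t for t in troughs if lo < t < hi]
            # fall back to the grid minimum if no formal trough qualified
            cell = (grid >= lo) & (grid <= hi)
            candidates = [float(f(t)) for t in between]
            if np.any(cell):
                candidates.append(float(values[cell].min()))
            t_min = min(candidates) if candidates else min(float(f(lo)), float(f(hi)))
            depth = min(float(f(lo)), float(f(hi))) - t_min
            if depth < config.merge_depth_alpha * frange:
                keep = lo if f(lo) >= f(hi) else hi
                peaks[k : k + 2] = [keep]
                merged = True
                break

    # two-sided sharpness test
    w = config.sharpness_window
    beta = config.sharpness_beta * frange
    sharp = []
    for p in peaks:
        fp = float(f(p))
        left = grid[(grid >= p - w) & (grid <= p)]
        right = grid[(grid >= p) & (grid <= p + w)]
        ok_left = left.size > 0 and fp - float(f(left).min()) >= beta
        ok_right = right.size > 0 and fp - float(f(right).min()) >= beta
        if ok_left and ok_right:
            sharp.append(Peak(location=p, height=fp))
    return PeakSet(tuple(sharp))


def peak_reliability(
    bootstrap_profiles: list[ConsonanceProfile] | np.ndarray,
    reference_peaks: PeakSet,
    config: PeakPickConfig = PeakPickConfig(),
    grid: np.ndarray | None = None,
    ci_mult: float = 1.96,
) -> PeakSet:
    """Filter reference peaks by bootstrap reliability and attach CIs.

    ``bootstrap_profiles`` is a list of ConsonanceProfile replicates, or a
    (n_boot, n_grid) array of replicate values (then ``grid`` is required).
    A reference peak is retained iff the fraction of replicates containing
    a detected peak within the reliability window exceeds the threshold.
    """
    if isinstance(bootstrap_profiles, np.ndarray):
        if grid is None:
            raise ValueError("grid required with an array of replicates")
        bootstrap_profiles = [
            ConsonanceProfile(grid=grid, mean=row) for row in bootstrap_profiles
        ]
    if len(bootstrap_profiles) == 0:
        raise ValueError("need at least one bootstrap replicate")

    replicate_locs = [find_peaks(bp, config).locations for bp in bootstrap_profiles]

    out = []
    win = config.reliability_window
    for peak in reference_peaks:
        matched = []
        hits = 0
        for locs in replicate_locs:
            if locs.size == 0:
                continue
            d = np.abs(locs - peak.location)
            if d.min() <= win:
                hits += 1
                matched.append(locs[np.argmin(d)])
        reliability = hits / len(replicate_locs)
        if reliability > config.reliability_threshold:
            matched = np.asarray(matched)
            mu = float(matched.mean())
            sd = float(matched.std(ddof=1)) if matched.size > 1 else 0.0
            out.append(
                Peak(
                    location=peak.location,
                    height=peak.height,
                    ci_low=mu - ci_mult * sd,
                    ci_high=mu + ci_mult * sd,
                    reliability=reliability,
                )
            )
    return PeakSet(tuple(out))
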