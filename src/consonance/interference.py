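"""Interference (roughness) models of dissonance.

Two pure-dyad aggregates over all pairs of partials:

* the original Hutchinson-Knopoff model, using the Bigand parametric
  dissonance curve ``D(x) = (4x exp(1 - 4x))**2`` of critical-bandwidth
  distance ``x``, with pair contributions weighted by amplitude products
  (dissonance proportional to intensity);
* a revised model whose kernel ``D*`` turns slightly-detuned pairs
  (x below the slow-beat boundary ``p``) into negative dissonance, i.e.
  pleasant slow beating, and whose amplitude exponent ``r`` interpolates
  between amplitude (r=1) and intensity (r=2) weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ToneSpectrum

__all__ = [
    "DissonanceParams",
    "DEFAULT_DISSONANCE_PARAMS",
    "critical_bandwidth_distance",
    "kernel_original",
    "kernel_revised",
    "dissonance_original",
    "dissonance_revised",
]


@dataclass(frozen=True)
class DissonanceParams:
    """Revised-model parameters.

    p : slow-beat boundary in critical-bandwidth units
    q : slow-beat pleasantness strength
    r : amplitude exponent (2 recovers intensity weighting)
    """

    p: float = 0.096
    q: float = 1.632
    r: float = 1.359

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.r <= 0:
            raise ValueError("r must be > 0")


DEFAULT_DISSONANCE_PARAMS = DissonanceParams()


def critical_bandwidth_distance(f1, f2):
    """Frequency separation in critical-bandwidth units:
    ``|f2 - f1| / (1.72 * ((f1 + f2)/2)**0.65)``.

    Symmetric in its arguments; zero iff f1 == f2.  Accepts arrays.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(f1 <= 0) or np.any(f2 <= 0):
        raise ValueError("frequencies must be > 0")
    x = np.abs(f2 - f1) / (1.72 * ((f1 + f2) / 2.0) ** 0.65)
    return float(x) if x.ndim == 0 else x


def kernel_original(x):
    """Relative dissonance ``D(x) = (4x exp(1 - 4x))**2``.

    Zero at x = 0, unique maximum of 1 at x = 0.25, decaying to zero.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("critical bandwidth distance must be >= 0")
    d = (4.0 * x * np.exp(1.0 - 4.0 * x)) ** 2
    return float(d) if d.ndim == 0 else d


def kernel_revised(x, params: DissonanceParams = DEFAULT_DISSONANCE_PARAMS):
    """Revised kernel D*(x): for x < p,

        D*(x) = (x/p) D(x) - q (1 - x/p) (1 + sin(2 pi x/p - pi/2))

    and D(x) otherwise.  Continuous at x = 0 and x = p; negative values
    encode the pleasantness of slow beats.  With p = 0 the revised kernel
    degenerates to the original.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("critical bandwidth distance must be >= 0")
    d = kernel_original(x)
    p, q = params.p, params.q
    if p == 0:
        return d
    d = np.asarray(d, dtype=float)
    below = x < p
    if np.any(below):
        xb = x[below] if x.ndim else x
        ratio = xb / p
        slow = ratio * kernel_original(xb) - q * (1.0 - ratio) * (
            1.0 + np.sin(2.0 * np.pi * ratio - np.pi / 2.0)
        )
        if x.ndim:
            d[below] = slow
        else:
            d = slow
    return float(d) if np.ndim(d) == 0 else d


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def dissonance_original(spectrum: ToneSpectrum) -> float:
    """Original aggregate: sum over partial pairs of A_i A_j D(x_ij),
    normalized by sum_k A_k**2.  Invariant to partial order and to global
    amplitude scaling; zero for a single partial."""
    n = len(spectrum)
    if n == 0:
        raise ValueError("spectrum must contain at least one partial")
    if n == 1:
        return 0.0
    f, a = spectrum.frequencies, spectrum.amplitudes
    i, j = _pair_indices(n)
    x = critical_bandwidth_distance(f[i], f[j])
    num = np.sum(a[i] * a[j] * kernel_original(x))
    return float(num / np.sum(a**2))


def dissonance_revised(
    spectrum: ToneSpectrum,
    params: DissonanceParams = DEFAULT_DISSONANCE_PARAMS,
) -> float:
    """Revised aggregate: sum over pairs of (A_i A_j)**(r/2) D*(x_ij),
    normalized by sum_k A_k**r.  May be negative (net slow-beat
    pleasantness); reduces to the original model at r = 2, q = 0, p -> 0."""
    n = len(spectrum)
    if n == 0:
        raise ValueError("spectrum must contain at least one partial")
    if n == 1:
        return 0.0
    f, a = spectrum.frequencies, spectrum.amplitudes
    i, j = _pair_indices(n)
    x = critical_bandwidth_distance(f[i], f[j])
    num = np.sum((a[i] * a[j]) ** (params.r / 2.0) * kernel_revised(x, params))
    return float(num / np.sum(a**params.r))


def dissonance_revised_batch(
    freqs: np.ndarray,
    amps: np.ndarray,
    params: DissonanceParams = DEFAULT_DISSONANCE_PARAMS,
) -> np.ndarray:
    """Vectorized revised aggregate for a batch of spectra sharing one
    amplitude vector: ``freqs`` is (B, N), ``amps`` is (N,).

    Equivalent to calling :func:`dissonance_revised` row by row (asserted
    in the test suite); used on dense profile grids.
    """
    freqs = np.asarray(freqs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    n = freqs.shape[1]
    if n == 1:
        return np.zeros(freqs.shape[0])
    i, j = _pair_indices(n)
    x = critical_bandwidth_distance(freqs[:, i], freqs[:, j])
    pair_w = (amps[i] * amps[j]) ** (params.r / 2.0)
    return (kernel_revised(x, params) @ pair_w) / np.sum(amps**params.r)
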