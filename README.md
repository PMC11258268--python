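# consonance

A toolkit for psychoacoustic consonance modeling:

- **spectra** — additive-synthesis tone spectra (harmonic, stretched/compressed,
  pure, five-equal-harmonic, bonang, custom), MIDI↔frequency mapping, ADSR
  rendering to WAV, beat rates, and spectrum estimation from recorded
  instrument tones (cosine filterbank + Hilbert envelopes).
- **interference** — the Hutchinson–Knopoff roughness aggregate with the Bigand
  parametric kernel `D(x) = (4x·e^(1−4x))²`, plus a revised model whose kernel
  turns slow beats (critical-bandwidth distance below a boundary `p`) into
  negative dissonance and whose amplitude exponent `r` interpolates between
  amplitude and intensity weighting. Defaults `p=0.096, q=1.632, r=1.359`.
- **harmonicity** — Milne-style pitch-class spectra, cosine-similarity template
  matching (virtual pitch profiles), KL-uncertainty (Harrison–Pearce) and
  max-peak (Milne) scores.
- **composite** — weighted combination (−1 × interference, +0.837 × harmonicity)
  with median normalization.
- **analysis** — within-participant z-scoring, Nadaraya–Watson kernel-smoothed
  consonance profiles (1D and interval×roll-off product kernels), participant
  bootstrap confidence bands, Monte Carlo split-half reliability.
- **peaks** — the 8-step peak-picking algorithm (spline derivatives, curvature
  threshold, trough-depth merging, two-sided sharpness test) plus bootstrap
  peak reliability and location confidence intervals.
- **fitting** — peak-Jaccard model-fit objective and gradient-free (multi-start
  Nelder–Mead) optimization of `(p, q, r, w_harmonicity)`.
- **gsp** — Gibbs-Sampling-with-People chain simulation over the 2D triad
  space, fixed-bandwidth KDE aggregation, octave-diagonal extraction.
- **simdata** — synthetic dense-rating datasets (participant intercepts, trial
  noise, 7-point likert mapping, roving bass) so the whole pipeline is
  testable without behavioral data.

## CLI

```bash
# render a perfect fifth with 3 dB/octave harmonic tones
consonance synth --bass 60 --intervals 7 --timbre harmonic --rolloff 3 --out chord.wav

# score a chord under a model (hk-original | hk-revised | hp | milne | composite)
consonance score --model composite --bass 60 --intervals 7 --timbre harmonic

# simulate raters around the composite surface, then smooth + bootstrap
consonance simulate-raters --timbre harmonic --n 200 --seed 1 --out ratings.csv
consonance profile --ratings ratings.csv --bandwidth 0.2 --nboot 1000 --seed 1 --out profile.csv
consonance peaks --profile profile.csv --beta 0.01

# GSP simulation over the triad plane with stretched tones
consonance gsp-sim --timbre stretched --gamma 2.1 --seed 7 --out chains.csv

# fit (p, q, r, w_h) against behavioral peaks listed in a YAML manifest
consonance fit --experiments manifest.yaml --out params.json
```

Commands that write artifacts also write a `*.manifest.json` recording the
parameters, seed, and output checksums.

## Python API sketch

```python
import numpy as np
from consonance import TimbreParams, composite_profile
from consonance.analysis import model_profile
from consonance.peaks import find_peaks, PeakPickConfig

grid = np.linspace(0, 15, 1000)
raw = composite_profile(grid, TimbreParams.stretched(2.1))   # stretched tones
prof = model_profile(raw, grid)                              # same smoothing as behavior
peaks = find_peaks(prof, PeakPickConfig(sharpness_beta=0.05))
print(peaks.locations)   # octave peak near 12 * log2(2.1) ≈ 12.84
```
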