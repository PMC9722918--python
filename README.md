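# mitorhythm

Quantification of circadian rhythms in mitochondrial biology from
fluorescence microscopy and plate assays. The package is aimed at
cell biologists and image analysts who image MitoTracker-style
mitochondrial stains over a synchronisation time course (e.g. after a
serum shock) and want a reproducible, scriptable path from raw TIFFs
to "is this oscillating, with what amplitude and peak time?".

It provides:

- **Segmentation** of cells and individual mitochondria: 16-bit
  normalisation, difference-of-Gaussians band-pass, auto-thresholding,
  tiny-object removal, and marker-controlled watershed splitting of
  touching mitochondria seeded from prominent maxima of the distance
  transform.
- **Morphology**: per-object area, length (max Feret diameter),
  aspect ratio and circularity in physical units; per-cell medians and
  total area; fission/fusion scoring by the three length classes
  < 1 µm, 1–3 µm, > 3 µm.
- **Rhythm statistics**: the fixed-period cosinor model
  Y = M + β·cos(2πt/τ) + γ·sin(2πt/τ) with amplitude
  A = √(β²+γ²), acrophase Φ = atan2(γ, β)·τ/2π, and the
  zero-amplitude F test; plus a minimal JTK-style Kendall-tau test
  against phase-shifted cosine references with Bonferroni adjustment
  over phases.
- **Assay quantities**: Mito Stress respiration parameters
  (non-mitochondrial, basal, maximal, spare respiratory capacity) from
  4-phase OCR traces, and ΔΔCt fold changes (2^−ΔΔCt) from Ct tables.
- **Synthetic data generators** with exact ground truth (capsule-shaped
  mitochondria with known lengths, cosinor time series, OCR step
  traces), so the whole chain is testable without any downloads.
- An end-to-end **pipeline** (`mitorhythm run`) from a
  directory-per-timepoint image layout to per-cell tables,
  per-timepoint means ± SEM and rhythm fits on fission fraction,
  fusion fraction, median length and MFI.

## Worked example

Simulate a noisy 48-h rhythm (mesor 10, amplitude 2, peak at 6 h,
σ = 1, 3 replicates every 4 h) and fit it:

```python
import numpy as np
from mitorhythm import Cosinor, RhythmSimSpec, generate_timeseries, jtk_test

ts = generate_timeseries(RhythmSimSpec(mesor=10, amplitude=2,
                                       acrophase_h=6, noise_sd=1, seed=42))
res = Cosinor.from_timeseries(ts).fit()
print(res.summary())
```

```
Cosinor regression results
==============================================
n observations                    39
period (h)                        24
design rank                        3
----------------------------------------------
coef          estimate     std err
mesor           10.043      0.1308
beta          -0.27144      0.1782
gamma           1.7717      0.1914
----------------------------------------------
amplitude                     1.7924
acrophase (h)                 6.5807
p (zero amplitude)         2.154e-10
residual SS                   23.746
```

The fit recovers the planted rhythm: mesor 10.04 (truth 10), amplitude
1.79 (truth 2), acrophase 6.6 h (truth 6 h), and the zero-amplitude
null is rejected decisively (p ≈ 2×10⁻¹⁰). The nonparametric check
agrees at the grid resolution of the sampling interval:

```python
j = jtk_test(ts)
# JTK: best phase 8 h, tau=0.670, adjusted p=1.95e-07
```

`res.plot()` overlays the fitted cosine on the observations. The same
objects back the batch interface (`batch_rhythm`) for tidy
analyte/time/value tables and the CLI:

```sh
mitorhythm simulate image --out sim --seed 7     # image + ground truth
mitorhythm segment --images sim --pixel-size-um 0.1 --out seg
mitorhythm rhythm --csv series.csv --method both --out report
mitorhythm mitostress --csv ocr_trace.csv
mitorhythm run --config run.yaml                 # full time course
```

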