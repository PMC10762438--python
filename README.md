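# pamscape

Passive-acoustic-monitoring (PAM) soundscape analysis for polar marine
mammal communities: from duty-cycled hydrophone recordings and manual
detection logs to presence time series, ray-traced audible areas,
ice-constrained environmental covariates, and community statistics.

A single moored recorder hears a region whose size changes daily with
ambient noise and sound propagation. Counting detections without accounting
for that *audible area* conflates animal behaviour with acoustics.
`pamscape` implements the full chain needed to make detection time series
interpretable, and ships a seeded synthetic polar scene (shelf/trough/basin
bathymetry, a seasonal sea-ice cycle with an El Niño-like anomaly year, and
guild-structured calling species) so every stage is testable end to end
without external data. It is aimed at bioacousticians and quantitative
ecologists working with single-station PAM deployments.

## What it computes

**Presence series.** Acoustic presence is assessed per clock hour: an hour
scores 1 for a species iff at least one confident, non-chorus detection
falls in that hour's recording (presence-only; call counts are ignored).
Daily presence is the percentage of recorded hours with presence; the
day × species matrix of positive hours (0–24) is the community response.

**Audible area.** For a calling species with source level SL (dB re 1 µPa
at 1 m), the signal excess at the recorder is

    SNR = SL − TL − NL

where TL is the modelled transmission loss and NL the ambient noise level
at the call frequency, from a Welch spectrum (Hamming window) of the first
minutes of each recording, calibrated through the hydrophone sensitivity,
gain and ADC chain. The audible area is the region with SNR > 5 dB. TL
comes from an in-package 2-D geometric ray tracer run along radial slices
around the recorder: a fan of rays refracted by the sound-speed profile
(Mackenzie equation), reflected at the surface and at a Rayleigh fluid
seabed with absorption, with incoherent ray-tube intensity accumulation.
The tracer reproduces the spherical (20 log r) and cylindrical (10 log r)
spreading limits that control detection-range estimates.

**Constrained covariates.** Daily audible masks clip the environmental
fields: the proportion of audible area under sea ice (SIC > 30%), mean
SST/SSH over the ice-free audible cells, and the coefficient of variation
of depth there (vBAT), plus mean SIC within 25 and 100 km of the recorder.

**Community statistics.** Variance-inflation-factor screening; constrained
correspondence analysis (CCA) of the community matrix on the covariates
(chi-square standardization, row-weighted projection, SVD); and
quasi-binomial penalized-spline GAMs of daily presence,
`logit E[y] = β₀ + Σ f_j(x_j)`, with low-rank thin-plate-type splines,
REML-chosen smoothing, Pearson-estimated dispersion and pointwise 95%
intervals. `CCA(...)` and `PresenceGAM(...)` are model objects whose
`.fit()` returns results with `summary()`, scores/effects and plots.

## Worked example

Fit a presence model to a season of daily detections whose true
ice response is `logit p = −1 + 2·SIC`:

```python
import numpy as np, pandas as pd
from pamscape import PresenceGAM

rng = np.random.default_rng(0)
sic = rng.uniform(0, 1, 245)                  # daily sea-ice proportion
p = 1 / (1 + np.exp(-(-1 + 2 * sic)))         # true presence model
y = rng.binomial(24, p) / 24                  # proportion of positive hours
res = PresenceGAM(y, np.full(245, 24.0), pd.DataFrame({"SIC": sic})).fit()
print(res.summary())
```

```
Quasi-binomial penalized-spline presence model
  n = 245, total edf = 2.00, dispersion = 0.914
  deviance = 230.02, QAIC = 255.78
  smooth        edf    lambda      p-value
  s(SIC       )  1.00   6.57e+07     0.0000
```

The REML criterion recognises the linear truth (edf 1.00, a very large
smoothing parameter), the dispersion is near 1 as expected for binomial
data, and the smooth is strongly significant. The centred partial effect
rises from −0.65 at SIC = 0.2 to +0.52 at SIC = 0.8 on the logit scale —
the fitted ice affinity — with the simulated truth inside the 95% band.

End to end, `pamscape.run_scene_pipeline(seed=0)` generates the anomaly
year scene, measures daily noise, traces monthly TL, builds daily audible
masks and constrained covariates, and fits the CCA: the ice-affiliated and
ice-avoiding guilds separate on axis 1 and the SIC arrow points toward the
ice-affiliated cluster.

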