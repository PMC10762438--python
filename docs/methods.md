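# Methods

This note documents the models, numerical choices and limitations behind
`pamscape`, in the order data flows through the pipeline.

## Synthetic scene (`pamscape.scene`)

The generator emulates a single autonomous recorder moored in a trough on
a polar shelf break, so every downstream stage can be exercised without
external rasters or audio.

**Bathymetry.** Depth (m, positive down) is a logistic south-to-north ramp
from a ~350 m shelf band to a ~3500 m basin, plus a Gaussian trough
(~900 m over-deepening) around the recorder and 5% smoothed multiplicative
noise, clipped to [150, 4200] m. A `flat_depth` override produces idealised
test environments.

**Daily fields.** SST is a south–north gradient plus an annual cosine
peaking in mid February (austral summer) plus smooth space–time noise.
SSH is a weak seasonal oscillation with a small meridional gradient. Sea
ice is a 1-D logistic front in latitude: the front latitude follows an
annual cosine fully advanced in mid September, with smooth per-longitude
jitter (0.15°); concentration is 100/(1+exp(−(φ_front−φ)/0.30)), clipped
to [0, 100]%. The front is 1-D because the only dynamics the statistics
see — a seasonal northward advance and retreat past the recorder — do not
require a 2-D ice model.

**Anomaly year.** `year_mode="anomaly"` delays the ice-advance phase by
`ice_delay_days` (default 30 d) and adds `sst_summer_offset` (default
0.7 °C) times a summer-peaked weight to SST, mimicking an El Niño-like
season with warm summer water and late freeze-up.

**Calling model.** Each species calls in a given hour with probability
`logit⁻¹(a + b·SIC + c·SST + d·SSH)` from the *recorder-cell* covariates
(SIC as proportion 0–1). Driving presence from the single cell makes the
pipeline's audible-area covariate extraction a nontrivial estimator of the
generating covariate rather than a tautology. Default coefficients encode
the guild contrast (ice-affiliated slopes b ≈ +2.5…+3.5, ice-avoiding
b ≈ −2…−4, a near-always-on resident); magnitudes were chosen once to give
realistic presence rates (a few percent for rare seals, ~75% hourly for
the resident) and are not tuned thereafter. `a = −inf` is a sentinel for
a silent species.

**Recordings.** Gaussian ambient noise with a flat spectral density at the
requested level (variance = 10^(NL/10)·fs/2) plus one Tukey-windowed tone
(optionally a down-sweep) per scheduled species, scaled to a configured
RMS received level. Calls are energy-at-a-frequency stand-ins, not call
mimics — downstream only the Welch level at the call frequency matters.
Waveforms are expressed in ADC counts through the calibration chain and
clipping beyond full scale is an error.

What the generator does *not* emulate: ocean dynamics, krill fields,
animal movement or call directionality, ice-quake transients, flow noise.
Passing tests therefore demonstrate the correctness of the pipeline's
arithmetic and its qualitative community-level behaviour, not fidelity to
any particular ocean.

## Presence series (`pamscape.presence`)

Hour bins are half-open [h, h+1) UTC, aligned to the duty cycle (recording
at the top of each hour). An hour is positive for a species iff ≥1
confident, non-chorus annotation of it falls in that hour; uncertain
annotations are dropped at ingest (a `keep_uncertain` flag retains them
for sensitivity analysis). The daily percentage uses *hours actually
recorded that day* as denominator, so deployments starting or ending
mid-day are handled without bias. Months inside the deployment with no
positive hours report 0; months with no recording report NA. The duty-cycle
audit classifies each (file, species) pair as before-mark if any detection
starts before the mark (default 8 min), supporting checks that a shorter
duty cycle would not have lost detections.

The bundled 2016 (16 Feb–23 Aug, 12/60 duty) and 2017 (10 Feb–12 Oct,
8/60) deployments give inclusive day counts of 190 and 245.

## Calibration and spectra (`pamscape.noise`)

Counts→pressure uses µPa = counts·(V_fs/2^(bits−1)) / (10^(gain/20)·
10^(sens/20)) with defaults sensitivity −165 dB re V/µPa, gain 16 dB, 5 V
full scale (AURAL-class; the full-scale voltage is configurable because
recorder documentation rarely states it), 16 bit. Welch spectra use a
Hamming window, default nfft 65536, 50% overlap, density scaling (the
integral of the density recovers the variance); shorter recordings are
used whole with a warning. NL at a species frequency is the nearest single
bin (ties to the lower bin); a ±k-bin linear-mean band average is available
by option. Whether a deployment's noise metric should be spectral density
or band level is a judgement call; density is the default and band level
is reachable through the band-average option.

## Ray-traced transmission loss (`pamscape.raytrace`)

A deliberate simplification of beam tracing: geometric rays with
incoherent ray-tube intensity summation. This reproduces the spreading
laws that control audible-area estimates (spherical 20 log r in a free
field; cylindrical 10 log r in a waveguide) but no coherent interference
structure (no convergence-zone fine structure, no modal interference).

Details:

- **Sound speed**: Mackenzie nine-term equation of T, S, z. Slice water
  columns take the (monthly mean) surface temperature decaying
  exponentially (scale 100 m) to a 0.5 °C deep value, salinity constant
  34.2 psu — a minimal polar profile producing the upward-refracting
  winter duct typical of the region.
- **Geometry**: slices along great-circle bearings (spherical Earth,
  R = 6371 km; at 500 km the ellipsoidal correction is below the TL-mesh
  resolution), bearings clockwise from true north, land truncating the
  slice. The fan is launched from the *receiver* (recorder) depth by
  reciprocity; the reported curve is TL at the caller's source depth
  (default 15 m) per range.
- **Stepping**: fixed range step; Snell's invariant cosθ/c is re-imposed
  each step from the local profile; refraction turning points flip the
  vertical direction without advancing depth. Surface reflection is
  specular and lossless. Bottom reflections use the Rayleigh fluid–fluid
  coefficient with the seabed absorption (dB/λ) entering as a complex
  sound speed (loss tangent α·ln10/(40π)), specular reflection about the
  local bathymetric slope, and a configurable bounce budget (default 20,
  after which a ray is dropped). Thorp volume absorption is on by default
  (negligible below 200 Hz).
- **Intensity deposit**: adjacent-ray pairs form tubes carrying flux
  cosθ₀Δθ₀; a tube's intensity at range r is flux·loss/(r·Δz·cosθ).
  Cell *averages* are deposited, which keeps caustics finite at lattice
  resolution. Pairs straddling one boundary reflection are folded into two
  image sub-tubes meeting at the boundary (energy-conserving), and pairs
  that folded more than once between deposits are spread uniformly over
  the water column — without this, near-boundary cells are systematically
  starved. Optionally several range samples per output cell are averaged
  (`deposits_per_cell`) to reduce sampling noise, e.g. for reciprocity
  studies. TL is clipped at 0 dB (incoherent sums cannot exceed the 1 m
  reference) and +inf marks cells no ray reaches.
- **Seabed parameters**: density 1200 kg m⁻³, sound speed 1450 m s⁻¹,
  absorption 1 dB/λ. (The density is interpreted as kg m⁻³; the units of
  archival seabed tables are not always printed consistently.) Note that a
  seabed *slower* than the water column has an angle of intromission where
  R = 0; increasing seabed absorption then *raises* |R| near that angle,
  so "more absorption ⇒ more TL" holds only in the sub-critical grazing
  regime over a fast seabed — the regime that dominates long-range ducted
  propagation.
- **Gridding**: per-bearing TL curves are interpolated bilinearly in polar
  (bearing, range) coordinates with periodic bearing wrap onto a
  cell-centred lat/lon mesh (default 218 × 464, configurable); cells
  beyond slice reach or on land carry the sentinel.

Verified limit behaviour (see the test suite): spherical spreading within
±0.3 dB over 100 m–10 km; waveguide slope 9.5–10.6 dB/decade over
50–400 km with the theoretical offset 10·log₁₀(D/Σθ) matched to ~1 dB;
source/receiver reciprocity within 0.5 dB in test waveguides.

## Audible areas and constrained covariates (`pamscape.covariates`)

SNR = SL − TL − NL elementwise; the audible mask is the *strict* SNR >
5 dB set with latitude-dependent cell areas (R²ΔλΔφcosφ). Daily masks
binarize the per-recording occupancy at ≥ 0.5 (so 12 of 24 recordings
counts); the continuous occupancy is retained alongside. A cell is
ice-covered iff SIC > 30% (strictly); the SIC proportion is area-weighted.
Covariate statistics are taken over audible ∧ ice-free cells; vBAT is the
population coefficient of variation sd(depth)/mean(depth). Empty masks or
empty eligible sets propagate NA (and such days are listwise-deleted
before the statistics). Grids are co-registered by nearest-neighbour
resampling onto the mask mesh (bilinear available). Recorder-radius SIC
(25/100 km) is an area-weighted mean over cells whose centres lie within
the geodesic radius.

## Ordination and collinearity (`pamscape.ordination`)

VIF_j = 1/(1−R²_j) from OLS of predictor j on the others with intercept;
exact collinearity reports inf.

CCA follows the standard chi-square formulation: with P the relative
abundance table, r and c its margins, Q = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2)
is projected onto the column span of the row-weighted, weighted-centred
predictors (√r·(X − x̄_w)); the SVD of the projection gives constrained
eigenvalues (singular values squared), and the residual the unconstrained
ones; their sum equals the total inertia ‖Q‖² to machine precision.
Species scores use type-2 scaling (species scores carry the eigenvalue
scale, D_c^(−1/2)·V·diag(s)); site scores are the unit-scaled
linear-combination scores D_r^(−1/2)·U; biplot arrows are correlations of
the standardized constraints with the constrained axes. Month enters as a
numeric predictor by default (it describes a monotone within-season drift;
factor coding can be layered on by dummy-expanding the predictor table).
All-zero community rows or columns are rejected by name.

## Presence GAMs (`pamscape.gam`)

One smooth per covariate: a cubic radial basis |x−κ|³ on k (default 10)
quantile knots of the internally standardized covariate, with the two
thin-plate constraints (Σδ = Σδκ = 0) absorbed by a null-space
reparameterization, an unpenalized linear part, and the bending-energy
penalty on the radial block. All columns are centred over the data
(sum-to-zero identifiability); internal standardization makes the fit
invariant to affine rescaling of covariates. Covariates left with fewer
than four distinct values after constraint/deletion degrade gracefully to
a linear term.

Fitting is penalized IRLS for the quasi-binomial logit model with trial
weights (recorded hours per day). Smoothing parameters minimise a
REML-type criterion — the Gaussian restricted likelihood of the converged
working model with the working dispersion plugged in (performance
iteration) — over log λ by Nelder–Mead, λ clipped to e^[−12, 18].
Dispersion φ is Pearson χ²/(n − edf). Coefficient uncertainty uses the
Bayesian posterior covariance φ(XᵀWX+S_λ)⁻¹; partial effects come with
pointwise 95% intervals. Term p-values are approximate Wald/quasi-F tests
with rank ≈ rounded edf — adequate for screening, not exact. "GAMM" here
has no random effects or autocorrelation term: with one observation per
day and year-specific models there is no grouping structure to absorb,
and residual autocorrelation is left to the user to assess; `backward_select`
provides QAIC-based term selection mirroring keep-only-what-improves-fit
model building. Trial weighting by recorded hours, and listwise deletion
of days with any missing covariate, are the package's documented choices
where field practice varies.

## End-to-end pipeline (`pamscape.pipeline`)

Problem sizes were set once for desk-scale runs: bearings every 15°,
120 km slices, an 80 × 160 mesh, ray fan of 121 over ±80°, 2 km × 50 m TL
cells, one 30 s synthetic recording per day at 2048 Hz, and a shared
audible-area frequency of 50 Hz with a nominal 160 dB source level (a
single shared covariate set is used for the community statistics; the
species-specific frequencies remain available per species). Ambient level
at the recorder declines linearly with local ice cover (82 dB open water,
−12 dB under full ice), the documented ice-quieting proxy. A full
245-day anomaly season runs in ~40 s on one core; the guild contrast
(axis-1 separation with an aligned SIC arrow) is stable across seeds.

## Known limitations

- Incoherent ray tracing cannot produce interference or diffraction; TL in
  shadow zones is a sentinel rather than a diffracted level. Sea-ice
  scattering loss on propagation is not modelled (only its effect on NL).
- The working-model REML criterion is not exactly the marginal-likelihood
  criterion of a full mixed-model formulation; smoothing parameters can
  differ from other implementations in the third significant figure, and
  p-values are approximate.
- The spherical-Earth geodesy is exact only on the sphere; at 500 km an
  ellipsoidal geodesic differs by up to ~1–2 km (below mesh resolution).
- The synthetic scene's guild structure is generated through the same
  covariates later used for inference; the pipeline tests estimator
  consistency and sign structure, not discovery power on real data.
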