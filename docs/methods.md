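# Methods

This note documents the models, defaults, numerical choices, and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Image formation model (synthetic data)

Movies are rendered from point emitters with an isotropic 2-D Gaussian PSF
applied after maximum projection, which is how all analyses here operate.
The PSF is *pixel-integrated* (difference of error functions per pixel), so
a fully in-frame emitter contributes exactly `photon_scale × brightness`
photons above background; the photon-conservation tests rely on this
exactness. Default `psf_sigma_nm = 110`, roughly the diffraction limit of
high-NA (≈1.4) oil optics at green wavelengths; default
`pixel_size_nm = 100` and `frame_interval_s = 10` match a spinning-disk
single-molecule acquisition (every 10 s for 30 min).

Noise is Poisson shot noise on the expected photon image followed by
additive Gaussian read noise (`read_noise_sd = 2`), clipped at zero. The
camera's gain register and EM noise are not modelled. One consequence used
in the tests: with a zero background, the zero-clipping of read noise adds
a small positive pedestal to frame means, so bleach-fit fixtures use
Poisson-only noise or a nonzero background.

Global photobleaching multiplies all brightnesses by `e^(−λt)`, giving the
bleach-correction stage an exact ground truth.

### Single-molecule (flux) movies

Channel 0 carries persistent centriole emitters, channel 1 transient
molecules. Labeled binding events arrive per centrosome as a Poisson
process with rate `−ln(1 − target_occupancy) / dwell_mean_s`, so the
expected fraction of centrosomes holding ≥1 visible molecule equals
`target_occupancy` (default 0.07, inside the sparse 5–10% single-molecule
band). Bound dwells are exponential (default mean 40 s). Binding radii are
folded-normal (default 300 ± 150 nm) and isotropic in angle; the empirical
radial distribution of real binding sites is not known beyond being
unimodal, and nothing downstream depends on its exact shape.

In `flux` mode the radial distance grows at `outward_speed_nm_s` (default
10 nm/s) while bound; in `static_turnover` mode the position is frozen —
the two regimes embody physical outward transport versus a spatial gradient
in binding-site turnover. Fluorophore blinking is a one-frame dark state
(probability 0.05 per frame, never twice in a row), exercising the
gap-closing / blink-tolerance rules.

Note on sampling: the observed span between the first and last *frame* of a
visit underestimates the true dwell at short dwells and overestimates it
conditional on ≥2 observations; for exponential dwells of mean 40 s sampled
every 10 s, `E[observed span | ≥2 frames] ≈ 45 s`, so end-to-end mean
displacement estimates sit near `v × 40–45 s` and are compared to
`v × E[dwell]` within Monte-Carlo error, not exactly.

### FRAP movies

A centrosome is a disc of unit-capacity sub-emitters (radius 1.2 µm). At
the bleach frame, sub-emitters inside the circular ROI drop to
`residual_fraction` (default 0.1; the experimental residual is not known,
so it is a parameter). Recovery follows the scaffold mode:

- **liquid**: every sub-emitter exchanges with the cytoplasmic pool at rate
  `k`; with a single centrosome the pool is effectively infinite and the
  ROI-summed recovery is *exactly* one-phase association with rate `k`
  (immobile fraction `f` caps the plateau at `1 − f`).
- **liquid + paired**: two centrosomes share a finite pool (default 5× the
  scaffold capacity), integrated by sub-stepped Euler (20 steps/frame);
  returning bleached molecules dilute the pool, so the unbleached partner
  declines monotonically — the redistribution signature.
- **solid**: only sub-emitters within `central_recovery_radius_nm`
  (default 400 nm) exchange; the periphery stays bleached and there is no
  inter-centrosome transfer.

### FCS traces

Traces are sums of 3-D Gaussian-profile weights
`exp(−2r²_xy/w² − 2z²/w_z²)` over Brownian particles in a periodic box,
with `w = 0.2 µm`, `w_z = S·w`, and `D = w²/(4τ_D)`; intensities are scaled
so the mean equals `N × CPM`. Two numerical points matter:

1. **Grand-canonical count.** The particle number is drawn Poisson; a fixed
   count would suppress occupancy fluctuations of the focal volume and
   depress G by ≈ `V_eff/V_box`.
2. **Box dilution.** Even so, a particle in a bounded periodic box has a
   positive time-averaged weight, which depresses the *within-trace*
   estimator by up to `1/M` (M = particles in the box) until box-mixing
   times. The box is therefore 150 effective volumes by default
   (`box_volume_ratio`); the residual effect at the standard round-trip
   condition (N = 10, τ_D = 1 ms, 24 s trace) is a ≈ −10% bias on fitted
   τ_D, within the 15% recovery tolerance the round-trip tests use. Larger
   boxes reduce the bias linearly at proportional cost.

The Brownian walk runs in a compiled (numba) kernel fed by numpy-generated
Gaussian steps, keeping one seeded RNG stream; traces are bit-reproducible
for a given seed. Optional triplet/blinking dark states are two-state
telegraph processes simulated event-wise (used at small scale in tests;
they bypass the compiled path).

## Centrosome quantification

- Background estimation is Gaussian low-pass subtraction (floored at zero).
  A rolling-ball estimator would serve equally; the low-pass is separable,
  fast, and exactly testable on ramp fixtures. The smoothing scale should
  be much larger than the object diameter (a warning fires otherwise).
- The Crocker–Grier detector band-passes (noise-scale Gaussian minus
  feature-size boxcar), finds candidates by grayscale dilation, and refines
  each by iterated masked centroiding (window re-centered while the offset
  exceeds 0.5 px, ≤10 iterations). Duplicates within one radius keep the
  larger mass (the suppression radius is unstated in common practice;
  diameter/2 here). The mass cutoff `min_mass` is exposed with a default of
  0 — it depends on optics and must be set per dataset.
- Otsu threshold: 256 bins over [min, max], between-class variance
  maximized over interior bin edges, ties to the lower threshold. The
  acceptance suite checks exact agreement with an exhaustive scan.
- Segmentation is 8-connected; per-object sum intensity is computed on the
  (by default background-corrected) image. Note an Otsu cut on a Gaussian
  spot keeps only the supra-threshold core (≈ two thirds of the mass);
  truth-comparison tests therefore use a low manual threshold.
- Fold enrichment is a ratio of mean pixel intensities (object over
  cytoplasm), making it independent of object area; both regions must be
  background-corrected consistently and disjoint.
- Coordinates are (y, x), 0-based, pixel centers at integers; distances are
  reported in nm via the pixel size.

## FRAP analysis

- Bleach correction fits `A·e^(−λt)` to the mean intensity outside the
  excluded region by weighted least squares on the log (weights ∝
  intensity, the Poisson-appropriate choice); λ is clipped at zero with a
  warning if the fit prefers growth. A constant camera offset can be
  subtracted before fitting (`offset=`).
- The measurement ROI is a circle fixed in the tracked centrosome's moving
  frame (bleach ROIs of 3.5–4 µm diameter are standard; the default
  examples use ~1.4–1.8 µm measurement radii).
- Normalization is full-scale: prebleach mean → 1, first post-bleach
  value → 0. This makes the fitted plateau read directly as the mobile
  fraction. Group-level averaging normalizes per centrosome first.
- The one-phase fit multi-starts K from the observed half-rise time
  (decade variations), bounded by `10 / frame interval`; failures across
  all starts are flagged, never silently defaulted.
- Kymographs use bilinear interpolation at unit steps along the line,
  averaged across an odd perpendicular width; they agree with a direct
  resampling oracle to numerical precision.

## Single-molecule flux analysis

- LoG detection at σ = diameter/(2√2), local maxima above a quality
  threshold (default: 10 robust SDs of the response), quadratic-fit
  subpixel refinement, and the brightest raw pixel within one radius
  recorded per spot.
- Linking is minimum-total-squared-distance bipartite assignment per frame
  pair with a hard cap (2.0 µm), realized as a padded linear assignment in
  which an unmatched spot costs cap²; gap closing joins track ends to
  starts across ≤1 missing frame within 2.0 µm. This reduces a full
  birth/death LAP to a capped matching — adequate at single-molecule
  densities and exactly checkable against enumerated matchings.
- A *visit* is a maximal run of track points within the association radius
  of one centriole, tolerating single-frame interruptions.
  **The association radius (default 1.5 µm) is an analysis choice**: the
  original colocalization judgment was visual, and the default covers
  observed unbinding distances (≲1.1 µm) with margin. It is configurable
  and should be reported with any result.
- Rule operationalizations: entry/exit are "observed" iff the visit does
  not abut the movie's first/last frame (a track appearing mid-movie
  already colocalized counts as an observed binding — molecules become
  visible when they bind). A single-frame visit is rejected. Any temporal
  overlap of visits at one centrosome rejects all still-accepted
  participants. The sparse-labeling gate is strict (`< 5%` at every
  frame) and is a movie-level screen, checked separately from per-track
  selection; note the simulator's default occupancy (5–10%) reflects the
  imaging condition, which is screened *before* analysis in the real
  protocol.
- Distances: centriole reference is the intensity-weighted center of mass
  of its Otsu-segmented region within a 1 µm box around the tracked
  position (green channel); the molecule position is its brightest raw
  pixel by default (subpixel centroid available as `mode="subpixel"`).
  All distances are 2-D, post-projection.
- The In/Out comparison uses the paired Wilcoxon signed-rank test (the
  original test is unnamed; a nonparametric paired test is the conservative
  choice). All-zero differences report p = 1 rather than an error.

## FCS analysis

- Multi-tau correlator: m = 16 channels per octave, two full-resolution
  octaves then factor-2 binning; estimator `⟨ab⟩/(⟨a⟩⟨b⟩) − 1` with
  symmetric normalization; G(∞) → 0 convention throughout. Per-lag weights
  are standard deviations across six trace segments (mirroring six repeated
  4-s measurements), and the lag grid is capped so every lag is estimable
  within one segment. Erratic traces (large-object transits) are flagged
  when the worst segment's ACF deviates from the median curve by more than
  5× the median segment score.
- The model zoo is the standard 3-D Gaussian confocal family with
  multiplicative exponential dark-state factors. Triplet and blinking share
  the functional form and differ only by bounds: τ_T ≤ 50 µs, τ_B ≥ 50 µs.
  The structure parameter S is fixed at 5 by default (fitting it is
  unstable on single curves) and configurable.
- Fits are weighted least squares (lmfit) with data-driven initials
  (N from 1/G at short lags, τ_D from the half-amplitude lag) and a
  3-point multi-start on τ_D; two-species ordering is enforced by fitting
  τ_D2 = τ_D1 × ratio with ratio ≥ 1. Flat curves yield flagged failures.
- Model ranking uses BIC on the weighted residual sum of squares (the
  ln(n)-per-parameter penalty holds the chance rate of a nested over-model
  beating the truth to ~1% per competitor, where an AIC-style +2 penalty
  loses ~12% per competitor); ties go
  to fewer parameters. Fits with a timescale pinned at a bound *and* a
  non-negligible associated fraction are flagged degenerate (a
  non-identifiable optimum, e.g. a blinking term collapsed onto the triplet
  boundary) and rank after clean fits.
- Physical quantities: concentration `N/(N_A·V_eff)` with V_eff = 0.25 fl
  by default; the lateral waist follows from `V_eff = π^{3/2} w³ S`, giving
  `D = w²/(4τ_D)`; CPM = mean intensity / N.

## Problem sizes used by the tests and acceptance script

Detection fidelity: 20 fields × 10 spots at default SNR. Flux
discrimination: 8–10 rendered 150-frame movies per regime (≥200 accepted
events each). FRAP: 50 noisy recovery curves; 20 paired movies per scaffold
mode. FCS: 20 round-trip seeds of 24 s traces (six 4-s segments); 50
model-selection replicates at 1% curve noise — the level of a curve
averaged over six repeats. These sizes give Monte-Carlo errors comfortably
inside the asserted tolerances.

## What the synthetic tests do and do not show

The generator reproduces the *geometry and statistics* the analyses rely
on: calibrated PSF and noise, sparse transient binding with known In/Out
positions, exactly-one-phase liquid recovery, and diffusion through a
Gaussian focal volume. It omits embryo-scale structure (nuclear cycles,
yolk autofluorescence, centrosome movement and flares, 3-D PSF anisotropy,
EM-gain noise, chromatic offsets between channels). Passing tests therefore
demonstrate correctness of the measurement chain under its stated model,
not robustness to every feature of real embryo movies; the association
radius, detector thresholds and `min_mass` in particular need per-dataset
calibration.

## Known limitations

- Tracking is nearest-assignment with hard caps; no motion model, no 3-D.
- The FRAP model is exchange-limited (no reaction–diffusion spatial
  profile within the recovering region beyond the solid-core geometry).
- FCS fitting fixes S; triplet/blinking are distinguished only by timescale
  bounds; no photon-arrival (time-tagged) correlation.
- The simulated τ_D carries the finite-box bias discussed above (≈ −10% at
  defaults); analyses of *measured* traces are unaffected.
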