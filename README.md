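# pcmflux

Quantitative image and spectroscopy analysis for centrosome biology:
measuring pericentriolar-material (PCM) scaffolds in fluorescence movies,
discriminating solid-like from liquid-like scaffold behaviour by FRAP, and
testing whether single client molecules physically move outward through the
PCM while bound — plus fluorescence correlation spectroscopy (FCS) for
cytoplasmic concentrations and diffusion rates, and a calibrated synthetic
movie/trace generator so every stage can be validated against known ground
truth.

## Who it is for

Labs quantifying centrosome (or other organelle-scale condensate) dynamics
from spinning-disk / confocal time-lapse data: centrosome segmentation and
intensity measurement, FRAP recovery kinetics, sparse single-molecule
binding analysis against a second (centriole marker) channel, and point-FCS
model fitting.

## What it computes

**Centrosome quantification** (`pcmflux.quant`): maximum z-projection,
uneven-illumination background correction (Gaussian low-pass subtraction),
Crocker–Grier centroid detection, Otsu segmentation with per-object sum
intensity and area, centrosome-to-cytoplasm fold enrichment, and
Laplacian-of-Gaussian (LoG) bead measurement (default bead diameter 2.7 µm).

**FRAP** (`pcmflux.frap`): global photobleaching correction by a
single-exponential fit outside the bleach region, centrosome tracking,
full-scale-normalized recovery curves, and the one-phase association model

    Y(t) = Y0 + (plateau − Y0) · (1 − e^(−K t)),
    t½ = ln 2 / K,   mobile fraction = (plateau − Y0) / (1 − Y0),

plus kymographs along user lines and the paired-centrosome redistribution
statistic (fractional intensity loss of the unbleached partner — positive
loss indicates molecules exchange between centrosomes, a liquid-like
signature).

**Single-molecule flux** (`pcmflux.flux`): LoG spot detection (0.5 µm
molecules), linear-assignment track linking with hard caps (2.0 µm link,
2.0 µm gap close, one-frame gaps for fluorophore blinking), the five
binding-event selection rules (sparse labeling < 5% of centrosomes at any
time point; observed entry *and* exit; more than one time point at the
centrosome; one-frame blink tolerance; no simultaneous events at one
centrosome), and the paired distance statistic: the centriole-to-molecule
distance at the first (`d_in`) and last (`d_out`) colocalized time point,
compared by Wilcoxon signed rank. Mean `d_out` > `d_in` is the signature of
outward molecular flux; a static-binding (turnover-gradient) regime gives
no shift.

**FCS** (`pcmflux.fcs`): multi-tau autocorrelation (16 channels/octave),
the eight standard confocal diffusion models (one or two species × no dark
state / triplet / blinking / both),

    G(τ) = (1/N) · X_T(τ) · X_B(τ) · Σᵢ fᵢ (1 + τ/τD,ᵢ)⁻¹ (1 + τ/(S²τD,ᵢ))^(−1/2),

weighted fits with BIC model ranking, and physical quantities:
concentration `N/(N_A·V_eff)` (default V_eff = 0.25 fl), diffusion
coefficient `w²/(4τD)`, and counts per molecule (CPM).

**Synthetic data** (`pcmflux.simulate`): pixel-integrated Gaussian-PSF
rendering with Poisson + read noise, centrosome fields, FRAP movies with
solid/liquid scaffold modes, two-channel single-molecule movies under flux
or static-turnover regimes (sparse 5–10% occupancy), and FCS traces from
Brownian particles in a 3-D Gaussian observation volume — all with exact
ground-truth tables.

## Worked example

Simulate a two-channel single-molecule movie under the outward-flux regime
(10 nm/s, mean bound dwell 40 s, frames every 10 s) and run the full
detection → linking → selection → distance pipeline:

```python
import numpy as np
from pcmflux import SimConfig, FluxRegime, simulate_flux_movie
from pcmflux.flux import analyze_flux_movie

config = SimConfig(image_shape=(256, 256), n_frames=150)   # 100 nm px, 10 s frames
regime = FluxRegime(mode="flux", outward_speed_nm_s=10.0, dwell_mean_s=40.0)
movie = simulate_flux_movie(config, regime, n_centrosomes=16, seed=7)

tracks, events, summary = analyze_flux_movie(
    movie.stack, pixel_size_nm=100.0, frame_interval_s=10.0
)
print(f"accepted events: {summary.n_events}")
print(f"In  distance: {summary.d_in_mean_nm:.0f} +/- {summary.d_in_sd_nm:.0f} nm (mean +/- SD)")
print(f"Out distance: {summary.d_out_mean_nm:.0f} +/- {summary.d_out_sd_nm:.0f} nm")
print(f"paired Wilcoxon p = {summary.p_value:.2e}")
```

Output:

```
accepted events: 22
In  distance: 355 +/- 128 nm (mean +/- SD)
Out distance: 714 +/- 294 nm
paired Wilcoxon p = 4.77e-07
```

Molecules bound close to the centriole (355 nm) and unbound roughly
`v × E[dwell] ≈ 400 nm` farther out — the outward-flux signature. Rerunning
with `FluxRegime(mode="static_turnover", outward_speed_nm_s=0.0)` gives
indistinguishable In/Out distances.

A command-line interface mirrors the library:
`pcmflux simulate flux --seed 7 --out-dir scratch/`, then
`pcmflux flux --movie scratch/flux.tif --out-dir scratch/results/`; see
`pcmflux --help` for the `quantify`, `frap`, and `fcs` subcommands.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
details, and known limitations of both the analysis stages and the
synthetic-data generator.
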