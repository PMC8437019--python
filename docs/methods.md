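# Methods

`spechvol` estimates the *n*-dimensional spectral space ("spectral
hypervolume") occupied by individual plants and plant communities from leaf
reflectance spectra, and relates its size to plant growth and ecosystem
productivity. This note documents the model, its assumptions, the tunable
parameters, the synthetic-data generator, and the numerical choices made
where the design was genuinely open.

## Spectral preprocessing

Leaf-clip reflectance from multi-detector field spectrometers carries small
discontinuities at the detector overlap wavelengths (around 1000 nm between
the Si and first InGaAs sensors, and around 1900 nm between the two InGaAs
sensors), plus noisy spectrum ends. Preprocessing applies, in order:

1. **Splice correction** (`splice_correct`): for each junction, processed in
   increasing wavelength order, the segment at and beyond the junction is
   shifted *additively* so that its first band equals the linear
   extrapolation from the two bands just left of the junction. The additive
   (offset) form was chosen over a multiplicative one because detector-step
   artefacts in leaf-clip reflectance are approximately offset-like and the
   additive correction is exactly idempotent — re-running it is a no-op at
   machine precision.
2. **Trimming** (`trim`): bands outside a closed window, 400–2400 nm by
   default, are removed. This window is the standard usable range for the
   SVC HR-1024i / PSR+ 3500 class of instruments.
3. **Resampling** (`resample_1nm`): linear interpolation onto the integer-nm
   grid spanning ceil(min λ)…floor(max λ). Values at original integer nodes
   are preserved exactly; no extrapolation beyond the measured range.
4. **Averaging** (`aggregate_mean`): band-wise arithmetic means per group of
   metadata keys — replicate leaves per canopy layer (tree data) or per
   individual (grassland data).

## Dimensionality reduction

Covariance PCA (centered, not per-band standardized) is fitted once per
experiment on the full spectral matrix; the first *k* = 3 component scores
are the hypervolume axes. Raw reflectance is used because per-band
standardization would inflate the weight of low-variance noisy bands and
destroy the physical amplitude structure the hypervolume interprets; a
`scale=True` switch exists for the standardized variant. Component signs are
fixed by making each loading's largest-magnitude element positive, so fits
are reproducible across BLAS builds. `k_for_variance` applies a strict
"more than the threshold" criterion (e.g. more than 98% of total variance),
with a 1e-9 guard so a cumulative sum equal to the threshold up to rounding
does not count as exceeding it. One PCA is shared by all communities of an
experiment; per-community PCA is deliberately not done, so all hypervolumes
live on common axes. PC scores are passed to the hypervolume unstandardized:
the per-dimension Silverman bandwidths already adapt to each axis's scale.

## KDE hypervolumes

Given an *n* × *d* score matrix, the density is a Gaussian kernel mixture
f(x) = (1/n) Σᵢ N(x; pᵢ, diag(h²)) with per-dimension Silverman bandwidths

    h_j = sd_j · (4/(d+2))^{1/(d+4)} · n^{−1/(d+4)},

sd_j the sample SD (denominator n−1). The hypervolume is the level set
{x : f(x) ≥ t} with t the empirical (1−q) quantile of f evaluated at draws
from f itself, so the region retains mass q (default q = 0.95, a "5%
quantile threshold"). The mass interpretation of the quantile is the
default; a density-height alternative (quantile of densities at the data
points) is available via `threshold_mode="height"` but is not used in the
analysis. Volume uses the importance-sampling identity
Vol{f ≥ t} = E_{X∼f}[1{f(X) ≥ t}/f(X)], averaged over the same n_mc draws
(default 10 000).

Numerical choices:

- Sampling and density evaluation happen in bandwidth-standardized
  coordinates. Because Silverman bandwidths are linear in the data scale,
  the standardized point cloud — and hence the draws, densities and the
  inside/outside classification — is *identical* for X and c·X at the same
  seed, making volume(c·X) = c^d · volume(X) exact up to one floating-point
  product, and volume translation-invariant.
- Diagonal kernels only (no covariance kernels), mirroring the per-dimension
  Silverman estimator and keeping the scaling property exact.
- Degenerate dimensions (zero SD) raise an error rather than being silently
  jittered; `jitter=ε` opts into uniform noise of half-width ε (suggested
  1e-9 axis units) when that is scientifically acceptable.
- Volumes are reported in raw PC-score units; downstream analysis uses the
  natural logarithm.

A brute-force grid oracle (`grid_volume_oracle`, d ≤ 2) integrates the same
mixture on a dense grid padded by 4·max(h) and serves as the independent
correctness standard: the Monte Carlo estimate agrees with it within 5% on
uniform, Gaussian and bimodal fixtures, and with the closed-form 95% HDI
width 2·1.96·√(sd²+h²) of a smoothed normal. Parity with any particular
existing hypervolume implementation is not claimed; parity with the oracle
is.

Overlap (`overlap_jaccard`) estimates V(A∩B)/V(A∪B) by classifying each
hypervolume's Monte Carlo draws with the other's threshold rule, averaging
the two importance-sampling intersection estimates, and applying
inclusion–exclusion for the union. `centroid_distance` is the Euclidean
distance between the two point-set means.

## Fixed-size resampling protocol

KDE hypervolume size depends on the number of points used to fit it — in
the 3-D small-sample regime relevant here, expected volume grows with n —
so communities sampled with different intensity are not directly
comparable. The protocol fits each community on fixed-size random
subsamples: 9 spectra per plot for the tree design ("FAB"), and 12
individuals per plot for the prairie design ("BioDIV": 3 individuals from
each of 4 subplots chosen without replacement). The random selection is
iterated (50 times by default) and the mean and SD of ln(volume) across
iterates summarize each community. Plots failing the minimum-size
precondition (fewer members than the subsample, or fewer than 4 subplots
with 3 individuals) raise a protocol error and are excluded with a logged
warning.

Per-iterate RNGs are derived counter-style as SeedSequence([master, i]);
the hypervolume fit inside an iterate is seeded from the drawn subsample
indices, so iterates that draw identical subsamples give identical volumes
and the reported SD reflects sampling variation only.

## Biodiversity-effect partition

For a mixture with monoculture yields Mᵢ, observed mixture yields Y_Oᵢ and
expected relative yields RY_Eᵢ (planting proportions; default 1/N for the
substitutive designs), with ΔRYᵢ = Y_Oᵢ/Mᵢ − RY_Eᵢ:

    NBE = Σ Y_Oᵢ − Σ RY_Eᵢ·Mᵢ,  CE = N·mean(ΔRY)·mean(M),  SE = N·cov(ΔRY, M)

with the *population* covariance (denominator N), which makes NBE = CE + SE
an exact algebraic identity. Monoculture plots are tabulated but flagged and
excluded from NBE analysis. The allometric biomass helper uses the generic
power law M = a·D^b·H^c with user-supplied per-species coefficients;
productivity is the between-census increment of this quantity.

## Regressions

The analysis surface is univariate OLS throughout: ln hypervolume size
against height/diameter at the individual scale, and mean ln community
volume against NBE, CE, SE, richness and biomass at the community scale.
Each fit reports slope, intercept, r², F = r²/(1−r²)·(n−2) with df (1, n−2),
and the exact p-value. No mixed models or covariate adjustment.

## Synthetic-data generator

The generator emulates the structure of leaf spectral libraries from
diversity experiments so that every stage is testable with known ground
truth:

- **Spectra.** Reflectance over 400–2400 nm at 1 nm is a smooth parametric
  curve per species: a pigment-free visible level of 0.38 depressed by
  Gaussian chlorophyll/carotenoid absorptions at 450/680 nm (widths 30/25
  nm, scaled by `pigment_depth`), a logistic red edge (scale 12 nm) rising
  to `nir_plateau`, water absorptions at 1450/1940 nm (widths 60/90 nm,
  scaled by `water_depth`), and a linear SWIR decay beyond 1300 nm — clipped
  to [0, 1]. Canopy layers apply multiplicative (pigment, NIR) modifiers:
  shade leaves have deeper pigment absorption and a slightly lower plateau.
  Individuals perturb the archetype parameters smoothly
  (`intra_individual_sd`, default 0.01 reflectance units of induced
  deviation) and each spectrum gets additive i.i.d. Gaussian noise
  (`noise_sd`, default 0.002), truncated to keep reflectance in [0, 1].
  Noise-free first differences stay below 0.02 per nm (smoothness
  contract).
- **Low-rank interspecific variation.** Species parameters are driven by
  three latent axes (leaf structure/water status, pigment pool, a small
  residual), so the default dataset satisfies a designed contract: the first
  three PC axes of a ≥500-spectrum sample explain ≥98% of total variance.
  Field data do not pin down the intra-individual vs interspecific variance
  ratio, so defaults were chosen to honour this contract rather than to
  match any particular instrument's moments — synthetic results demonstrate
  pipeline correctness, not field effect sizes.
- **Designs.** FAB-style: 3 individuals per species per plot, 3
  canopy-layer spectra each (9/18/45/108 spectra at richness 1/2/5/12);
  BioDIV-style: 4 subplots sampled for richness ≤ 2, 6 below 8, 8 otherwise,
  4 individuals per subplot, one averaged spectrum each (16/16/24/32 at
  richness 1/2/4/8), with every plot species guaranteed at least one
  individual. The default configuration is the 14-species pool at richness
  {1, 2, 4, 8}, six plots per level (528 spectra).
- **Yields.** Monoculture yields are log-normal (median 400, σ = 0.3).
  Mixture yields follow
  Y_Oᵢ = RY_Eᵢ·Mᵢ·(1 + β_c·D_plot + β_s·rankᵢ + ε), truncated at 0, where
  D_plot is the mean pairwise Euclidean distance among the plot species'
  archetype PC scores, rankᵢ a centered within-plot rank of Mᵢ in
  [−1/2, 1/2], and ε ~ N(0, `yield_noise_sd`). With β_s = 0 and ε = 0 the
  Loreau–Hector partition returns CE > 0 and SE = 0 exactly, which is the
  recoverable ground truth; β_c defaults to 0.08 per unit dispersion
  (relative yield gains of roughly 10–40% at typical dispersions),
  `yield_noise_sd` to 0.05.
- A single RNG stream per `simulate_experiment` call, seeded from the
  config, makes outputs bit-identical across reruns and platforms.

What the generator does **not** emulate: radiative-transfer realism
(no PROSPECT-style leaf optics), canopy BRDF, phenology, measurement-session
drift, and realistic covariance between yield noise and spectra. Passing
tests therefore show that the pipeline recovers effects *of the assumed
form*; they are not evidence about field data.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale by choice: oracle
fixtures use 600–2000 points with 30 000–50 000 Monte Carlo draws and grid
steps of 0.01–0.02; the protocol de-biasing check uses 200 synthetic
communities (sizes 9–144) with 6 iterates × 1500 draws; the regression
calibration uses 200 replicate null experiments with 4 iterates × 1500
draws. These sizes give comfortable statistical margins for every asserted
tolerance while keeping a full run in minutes on one core.

## Known limitations

- The Monte Carlo volume is unbiased only up to the empirical-quantile
  threshold coupling (threshold and volume share one draw set); the grid
  oracle bounds the resulting error at well under 5% at the shipped sizes.
- The grid oracle is exponential in dimension and restricted to d ≤ 2.
- The splice correction assumes offset-like junction artefacts; strongly
  multiplicative artefacts would need a ratio-based variant.
- BioDIV subplot counts for richness levels strictly between the designed
  ones (3, 5–7) follow a monotone interpolation of the design rule (4/6/8),
  which is an assumption.
- The allometric power law is a placeholder form; species-specific published
  allometries should be supplied where they exist.
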