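# Methods

This note records the scientific and numerical choices behind
`specyield`: what each component computes, the assumptions it makes,
what the synthetic generator does and does not emulate, and the
tolerances used throughout.

## Spectra

Spectra live on a regular integer-nm grid, canonically 350–2500 nm at
1 nm (2151 bands), the working resolution of field spectroradiometer
data after instrument-side resampling. Reflectance is a fraction:
negative values are rejected; values above 1 are accepted with a
warning, since sun-glint and white-panel calibration can push apparent
reflectance slightly above unity. White-panel calibration is the
elementwise ratio of target to panel radiance. Resampling is linear
interpolation, exact at coincident wavelengths, and refuses to
extrapolate — index wavelengths must be measured, not invented.
Index band lookup is exact on the grid (no nearest-neighbour
snapping): after resampling, the canonical grid contains every
integer-nm band an index can address.

File dialects: `wide_csv` (first column `wavelength_nm`, one column
per sample named `S{season}_I{rate}_D{density}_R{replicate}`) and an
`xlsx` mirror of the same layout. CSV round-trips bit-exactly (writes
use shortest-round-trip float repr, reads use the `round_trip` float
parser); xlsx round-trips to ~1e-15 relative, a limit of Excel cell
storage.

## Spectral indices

The 20 built-in definitions comprise twelve two-band
normalized-difference indices (band pairs 548/522, 626/386, 680/1650,
840/818, 1226/670, 1382/670, 1450/900, 1650/920, 2450/2100, 2498/1450,
2500/2250, 2500/2470) and eight published indices: MSI = R1600/R820,
SRWI = R860/R1240, NWI-3 = ND(970, 880), NDVI = ND(900, 685),
NDMI = ND(2200, 1100), NMDI, OSAVI = (R800 − R670)/(R800 + R670 + 0.16)
and MTVI = 1.2·[1.2·(R800 − R550) − 2.5·(R670 − R550)].

Two formulas circulate in typographically corrupted forms and need a
decision:

* **NMDI.** The default is the literature form
  (R860 − (R1640 − R2130))/(R860 + (R1640 − R2130)), where the SWIR
  difference plays the role of the measurement band. The
  sum-denominator variant seen in some printings is available via
  `builtin_definitions(nmdi_as_printed=True)`. Which variant a given
  published result used is generally not recoverable from the text.
* **MTVI.** Printed versions often carry an unbalanced bracket; the
  implementation follows the canonical structure above.

Normalized-difference and ratio-type indices (including NMDI) are
invariant under uniform rescaling of the spectrum; OSAVI (additive
soil term) and MTVI (affine in reflectance) are not. The test suite
asserts exactly this split, and checks every formula against an
independent hand-coded oracle at 1e-12 on random spectra.

## Exhaustive two-band search

For each wavelength pair the map stores the coefficient of
determination of the simple regression of the trait on NDI(λ₁, λ₂),
computed as the squared Pearson correlation — algebraically identical
to the one-regressor OLS R², and vectorizable row-by-row. Cells where
the index is constant across samples (the whole diagonal, since
NDI(λ, λ) ≡ 0) or touches a zero denominator are masked undefined and
stored as 0 under the mask, keeping the lattice full so hotspot
connectivity is well defined. Swapping λ₁ and λ₂ flips the sign of the
regressor and leaves R² unchanged, so maps are symmetric; tests assert
this and the agreement with a loop-based per-pair regression oracle at
1e-10.

The default search step is 4 nm (~538 bands, ~145k pairs), adequate to
locate hotspot geometry; 1 nm (2151 bands, ~2.3M pairs) is available
where the full-resolution map is wanted. Hotspots are 4-connected
components of supra-threshold cells (diagonal contact does not merge
regions), reported with their peak pair and sorted by peak R².

## Treatment-subset regressions

Five grouping schemes reproduce the reporting structure of
index-vs-trait tables on an S-season × 3-rate × 5-density × R-replicate
design. Replicate means are always formed first; seasons remain
separate points. On the reference design (S = 2, R = 3) the schemes
give n = 10 (within one rate), 6 (within one density), 6 (rate means
over densities), 10 (density means over rates) and 30 (all cells).
Means for the pooled schemes are taken over derived quantities (index
values and traits), not over spectra: indices are nonlinear in
reflectance, so the order of averaging matters, and subset tables are
built from per-plot index values.

Fits are ordinary least squares; R² is plain (not adjusted — adjusted
R² is reserved for the multivariate validation reports); p-values are
two-sided t-tests on the slope with n − 2 df; stars mark 0.05/0.01/
0.001. No multiple-testing correction is applied, matching the
single-cell reporting convention of the field. A constant regressor
yields a flagged-undefined cell rather than an exception.

The production function is the OLS line of grain yield on seasonal ET;
basal ET — the ET at which the line crosses zero yield — is
−intercept/slope, reported only for positive slopes.

## Water budget

Reference ET follows FAO-56 Penman–Monteith:
ETo = [0.408·Δ·(Rn − G) + γ·(900/(T + 273))·u₂·(es − ea)] /
[Δ + γ·(1 + 0.34·u₂)], clipped at zero. Vapour-pressure terms default
to the standard psychrometric formulas (Tetens saturation pressure
averaged over Tmax/Tmin; ea = es·RH/100); γ defaults to its ~400 m
elevation value 0.0643 kPa °C⁻¹ when records are built by the met
generator.

Crop ET is Σ(ETo·Kc) scaled by the deficit factor (1.00/0.75/0.50), so
deficit plans are exactly proportional. Kc values are inputs, not
estimated. The seasonal balance is ET = ETc + P + Cr − R − D + ΔS with
Cr = R = 0 by default (deep groundwater; diked surface-irrigated
basins). Sign convention: ΔS = storage(sowing) − storage(harvest),
added with "+", so profile depletion adds to seasonal ET. Deep
percolation uses a capacity-overflow rule per irrigation event:
max(0, pre-irrigation storage + application − field-capacity storage
over the 0.9 m root zone). Soil constants default to the sandy-loam
profile FC 0.151 m³ m⁻³, PWP 0.054 m³ m⁻³, bulk density 1.49 g cm⁻³,
depth 0.9 m; gravimetric-to-mm conversion is content × bulk density ×
depth × 1000.

ky is the ratio of relative yield decrease to relative ET deficit for
one actual/maximum pair, undefined (flagged) at zero deficit; reports
round to 2 decimals while records keep full precision, and printed-value
comparisons use |computed − printed| ≤ 0.005. Pooled ky defaults to the
through-origin slope Σxy/Σx², the classical production-function form
that ties zero yield loss to zero deficit; a free-intercept option
exists for comparison because some published pooled fits do not state
whether an intercept was allowed.

## Multivariate calibration

PLSR and SVR operate on the full working spectrum. Preprocessing is
mean-centering of X and y only (no variance scaling) — the minimal
canonical chemometric choice, configurable. Model selection is
leave-one-out cross-validation (full CV is the natural reading of
"cross-validation through all the data" at n of a few dozen;
5-fold is available): PLSR over latent factors 1..min(20, n − 2,
bands) — capped to avoid overfitting n ≪ p spectra — SVR over a small
deterministic grid (linear kernel by default, C ∈ {0.1, 1, 10, 100},
ε ∈ {0.01, 0.1}·sd(y)). The setting with minimal RMSECV wins; ties
break toward the simpler model; selection is fully deterministic.
Candidate factor counts above the effective data rank are legitimate
ladder entries; the PLS "residual is constant" warning they trigger is
suppressed during scanning.

Validation never refits: the frozen model predicts each subset (per
irrigation rate, per density, per season — 10 reports on the reference
design) and reports RMSE, the observed-vs-predicted OLS line, its R²
and the single-regressor adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

## Synthetic experiment generator

The generator produces the conditions the analysis assumes, not a
radiative-transfer simulation.

**Design and water budget.** Two seasons × rates (1.00, 0.75, 0.50) ×
densities (150…550 seeds m⁻²) × 3 replicates. Full-irrigation seasonal
applications are 558 and 555 mm with 38 and 45 mm sowing water;
effective precipitation defaults to 25 mm (an arid winter season);
storage depletion grows with the deficit (4 mm + 18 mm per unit
relative deficit) and percolation follows a threshold-overflow rule.
These defaults close the balance to relative ET deficits of ≈ 0.21
(0.75 ET) and ≈ 0.43 (0.50 ET). Per-record ΔS noise (sd 3 mm) makes ET
vary between replicates; the stored components always recompose to the
stored ET exactly, and WUE = GY/ET holds to machine precision.

**Agronomy.** Grain yield follows a concave quadratic in density whose
optimum (350 seeds m⁻² at full irrigation) shifts downward with the
relative deficit (100 seeds m⁻² per unit deficit), multiplied by a
deficit-loss factor 1 − ky(d)·δ with a density-dependent yield response
factor ky(d) = 0.95 + 0.60·((d − 325)/200)² — lowest near the standard
density, rising toward both extremes, reproducing the U-shaped ky
profile and a pooled ky ≈ 1.25. TDW is GY over a harvest index that
declines slightly with deficit; GLA is concave in density and scaled
down by deficit. Trait noise is multiplicative with cv 5% (per-plot
variance components of real field trials are unknown; these are free
parameters at agronomically plausible magnitudes). The second season
applies a small multiplicative offset (−3%) to the response, keeping
directions identical across seasons.

**Spectra.** Reflectance is cover × vegetation + (1 − cover) × soil
with multiplicative noise (sd 1%), clipped to [0, 1]. The vegetation
endmember is a piecewise-smooth analytic curve: a chlorophyll-darkened
VIS floor with a green peak near 552 nm, a red-edge sigmoid near
718 nm, an NIR plateau saturating as 1 − exp(−0.55·LAI), a SWIR taper
and water-scaled Gaussian absorption troughs near 970, 1200, 1450 and
1940 nm. The soil endmember brightens with wavelength with weak
moisture features. Latent drivers map from the agronomy: LAI ∝ TDW,
cover = 1 − exp(−0.65·LAI), chlorophyll and water proxies decline with
deficit. This yields the qualitative behaviour the indices rely on —
VIS down / NIR up with canopy growth, deeper water troughs with plant
water status — but not PROSAIL-class physics, soil heterogeneity, row
geometry, or instrument artefacts (detector-seam jumps, atmospheric
bands). Passing tests therefore demonstrate correctness of the
*analysis machinery* under known structure, not field-level accuracy.

**Meteorology.** Daily series from December 1 through smooth seasonal
curves calibrated to the site's December–April monthly normals
(e.g. December mean temperature 16.4 °C; the generator's own check
band is ±1.0 °C on the monthly mean) with Gaussian daily weather
noise, physically constrained (Tmax > Tmin, RH ∈ (0, 100), u₂ > 0,
Rn ≥ 0).

**Determinism.** Every plot draws from `default_rng([seed, record
index])`, so equal (config, seed) gives bit-identical output and
subsetting the design (e.g. dropping a season) leaves the remaining
records' draws unchanged.

## Problem sizes and tolerances in the test suite

Oracle comparisons: indices 1e-12; band-search map 1e-10; ETo 1e-10;
ky printed-value reproduction ±0.005 after 2-dp rounding. Statistical
checks run at fixed problem sizes chosen for stable Monte-Carlo
estimates: permutation-null star rate over 50 seeds (expected 5% ± 2%
at α = 0.05); PLSR noise-ceiling gap over 25 seeds at a 15-nm band
thinning (the latent structure survives thinning; the noise ceiling is
the R² of the treatment-conditional mean, the best predictor reachable
from spectra since trait noise is independent of them); basal-ET and
pooled-ky recovery over 50 seeds at ±10% and ±0.1. Pipeline-level
tests use one season and two replicates on the canonical grid.

## Known limitations

* The generator's ky is density-dependent but not rate-dependent;
  published per-combination tables show some rate asymmetry the
  generator does not emulate.
* The XLSX mapper expects the canonical wide layout; arbitrary
  spreadsheet layouts need conversion first.
* SVR with RBF kernels is supported through the hyperparameter grid
  but untuned defaults favour the linear kernel on n ≪ p spectra.
* No split-plot ANOVA / multiple-range testing, no red-edge or
  continuum-removal indices, no three-band exhaustive search — all
  outside the package's scope.
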