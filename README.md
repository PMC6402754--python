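# specyield

Estimating spring-wheat biophysical parameters — green leaf area (GLA,
cm² plant⁻¹), aboveground dry weight (TDW, g m⁻²), grain yield (GY,
g m⁻²) and water use efficiency (WUE, g m⁻² mm⁻¹) — from canopy
hyperspectral reflectance (350–2500 nm) under crossed irrigation-rate
(1.00 / 0.75 / 0.50 of crop ET) × plant-density (150–550 seeds m⁻²)
treatments.

The package is aimed at agronomists and remote-sensing researchers who
want a tested, reproducible implementation of this analysis chain:

* **Spectral indices.** Twenty built-in spectral reflectance indices:
  twelve two-band normalized-difference indices
  NDI(λ₁, λ₂) = (R_λ₁ − R_λ₂)/(R_λ₁ + R_λ₂) plus MSI, SRWI, NWI-3,
  NDVI, NDMI, NMDI, OSAVI and MTVI; user-defined indices via YAML.
* **Exhaustive two-band search.** The contour map
  R²(λ₁, λ₂) = corr(trait, NDI(λ₁, λ₂))² over all wavelength pairs, with
  connected-component extraction of high-R² "hotspot" regions.
* **Treatment-subset regressions.** Simple OLS between each index and
  each trait under five grouping schemes (per irrigation rate n = 10,
  per density n = 6, pooled rates n = 6, pooled densities n = 10, all
  pooled n = 30 on the reference 2-season × 3-rate × 5-density ×
  3-replicate design), with significance stars at 0.05/0.01/0.001.
* **Water budget.** FAO-56 Penman–Monteith reference ET,
  ETo·Kc crop ET with deficit scaling, the seasonal water balance
  ET = ETc + P + Cr − R − D + ΔS, soil-water storage conversion,
  WUE = GY/ET, and the yield response factor
  ky = (1 − GYa/GYm)/(1 − ETa/ETm), per treatment combination and
  pooled (through-origin regression slope).
* **Multivariate calibration.** Full-spectrum PLSR and SVR with
  leave-one-out selection of the latent-factor count (or SVR
  hyperparameters) by minimum RMSECV, then frozen-model validation per
  irrigation rate, density and season (adjusted R², RMSE,
  observed-vs-predicted line).
* **Synthetic experiment generator.** A first-class module producing
  spectra (two-endmember canopy/soil mixture driven by latent LAI,
  chlorophyll and water status), agronomy, water-balance components and
  daily meteorology with the statistical structure the analysis
  assumes — every stage is testable without field data.

## Worked example

```python
from specyield import (SyntheticConfig, generate_experiment,
                       builtin_definitions, index_table,
                       subset_regressions, fit_calibration)
from specyield.pipeline import _ky_table

cfg = SyntheticConfig(seed=1)
dataset, agronomy, water = generate_experiment(cfg)

table = index_table(dataset, builtin_definitions())
reg = subset_regressions(table, agronomy, "all_pooled", traits=("GY",))
best = reg.sort_values("r2", ascending=False).iloc[0]
print(f"best index for GY (all pooled, n={best.n}): {best['index']}, "
      f"R2={best.r2:.2f}{best.stars}")

kt = _ky_table(agronomy)
pooled = kt[kt.density.isna()].set_index("season")["ky"]
print(f"pooled ky: season 1 = {pooled.loc[1]:.2f}, season 2 = {pooled.loc[2]:.2f}")

keys, X = dataset.to_matrix()
y = agronomy.set_index("sample_id").loc[
    [k.sample_id() for k in keys], "GY"].to_numpy()
model = fit_calibration(X, y, max_factors=12, trait="GY",
                        wavelengths=dataset.grid.wavelengths)
print(model.summary())
```

prints

```
best index for GY (all pooled, n=30): NDI_1450_900, R2=0.90***
pooled ky: season 1 = 1.25, season 2 = 1.24
Calibration: PLSR for GY
  bands: 2151 (350-2500 nm)
  preprocessing: mean-centred X and y
  selected setting: {'n_components': 2}
  RMSECV at selection: 40.12
  candidates evaluated: 12
```

Reading: pooling all treatments, the strongest single two-band index
for grain yield is the 1450/900 nm normalized difference (a water
absorption vs NIR reference pair) at R² = 0.90; the pooled yield
response factors ≈ 1.25 mean yield falls slightly faster than
proportionally to the ET deficit; and a 2-factor PLSR on the full
spectrum cross-validates at an RMSE of ≈ 40 g m⁻² grain yield.

The same chain runs from the shell:

```sh
specyield simulate --seed 1 -o experiment/
specyield run config.yaml          # simulate → indices → contour →
                                   # regress → waterbudget → mvmodel
```

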