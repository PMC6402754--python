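"""Synthetic spring-wheat experiment generator.

Emulates a two-season field trial crossing three irrigation rates
(1.00, 0.75, 0.50 of crop ET) with five plant densities (150-550
seeds m-2) in three replicates, producing everything the downstream
analysis consumes:

* per-plot canopy reflectance spectra (350-2500 nm) from a two-
  endmember linear mixture (vegetation x soil) driven by latent plot
  state,
* a per-plot agronomy table (GLA, TDW, GY, seasonal ET, WUE) following
  a concave density response whose optimum shifts downward under
  deficit, with yield losses governed by a density-dependent yield
  response factor,
* per-plot water-balance components that recompose exactly to the ET
  used in WUE,
* a daily meteorology series calibrated to the arid-site monthly
  climate normals (December-April) of the reference experiment.

Determinism: every plot draws from its own RNG stream keyed by
``(seed, record_index)``, so subsetting the design never changes the
values generated for the remaining plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from specyield.spectra import SpectralDataset, Spectrum, TreatmentKey, WavelengthGrid

__all__ = [
    "SyntheticConfig",
    "LatentPlotState",
    "generate_experiment",
    "canopy_spectrum",
    "generate_met_series",
    "soil_endmember",
    "vegetation_endmember",
]

# Monthly climate normals (December-April) used to calibrate the met
# generator: max/min temperature (degC), relative humidity (%).
_MONTH_MID_DAY = np.array([15.0, 46.0, 76.0, 105.0, 136.0])
_TMAX_NORMALS = np.array([22.2, 20.2, 23.4, 27.7, 33.4])
_TMIN_NORMALS = np.array([10.6, 9.0, 11.2, 15.2, 20.4])
_RH_NORMALS = np.array([47.0, 51.0, 41.0, 36.0, 34.0])
_RN_NORMALS = np.array([9.5, 10.5, 13.5, 17.0, 20.5])  # MJ m-2 day-1

#: Calibration band asserted by the generator's own tests: monthly mean
#: December temperature stays within +/-1.0 degC of the site normal.
DECEMBER_MEAN_TEMP_C = 16.4
DECEMBER_TEMP_BAND_C = 1.0


@dataclass(frozen=True)
class LatentPlotState:
    """Latent drivers linking treatments to spectra and traits."""

    cover: float          # fractional vegetation cover, 0-1
    lai: float            # leaf area index
    chlorophyll: float    # canopy chlorophyll proxy, unitless
    water: float          # canopy water proxy, unitless

    def __post_init__(self) -> None:
        if not 0 <= self.cover <= 1:
            raise ValueError(f"cover must be in [0, 1], got {self.cover}")
        for name in ("lai", "chlorophyll", "water"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class SyntheticConfig:
    """Design and effect parameters of the synthetic experiment.

    The treatment structure defaults to the reference design: 2
    seasons x irrigation fractions (1.00, 0.75, 0.50) x densities
    (150...550 seeds m-2) x 3 replicates. Effect parameters shape the
    yield response surface; noise levels are free parameters of the
    generator (per-plot variance components of the field experiment
    are unknown) with defaults at agronomically plausible magnitudes.
    """

    seasons: int = 2
    irrigation_rates: tuple[float, ...] = (1.00, 0.75, 0.50)
    densities: tuple[int, ...] = (150, 250, 350, 450, 550)
    replicates: int = 3
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    # yield response surface
    gy_max: float = 650.0            # g m-2 at the optimum, full irrigation
    density_optimum: float = 350.0   # seeds m-2 under full irrigation
    optimum_shift: float = 100.0     # optimum decrease per unit relative deficit
    density_curvature: float = 0.35  # quadratic loss coefficient
    density_scale: float = 200.0     # seeds m-2 scaling the quadratic
    ky_base: float = 0.95            # minimum yield response factor
    ky_curvature: float = 0.60       # density dependence of ky
    ky_min_density: float = 325.0    # density with the lowest ky
    harvest_index: float = 0.42
    harvest_index_deficit_drop: float = 0.06
    season_effect: float = -0.03     # multiplicative latent offset per extra season

    # water budget (mm); first/second season values cycle for >2 seasons
    full_irrigation_mm: tuple[float, ...] = (558.0, 555.0)
    sowing_water_mm: tuple[float, ...] = (38.0, 45.0)
    effective_precipitation_mm: float = 25.0
    percolation_threshold_mm: float = 500.0
    percolation_fraction: float = 0.12
    storage_depletion_mm: float = 4.0    # dS at full irrigation
    storage_deficit_slope_mm: float = 18.0  # extra dS per unit (1 - rate)

    # noise levels
    spectral_noise_sd: float = 0.01  # multiplicative, per band
    agronomic_cv: float = 0.05       # multiplicative, per trait
    et_noise_sd_mm: float = 3.0      # additive on the storage-change term
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasons < 1:
            raise ValueError(f"seasons must be >= 1, got {self.seasons}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if not self.irrigation_rates:
            raise ValueError("irrigation_rates must be non-empty")
        if any(not 0 < r <= 1 for r in self.irrigation_rates):
            raise ValueError(
                f"irrigation_rates must lie in (0, 1], got {self.irrigation_rates}"
            )
        d = tuple(self.densities)
        if any(b <= a for a, b in zip(d, d[1:])) or not d:
            raise ValueError(
                f"densities must be strictly increasing, got {self.densities}"
            )
        for name in ("spectral_noise_sd", "agronomic_cv", "et_noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.harvest_index < 1:
            raise ValueError(f"harvest_index must be in (0, 1), got {self.harvest_index}")

    # -- deterministic (noise-free) response surface ------------------

    def _season_factor(self, season: int) -> float:
        return 1.0 + self.season_effect * (season - 1)

    def water_components(self, season: int, rate: float) -> dict[str, float]:
        """Noise-free seasonal water-balance components (mm) for one cell."""
        full = self.full_irrigation_mm[(season - 1) % len(self.full_irrigation_mm)]
        sow = self.sowing_water_mm[(season - 1) % len(self.sowing_water_mm)]
        applied = full * rate + sow
        perc = self.percolation_fraction * max(
            0.0, full * rate - self.percolation_threshold_mm
        )
        # profile depletion grows as the deficit deepens
        ds = self.storage_depletion_mm + self.storage_deficit_slope_mm * (1.0 - rate)
        return {
            "irrigation_mm": applied,
            "precipitation_mm": self.effective_precipitation_mm,
            "capillary_rise_mm": 0.0,
            "runoff_mm": 0.0,
            "deep_percolation_mm": perc,
            "storage_change_mm": ds,
        }

    def seasonal_et_mean(self, season: int, rate: float) -> float:
        c = self.water_components(season, rate)
        return (
            c["irrigation_mm"]
            + c["precipitation_mm"]
            + c["capillary_rise_mm"]
            - c["runoff_mm"]
            - c["deep_percolation_mm"]
            + c["storage_change_mm"]
        )

    def relative_deficit(self, season: int, rate: float) -> float:
        full = self.seasonal_et_mean(season, max(self.irrigation_rates))
        return 1.0 - self.seasonal_et_mean(season, rate) / full

    def ky_of_density(self, density: float) -> float:
        z = (density - self.ky_min_density) / self.density_scale
        return self.ky_base + self.ky_curvature * z * z

    def mean_gy(self, season: int, rate: float, density: float) -> float:
        """Expected grain yield (g m-2), noise off."""
        deficit = self.relative_deficit(season, rate)
        d_opt = self.density_optimum - self.optimum_shift * deficit
        z = (density - d_opt) / self.density_scale
        potential = self.gy_max * self._season_factor(season) * max(
            0.05, 1.0 - self.density_curvature * z * z
        )
        loss = self.ky_of_density(density) * deficit
        return potential * max(0.02, 1.0 - loss)

    def mean_traits(self, season: int, rate: float, density: float) -> dict[str, float]:
        deficit = self.relative_deficit(season, rate)
        gy = self.mean_gy(season, rate, density)
        hi = self.harvest_index - self.harvest_index_deficit_drop * deficit
        tdw = gy / hi
        zg = (density - 340.0) / self.density_scale
        gla = (
            130.0
            * self._season_factor(season)
            * (1.0 - 0.7 * deficit)
            * max(0.05, 1.0 - 0.30 * zg * zg)
        )
        return {"GLA": gla, "TDW": tdw, "GY": gy}


# -- spectra -----------------------------------------------------------


def _gauss(w: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-(((w - centre) / width) ** 2))


def soil_endmember(grid: WavelengthGrid) -> np.ndarray:
    """Dry sandy-loam background: brightening with wavelength, weak
    moisture features near 1450 and 1940 nm."""
    w = grid.wavelengths
    base = 0.14 + 0.16 * (1.0 - np.exp(-(w - 350.0) / 800.0))
    base -= 0.03 * _gauss(w, 1450.0, 100.0) + 0.04 * _gauss(w, 1940.0, 120.0)
    return np.clip(base, 0.0, 1.0)


def vegetation_endmember(
    grid: WavelengthGrid, lai: float, chlorophyll: float, water: float
) -> np.ndarray:
    """Green-canopy endmember.

    VIS: low floor deepened by chlorophyll absorption (strongest near
    670 nm) with a green peak near 550 nm. A red-edge sigmoid near
    718 nm hands over to an NIR plateau that saturates with LAI as
    1 - exp(-k LAI). SWIR: the plateau tapers off with wavelength and
    carries water-scaled Gaussian absorption troughs centred near 970,
    1200, 1450 and 1940 nm.
    """
    w = grid.wavelengths
    edge = expit((w - 718.0) / 16.0)
    floor = 0.035 + 0.085 * np.exp(-0.9 * chlorophyll)
    green = 0.05 + 0.04 * np.exp(-0.5 * chlorophyll)
    r_vis = floor + green * _gauss(w, 552.0, 34.0)
    plateau = 0.30 + 0.28 * (1.0 - np.exp(-0.55 * lai))
    taper = 0.35 + 0.65 * np.exp(-np.maximum(0.0, w - 1300.0) / 900.0)
    omega = water / (1.0 + water)
    depth = omega * (
        0.10 * _gauss(w, 970.0, 25.0)
        + 0.14 * _gauss(w, 1200.0, 30.0)
        + 0.55 * _gauss(w, 1450.0, 55.0)
        + 0.70 * _gauss(w, 1940.0, 70.0)
    )
    r_swir = plateau * taper * (1.0 - np.clip(depth, 0.0, 0.95))
    return np.clip((1.0 - edge) * r_vis + edge * r_swir, 0.0, 1.0)


def canopy_spectrum(
    state: LatentPlotState,
    grid: WavelengthGrid,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Two-endmember mixture spectrum for one plot.

    reflectance = cover x vegetation + (1 - cover) x soil, followed by
    multiplicative Gaussian noise of fractional sd ``noise_sd``; output
    clipped to [0, 1].
    """
    veg = vegetation_endmember(grid, state.lai, state.chlorophyll, state.water)
    mixed = state.cover * veg + (1.0 - state.cover) * soil_endmember(grid)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        mixed = mixed * (1.0 + noise_sd * rng.standard_normal(mixed.size))
    return Spectrum(grid, np.clip(mixed, 0.0, 1.0))


def latent_state(config: SyntheticConfig, tdw: float, deficit: float) -> LatentPlotState:
    """Map a plot's dry weight and water status to spectral drivers."""
    lai = max(0.0, tdw / 280.0)
    cover = 1.0 - np.exp(-0.65 * lai)
    chl = max(0.0, 1.5 * (1.0 - 0.6 * deficit))
    water = max(0.0, 1.8 * (1.0 - 0.7 * deficit) * min(lai / 4.0, 1.2))
    return LatentPlotState(float(cover), float(lai), float(chl), float(water))


# -- experiment --------------------------------------------------------


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[SpectralDataset, pd.DataFrame, pd.DataFrame]:
    """Generate spectra, agronomy and water-balance tables for the design.

    Returns one record per season x rate x density x replicate. The
    agronomy table carries GLA (cm2 plant-1), TDW and GY (g m-2),
    seasonal ET (mm) and WUE = GY / ET (exact by construction); the
    water-balance table carries the components that recompose to ET.
    """
    records = []
    agro_rows = []
    wb_rows = []
    idx = 0
    for season in range(1, config.seasons + 1):
        for rate in config.irrigation_rates:
            comps = config.water_components(season, rate)
            deficit = config.relative_deficit(season, rate)
            for density in config.densities:
                means = config.mean_traits(season, rate, density)
                for rep in range(1, config.replicates + 1):
                    rng = np.random.default_rng([config.seed, idx])
                    zs = rng.standard_normal(4)
                    cv = config.agronomic_cv
                    gla = means["GLA"] * max(0.05, 1.0 + cv * zs[0])
                    gy = means["GY"] * max(0.05, 1.0 + cv * zs[1])
                    tdw = means["TDW"] * max(0.05, 1.0 + cv * zs[2])
                    tdw = max(tdw, gy * 1.05)  # biomass cannot fall below grain
                    ds = comps["storage_change_mm"] + config.et_noise_sd_mm * zs[3]
                    et = (
                        comps["irrigation_mm"]
                        + comps["precipitation_mm"]
                        + comps["capillary_rise_mm"]
                        - comps["runoff_mm"]
                        - comps["deep_percolation_mm"]
                        + ds
                    )
                    key = TreatmentKey(season, rate, density, rep)
                    state = latent_state(config, tdw, deficit)
                    spectrum = canopy_spectrum(
                        state, config.grid, config.spectral_noise_sd, rng
                    )
                    records.append((key, spectrum))
                    agro_rows.append(
                        {
                            "sample_id": key.sample_id(),
                            "season": season,
                            "irrigation": rate,
                            "density": density,
                            "replicate": rep,
                            "GLA": gla,
                            "TDW": tdw,
                            "GY": gy,
                            "ET": et,
                            "WUE": gy / et,
                        }
                    )
                    wb_rows.append(
                        {
                            "sample_id": key.sample_id(),
                            "season": season,
                            "irrigation": rate,
                            "density": density,
                            "replicate": rep,
                            **{**comps, "storage_change_mm": ds},
                            "et_mm": et,
                        }
                    )
                    idx += 1
    dataset = SpectralDataset(config.grid, records)
    return dataset, pd.DataFrame(agro_rows), pd.DataFrame(wb_rows)


# -- meteorology -------------------------------------------------------


def generate_met_series(days: int, seed: int | None = None) -> pd.DataFrame:
    """Daily arid-site meteorology for a season starting December 1.

    Temperatures, humidity and net radiation follow smooth seasonal
    curves through the December-April monthly normals with daily
    Gaussian weather noise; vapour-pressure terms (es, ea, delta) are
    derived with the standard psychrometric formulas; gamma is fixed
    at its ~400 m elevation value. Deterministic per seed.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    rng = np.random.default_rng(seed)
    day = np.arange(days, dtype=float)
    tmax = np.interp(day, _MONTH_MID_DAY, _TMAX_NORMALS) + 1.2 * rng.standard_normal(days)
    tmin = np.interp(day, _MONTH_MID_DAY, _TMIN_NORMALS) + 1.0 * rng.standard_normal(days)
    tmin = np.minimum(tmin, tmax - 1.0)
    tmean = 0.5 * (tmax + tmin)
    rh = np.clip(
        np.interp(day, _MONTH_MID_DAY, _RH_NORMALS) + 4.0 * rng.standard_normal(days),
        5.0,
        95.0,
    )
    u2 = np.abs(2.0 + 0.8 * rng.standard_normal(days)) + 0.1
    rn = np.clip(
        np.interp(day, _MONTH_MID_DAY, _RN_NORMALS) + 1.5 * rng.standard_normal(days),
        0.5,
        None,
    )
    rain = np.where(rng.random(days) < 0.06, rng.exponential(5.0, days), 0.0)
    e0 = lambda t: 0.6108 * np.exp(17.27 * t / (t + 237.3))
    es = 0.5 * (e0(tmax) + e0(tmin))
    ea = es * rh / 100.0
    delta = 4098.0 * e0(tmean) / (tmean + 237.3) ** 2
    return pd.DataFrame(
        {
            "day": np.arange(1, days + 1),
            "t_max": tmax,
            "t_min": tmin,
            "t_mean": tmean,
            "rh": rh,
            "u2": u2,
            "rn": rn,
            "g": 0.0,
            "rain_mm": rain,
            "es": es,
            "ea": ea,
            "delta": delta,
            "gamma": 0.0643,
        }
    )
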