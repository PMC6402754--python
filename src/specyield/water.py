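"""Water budget: FAO-56 reference ET, crop ET, water balance, WUE and ky.

Units are mm of water depth unless stated otherwise. The seasonal
actual crop evapotranspiration of a plot is closed by the general
water balance

    ET = ETc + P + Cr - R - D + dS

where ETc is the irrigation water applied (crop ET scaled by the
deficit factor), P effective precipitation, Cr capillary rise, R
surface runoff, D deep percolation below the root zone, and dS the
soil-water storage change taken as storage(sowing) - storage(harvest),
so that net depletion of the profile adds to ET.

The yield response factor ky relates the relative yield decrease
1 - GYa/GYm to the relative ET deficit 1 - ETa/ETm; ky < 1 marks
tolerance to deficit irrigation. Pooled ky over several deficit
treatments is the slope of a through-origin regression by default
(the classical production-function form), with a free-intercept
option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DailyMet",
    "IrrigationPlan",
    "WaterBalanceInputs",
    "SoilProfile",
    "KyRecord",
    "penman_monteith_eto",
    "seasonal_etc",
    "seasonal_et",
    "soil_water_storage",
    "volumetric_water_storage",
    "deep_percolation",
    "ky_single",
    "ky_pooled",
    "wue",
    "saturation_vapour_pressure",
    "svp_slope",
]


def saturation_vapour_pressure(t_celsius: float) -> float:
    """Tetens form e0(T) in kPa."""
    return 0.6108 * math.exp(17.27 * t_celsius / (t_celsius + 237.3))


def svp_slope(t_celsius: float) -> float:
    """Slope of the saturation vapour pressure curve, kPa per deg C."""
    return 4098.0 * saturation_vapour_pressure(t_celsius) / (t_celsius + 237.3) ** 2


@dataclass
class DailyMet:
    """One day of meteorology for the reference-ET calculation.

    rn and g in MJ m-2 day-1, temperatures in deg C, u2 in m s-1 at 2 m,
    rh in %, vapour pressures in kPa, gamma and delta in kPa per deg C.
    es/ea/delta default to the FAO formulas evaluated from the
    temperatures and humidity when not given explicitly.
    """

    rn: float
    t_mean: float
    t_max: float
    t_min: float
    u2: float
    rh: float
    g: float = 0.0
    gamma: float = 0.0655
    es: float | None = None
    ea: float | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise ValueError(f"t_max ({self.t_max}) < t_min ({self.t_min})")
        if not 0 < self.rh <= 100:
            raise ValueError(f"relative humidity must be in (0, 100], got {self.rh}")
        if self.u2 < 0:
            raise ValueError(f"wind speed must be >= 0, got {self.u2}")
        if self.es is None:
            self.es = 0.5 * (
                saturation_vapour_pressure(self.t_max)
                + saturation_vapour_pressure(self.t_min)
            )
        if self.ea is None:
            self.ea = self.es * self.rh / 100.0
        if self.delta is None:
            self.delta = svp_slope(self.t_mean)
        if self.ea > self.es + 1e-12:
            raise ValueError(f"ea ({self.ea}) exceeds es ({self.es})")


def penman_monteith_eto(met: DailyMet) -> float:
    """FAO-56 Penman-Monteith reference evapotranspiration, mm day-1.

    ETo = [0.408 D (Rn - G) + g 900/(T+273) u2 (es - ea)]
          / [D + g (1 + 0.34 u2)]

    clipped at zero (condensation conditions report 0, not negative ET).
    """
    num = 0.408 * met.delta * (met.rn - met.g) + met.gamma * (
        900.0 / (met.t_mean + 273.0)
    ) * met.u2 * (met.es - met.ea)
    den = met.delta + met.gamma * (1.0 + 0.34 * met.u2)
    return max(0.0, num / den)


@dataclass
class IrrigationPlan:
    """Season-long irrigation schedule for one deficit treatment.

    ``eto`` is the daily reference-ET series (mm day-1), ``kc`` the
    matching daily crop coefficient (a scalar is broadcast), and
    ``deficit_factor`` the fraction of full crop ET actually applied
    (1.00, 0.75 or 0.50 in the reference design). ``events`` are the
    stage-timed application amounts; ``sowing_mm`` the germination
    application given to all treatments.
    """

    eto: np.ndarray
    kc: np.ndarray | float = 1.0
    deficit_factor: float = 1.0
    events: tuple[float, ...] = ()
    sowing_mm: float = 0.0

    def __post_init__(self) -> None:
        self.eto = np.asarray(self.eto, dtype=float)
        kc = np.broadcast_to(np.asarray(self.kc, dtype=float), self.eto.shape).copy()
        if np.any(kc <= 0):
            raise ValueError("crop coefficient Kc must be > 0")
        self.kc = kc
        if not 0 < self.deficit_factor <= 1:
            raise ValueError(
                f"deficit factor must be in (0, 1], got {self.deficit_factor}"
            )
        if any(e < 0 for e in self.events) or self.sowing_mm < 0:
            raise ValueError("application amounts must be >= 0")


def seasonal_etc(plan: IrrigationPlan) -> float:
    """Seasonal irrigation requirement: sum(ETo * Kc) * deficit factor, mm."""
    return float(np.sum(plan.eto * plan.kc) * plan.deficit_factor)


@dataclass
class WaterBalanceInputs:
    """Components of the seasonal water balance, all in mm.

    Capillary rise and runoff default to zero (deep groundwater;
    diked basins under low-pressure surface irrigation).
    """

    etc: float
    precipitation: float = 0.0
    capillary_rise: float = 0.0
    runoff: float = 0.0
    deep_percolation: float = 0.0
    storage_change: float = 0.0  # storage(sowing) - storage(harvest)

    def __post_init__(self) -> None:
        for name in (
            "etc", "precipitation", "capillary_rise", "runoff",
            "deep_percolation", "storage_change",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def seasonal_et(inputs: WaterBalanceInputs) -> float:
    """Close the water balance: ET = ETc + P + Cr - R - D + dS (mm)."""
    et = (
        inputs.etc
        + inputs.precipitation
        + inputs.capillary_rise
        - inputs.runoff
        - inputs.deep_percolation
        + inputs.storage_change
    )
    if et <= 0:
        raise ValueError(f"water balance closes to non-positive ET ({et:.3f} mm)")
    return float(et)


@dataclass(frozen=True)
class SoilProfile:
    """Root-zone soil hydraulics: volumetric FC and PWP, bulk density, depth."""

    field_capacity: float = 0.151   # m3 m-3
    wilting_point: float = 0.054    # m3 m-3
    bulk_density: float = 1.49      # g cm-3
    depth_m: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.wilting_point < self.field_capacity < 0.6:
            raise ValueError("need 0 < PWP < FC < 0.6 m3 m-3")
        if self.depth_m <= 0 or self.bulk_density <= 0:
            raise ValueError("depth and bulk density must be > 0")

    @property
    def capacity_mm(self) -> float:
        """Water held at field capacity over the profile depth, mm."""
        return volumetric_water_storage(self.field_capacity, self.depth_m)


def soil_water_storage(gravimetric_content: float, soil: SoilProfile) -> float:
    """Convert gravimetric water content (g/g) to mm over the profile.

    mm = gravimetric x bulk density x depth(m) x 1000 (bulk density in
    g cm-3 doubles as the dimensionless ratio to water density).
    """
    if gravimetric_content < 0:
        raise ValueError("gravimetric content must be >= 0")
    return gravimetric_content * soil.bulk_density * soil.depth_m * 1000.0


def volumetric_water_storage(theta: float, depth_m: float) -> float:
    """Volumetric content (m3 m-3) to mm over ``depth_m``."""
    if theta < 0 or depth_m <= 0:
        raise ValueError("need theta >= 0 and depth > 0")
    return theta * depth_m * 1000.0


def deep_percolation(
    pre_irrigation_storage_mm: float, applied_mm: float, soil: SoilProfile
) -> float:
    """Capacity-overflow estimate of percolation below the root zone.

    Water applied on top of the pre-irrigation profile storage that
    exceeds field-capacity storage is taken to drain below the root
    zone.
    """
    if pre_irrigation_storage_mm < 0 or applied_mm < 0:
        raise ValueError("storages and applications must be >= 0")
    return max(0.0, pre_irrigation_storage_mm + applied_mm - soil.capacity_mm)


@dataclass
class KyRecord:
    """One deficit observation: relative ET deficit, relative GY decrease, ky."""

    et_deficit: float
    gy_decrease: float
    ky: float | None

    @property
    def defined(self) -> bool:
        return self.ky is not None


def ky_single(ETa: float, ETm: float, GYa: float, GYm: float) -> KyRecord:
    """Yield response factor from one actual/maximum pair.

    ky = (1 - GYa/GYm) / (1 - ETa/ETm). A zero ET deficit leaves ky
    undefined (flagged None). Report ky rounded to 2 decimals; the
    record keeps full precision.
    """
    if not (ETm > 0 and 0 < ETa <= ETm):
        raise ValueError(f"need 0 < ETa <= ETm, got ETa={ETa}, ETm={ETm}")
    if GYm <= 0 or GYa < 0:
        raise ValueError(f"need GYm > 0 and GYa >= 0, got GYa={GYa}, GYm={GYm}")
    deficit = 1.0 - ETa / ETm
    decrease = 1.0 - GYa / GYm
    ky = decrease / deficit if deficit > 0 else None
    return KyRecord(deficit, decrease, ky)


def ky_pooled(
    records: Iterable[tuple[float, float] | KyRecord],
    method: str = "through_origin",
) -> float:
    """Pooled ky: regression slope of relative GY decrease on relative ET deficit.

    ``through_origin`` (default) is sum(xy)/sum(x^2); ``free_intercept``
    is the ordinary least-squares slope.
    """
    pairs = [
        (r.et_deficit, r.gy_decrease) if isinstance(r, KyRecord) else (r[0], r[1])
        for r in records
    ]
    if len(pairs) < 1:
        raise ValueError("need at least one record")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if method == "through_origin":
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise ValueError("all ET deficits are zero; pooled ky undefined")
        return float(np.sum(x * y) / sxx)
    if method == "free_intercept":
        if x.size < 2 or np.ptp(x) == 0:
            raise ValueError("free-intercept slope needs >= 2 distinct deficits")
        return float(np.polyfit(x, y, 1)[0])
    raise ValueError(f"unknown method {method!r}")


def wue(GY: float, ET: float) -> float:
    """Water use efficiency: grain yield per unit seasonal ET (g m-2 mm-1)."""
    if ET <= 0:
        raise ValueError(f"ET must be > 0, got {ET}")
    if GY < 0:
        raise ValueError(f"GY must be >= 0, got {GY}")
    return GY / ET
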