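"""Canopy spectra: containers, file I/O, calibration, resampling, averaging.

The canonical container is a :class:`SpectralDataset`: a shared integer-nm
:class:`WavelengthGrid` plus one :class:`Spectrum` per experimental unit,
keyed by a :class:`TreatmentKey` (season, irrigation fraction, plant
density, replicate).

Two on-disk dialects are supported:

``wide_csv``
    First column ``wavelength_nm``; one column per sample, named
    ``S{season}_I{rate}_D{density}_R{replicate}`` (e.g. ``S1_I0.75_D350_R2``).
    Wavelengths ascend; sample columns are ordered by sorted key.
``xlsx``
    The same layout on the first worksheet of an Excel workbook.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "TreatmentKey",
    "SpectralDataset",
    "SpectraIOError",
    "read_spectra",
    "write_spectra",
    "calibrate_reflectance",
    "average_spectra",
    "resample_to_grid",
]


class SpectraIOError(ValueError):
    """Raised for malformed spectra files or invalid calibration input."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Regular wavelength grid in nanometres (inclusive of both ends).

    The canonical grid is 350-2500 nm at 1 nm (2151 bands), the working
    resolution of field spectroradiometer data after resampling.
    """

    start_nm: float = 350.0
    end_nm: float = 2500.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})"
            )
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = self.n_bands
        return self.start_nm + self.step_nm * np.arange(n)

    @property
    def n_bands(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def index_of(self, wavelength_nm: float) -> int:
        """Exact band index of ``wavelength_nm``; raises if off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if idx < 0 or idx >= self.n_bands or abs(pos - idx) > 1e-9:
            raise KeyError(f"wavelength {wavelength_nm} nm is not on the grid")
        return idx


@dataclass
class Spectrum:
    """A single reflectance spectrum on a :class:`WavelengthGrid`.

    Reflectances are fractions; values above 1 are tolerated with a
    warning (specular or panel effects), negative values are rejected.
    """

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.grid.n_bands:
            raise ValueError(
                f"expected {self.grid.n_bands} values, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("spectrum contains negative reflectance")
        if np.any(self.values > 1):
            warnings.warn(
                "reflectance values above 1 present (specular/panel effects?)",
                stacklevel=2,
            )

    def at(self, wavelength_nm: float) -> float:
        """Reflectance at an on-grid wavelength."""
        return float(self.values[self.grid.index_of(wavelength_nm)])


class TreatmentKey(NamedTuple):
    """Experimental-unit key: season, irrigation ET fraction, density, replicate."""

    season: int
    irrigation: float
    density: int
    replicate: int

    def sample_id(self) -> str:
        return f"S{self.season}_I{self.irrigation:.2f}_D{self.density}_R{self.replicate}"

    @classmethod
    def from_sample_id(cls, sample_id: str) -> "TreatmentKey":
        m = re.fullmatch(r"S(\d+)_I([\d.]+)_D(\d+)_R(\d+)", sample_id)
        if m is None:
            raise SpectraIOError(f"cannot parse sample column name {sample_id!r}")
        return cls(int(m.group(1)), float(m.group(2)), int(m.group(3)), int(m.group(4)))


@dataclass
class SpectralDataset:
    """Spectra for a whole experiment on one shared grid, keys unique."""

    grid: WavelengthGrid
    records: list[tuple[TreatmentKey, Spectrum]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[TreatmentKey] = set()
        for key, spec in self.records:
            if spec.grid != self.grid:
                raise ValueError(f"spectrum for {key} is not on the shared grid")
            if key in seen:
                raise SpectraIOError(f"duplicate sample key {key.sample_id()}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keys(self) -> list[TreatmentKey]:
        return [k for k, _ in self.records]

    def to_matrix(self) -> tuple[list[TreatmentKey], np.ndarray]:
        """Return keys and an (n_samples, n_bands) reflectance matrix."""
        X = np.vstack([s.values for _, s in self.records]) if self.records else (
            np.empty((0, self.grid.n_bands))
        )
        return self.keys, X

    def subset(self, predicate) -> "SpectralDataset":
        return SpectralDataset(
            self.grid, [(k, s) for k, s in self.records if predicate(k)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide frame: wavelength_nm column plus one column per sorted sample."""
        data = {"wavelength_nm": self.grid.wavelengths}
        for key, spec in sorted(self.records, key=lambda r: r[0]):
            data[key.sample_id()] = spec.values
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectralDataset":
        if "wavelength_nm" not in frame.columns:
            raise SpectraIOError("missing required column 'wavelength_nm'")
        wl = frame["wavelength_nm"].to_numpy(dtype=float)
        if wl.size < 2:
            raise SpectraIOError("need at least two wavelength rows")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise SpectraIOError("wavelength_nm must be strictly increasing")
        step = steps[0]
        if not np.allclose(steps, step):
            raise SpectraIOError("wavelength_nm is not on a regular grid")
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
        records = []
        for col in frame.columns:
            if col == "wavelength_nm":
                continue
            key = TreatmentKey.from_sample_id(str(col))
            vals = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isfinite(vals))
            if bad.size:
                raise SpectraIOError(
                    f"non-numeric reflectance in column {col!r} at row {bad[0]}"
                )
            records.append((key, Spectrum(grid, vals)))
        return cls(grid, records)


def read_spectra(path: str | Path, dialect: str = "wide_csv") -> SpectralDataset:
    """Read a :class:`SpectralDataset` from ``wide_csv`` or ``xlsx``.

    Duplicate sample keys, a missing wavelength column and non-numeric
    reflectance are reported with row/column context.
    """
    path = Path(path)
    if not path.exists():
        raise SpectraIOError(f"spectra file not found: {path}")
    if dialect == "wide_csv":
        frame = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "xlsx":
        frame = pd.read_excel(path, sheet_name=0, engine="openpyxl")
    else:
        raise SpectraIOError(f"unknown dialect {dialect!r}")
    return SpectralDataset.from_frame(frame)


def write_spectra(
    dataset: SpectralDataset, path: str | Path, dialect: str = "wide_csv"
) -> Path:
    """Write a dataset deterministically (wavelength ascending, sorted keys)."""
    path = Path(path)
    frame = dataset.to_frame()
    if dialect == "wide_csv":
        # default float repr is shortest-round-trip: read(write(ds)) == ds
        frame.to_csv(path, index=False)
    elif dialect == "xlsx":
        frame.to_excel(path, index=False, engine="openpyxl")
    else:
        raise SpectraIOError(f"unknown dialect {dialect!r}")
    return path


def calibrate_reflectance(
    target_radiance: Sequence[float], reference_radiance: Sequence[float],
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """White-panel calibration: elementwise target / reference radiance.

    The reference is the radiance of the white calibration panel; the
    ratio is the reflectance factor. Any non-positive reference value
    is an error naming the offending band.
    """
    t = np.asarray(target_radiance, dtype=float)
    r = np.asarray(reference_radiance, dtype=float)
    if t.shape != r.shape:
        raise SpectraIOError(
            f"target and reference lengths differ: {t.shape} vs {r.shape}"
        )
    bad = np.flatnonzero(r <= 0)
    if bad.size:
        if grid is not None:
            where = f"{grid.wavelengths[bad[0]]:g} nm"
        else:
            where = f"band index {bad[0]}"
        raise SpectraIOError(f"reference radiance <= 0 at {where}")
    return t / r


def average_spectra(spectra: Iterable[Spectrum]) -> Spectrum:
    """Bandwise arithmetic mean of >=1 spectra on a common grid.

    Mirrors the field protocol of averaging sequential scans per plot.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("spectra are not on a common grid")
    return Spectrum(grid, np.mean([s.values for s in spectra], axis=0))


def resample_to_grid(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation onto ``grid``; exact at coincident wavelengths.

    Extrapolation outside the source support is refused.
    """
    src = spectrum.grid
    if grid.start_nm < src.start_nm - 1e-9 or grid.end_nm > src.end_nm + 1e-9:
        raise ValueError(
            f"target grid [{grid.start_nm}, {grid.end_nm}] nm extends outside "
            f"source support [{src.start_nm}, {src.end_nm}] nm"
        )
    if grid == src:
        return Spectrum(grid, spectrum.values.copy())
    vals = np.interp(grid.wavelengths, src.wavelengths, spectrum.values)
    return Spectrum(grid, vals)
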