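"""Exhaustive two-band normalized-difference index discovery.

For every wavelength pair (l1, l2) on a (possibly subsampled) grid,
regress a target trait on NDI(l1, l2) across samples and record the
coefficient of determination. The resulting symmetric R^2 surface is
the contour map from which new indices are selected; contiguous
high-R^2 regions ("hotspots") are extracted by connected-component
labelling.

R^2 is computed as the squared Pearson correlation between trait and
index, which for a single regressor equals the OLS coefficient of
determination. Cells where the index is constant across samples
(including the whole diagonal, NDI(l, l) = 0) are masked undefined and
stored as 0 under the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from specyield.spectra import SpectralDataset

__all__ = ["R2Matrix", "Hotspot", "ndi_r2_map", "hotspot_extract"]


@dataclass
class R2Matrix:
    """Symmetric R^2 surface over wavelength pairs.

    ``values[i, j]`` is R^2 of trait ~ NDI(wavelengths[i], wavelengths[j]);
    ``defined[i, j]`` is False where the index was constant or ill-posed.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    defined: np.ndarray
    trait: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        b = self.wavelengths.size
        if self.values.shape != (b, b) or self.defined.shape != (b, b):
            raise ValueError("matrix shapes do not match the wavelength axis")

    def best_pair(self) -> tuple[float, float, float]:
        """(l1, l2, R^2) of the maximum defined cell."""
        masked = np.where(self.defined, self.values, -1.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        return float(self.wavelengths[i]), float(self.wavelengths[j]), float(
            self.values[i, j]
        )


@dataclass
class Hotspot:
    """A 4-connected region of the map at or above an R^2 threshold."""

    lambda1_range: tuple[float, float]
    lambda2_range: tuple[float, float]
    peak_r2: float
    peak_pair: tuple[float, float]
    n_cells: int


def ndi_r2_map(
    dataset: SpectralDataset,
    trait: np.ndarray,
    step_nm: float = 4.0,
) -> R2Matrix:
    """Build the full dual-wavelength NDI-vs-trait R^2 map.

    Parameters
    ----------
    dataset
        Spectra on a shared grid; ``trait`` must be aligned with
        ``dataset.records`` order.
    trait
        Per-sample trait values (n >= 3).
    step_nm
        Wavelength subsampling step; 1 reproduces the full-resolution
        map (expensive), the default 4 nm is adequate for hotspot
        geometry.
    """
    trait = np.asarray(trait, dtype=float)
    keys, X = dataset.to_matrix()
    n = len(keys)
    if trait.shape != (n,):
        raise ValueError(
            f"trait has shape {trait.shape}, expected ({n},) aligned to dataset"
        )
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if step_nm < dataset.grid.step_nm:
        raise ValueError("step_nm must be >= the dataset grid step")

    stride = max(1, int(round(step_nm / dataset.grid.step_nm)))
    wl = dataset.grid.wavelengths[::stride]
    R = X[:, ::stride]  # (n, B)
    B = wl.size

    yc = trait - trait.mean()
    sy = np.sqrt(np.sum(yc**2))
    values = np.zeros((B, B))
    defined = np.zeros((B, B), dtype=bool)
    if sy == 0:
        # constant trait: every regression is undefined
        return R2Matrix(wl, values, defined, trait="", n=n)

    # One row of the map at a time: NDI of band i against every band j.
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(B):
            ri = R[:, i : i + 1]  # (n, 1)
            denom = ri + R
            ndi = np.where(denom != 0, (ri - R) / denom, np.nan)  # (n, B)
            ok = np.all(np.isfinite(ndi), axis=0)
            xc = ndi - np.nanmean(ndi, axis=0)
            sx = np.sqrt(np.nansum(xc**2, axis=0))
            ok &= sx > 0
            num = np.nansum(xc * yc[:, None], axis=0)
            r2 = np.zeros(B)
            r2[ok] = (num[ok] / (sx[ok] * sy)) ** 2
            values[i] = np.where(ok, np.clip(r2, 0.0, 1.0), 0.0)
            defined[i] = ok
    return R2Matrix(wl, values, defined, trait="", n=n)


def hotspot_extract(r2map: R2Matrix, threshold: float) -> list[Hotspot]:
    """Extract 4-connected supra-threshold regions, sorted by peak R^2."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    above = (r2map.values >= threshold) & r2map.defined
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_regions = ndimage.label(above, structure=structure)
    wl = r2map.wavelengths
    hotspots: list[Hotspot] = []
    for lab in range(1, n_regions + 1):
        ii, jj = np.nonzero(labels == lab)
        region_vals = r2map.values[ii, jj]
        k = int(np.argmax(region_vals))
        hotspots.append(
            Hotspot(
                lambda1_range=(float(wl[ii.min()]), float(wl[ii.max()])),
                lambda2_range=(float(wl[jj.min()]), float(wl[jj.max()])),
                peak_r2=float(region_vals[k]),
                peak_pair=(float(wl[ii[k]]), float(wl[jj[k]])),
                n_cells=int(ii.size),
            )
        )
    hotspots.sort(key=lambda h: h.peak_r2, reverse=True)
    return hotspots
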