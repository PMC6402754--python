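"""Spectral reflectance indices (SRIs).

Twenty built-in definitions: twelve two-band normalized-difference
indices selected from contour-map hotspots, and eight published indices
(MSI, SRWI, NWI-3, NDVI, NDMI, NMDI, OSAVI, MTVI). Arbitrary user
definitions of the same five kinds are supported and can be loaded from
YAML.

NMDI grouping
-------------
The NMDI has two circulating algebraic forms. The default here is the
literature form

    (R860 - (R1640 - R2130)) / (R860 + (R1640 - R2130))

in which the SWIR difference R1640 - R2130 acts as the "measurement"
band. A variant with the difference in the numerator but the *sum*
R1640 + R2130 in the denominator also appears in print; it is available
via ``IndexDefinition(..., constants={"variant": "sum_denominator"})``
or the ``nmdi_as_printed=True`` convenience flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from specyield.spectra import SpectralDataset, Spectrum

__all__ = [
    "IndexDefinition",
    "IndexComputationError",
    "builtin_definitions",
    "normalized_difference",
    "compute_index",
    "index_table",
    "load_definitions",
]

KINDS = ("normalized_difference", "simple_ratio", "osavi", "mtvi", "nmdi")

_BANDS_PER_KIND = {
    "normalized_difference": 2,
    "simple_ratio": 2,
    "osavi": 2,
    "mtvi": 3,
    "nmdi": 3,
}


class IndexComputationError(ValueError):
    """Raised for undefined index values (zero denominators, bad kinds)."""


@dataclass(frozen=True)
class IndexDefinition:
    """A named index formula over specific wavelengths.

    ``bands`` are wavelengths in nm: 2 for normalized_difference /
    simple_ratio / osavi, 3 for mtvi (NIR, green, red) and nmdi
    (NIR, SWIR1, SWIR2). ``constants`` carries formula constants
    (OSAVI soil term 0.16; MTVI scale factors 1.2 / 2.5) and the NMDI
    variant switch.
    """

    name: str
    kind: str
    bands: tuple[float, ...]
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown index kind {self.kind!r}")
        object.__setattr__(self, "bands", tuple(float(b) for b in self.bands))
        expected = _BANDS_PER_KIND[self.kind]
        if len(self.bands) != expected:
            raise ValueError(
                f"{self.kind} needs {expected} bands, got {len(self.bands)}"
            )


def builtin_definitions(nmdi_as_printed: bool = False) -> list[IndexDefinition]:
    """The 20 built-in SRI definitions (12 new NDIs + 8 published indices)."""
    nd_pairs = [
        (548, 522), (626, 386), (680, 1650), (840, 818),
        (1226, 670), (1382, 670), (1450, 900), (1650, 920),
        (2450, 2100), (2498, 1450), (2500, 2250), (2500, 2470),
    ]
    defs = [
        IndexDefinition(f"NDI_{a}_{b}", "normalized_difference", (a, b))
        for a, b in nd_pairs
    ]
    defs += [
        IndexDefinition("MSI", "simple_ratio", (1600, 820)),
        IndexDefinition("SRWI", "simple_ratio", (860, 1240)),
        IndexDefinition("NWI-3", "normalized_difference", (970, 880)),
        IndexDefinition("NDVI", "normalized_difference", (900, 685)),
        IndexDefinition("NDMI", "normalized_difference", (2200, 1100)),
        IndexDefinition(
            "NMDI",
            "nmdi",
            (860, 1640, 2130),
            {"variant": "sum_denominator" if nmdi_as_printed else "literature"},
        ),
        IndexDefinition("OSAVI", "osavi", (800, 670), {"soil_adjust": 0.16}),
        IndexDefinition(
            "MTVI", "mtvi", (800, 550, 670), {"outer": 1.2, "inner": 1.2, "red": 2.5}
        ),
    ]
    return defs


def normalized_difference(spectrum: Spectrum, lambda1: float, lambda2: float) -> float:
    """(R_l1 - R_l2) / (R_l1 + R_l2); in [-1, 1] for nonnegative reflectance."""
    r1, r2 = spectrum.at(lambda1), spectrum.at(lambda2)
    denom = r1 + r2
    if denom == 0:
        raise IndexComputationError(
            f"zero denominator in normalized difference ({lambda1}, {lambda2}) nm"
        )
    return (r1 - r2) / denom


def compute_index(spectrum: Spectrum, definition: IndexDefinition) -> float:
    """Evaluate one index definition on one spectrum."""
    kind = definition.kind
    b = definition.bands
    c = definition.constants
    if kind == "normalized_difference":
        return normalized_difference(spectrum, b[0], b[1])
    if kind == "simple_ratio":
        r1, r2 = spectrum.at(b[0]), spectrum.at(b[1])
        if r2 == 0:
            raise IndexComputationError(
                f"zero denominator in ratio {definition.name} at {b[1]} nm"
            )
        return r1 / r2
    if kind == "osavi":
        r1, r2 = spectrum.at(b[0]), spectrum.at(b[1])
        soil = c.get("soil_adjust", 0.16)
        denom = r1 + r2 + soil
        if denom == 0:
            raise IndexComputationError(f"zero denominator in {definition.name}")
        return (r1 - r2) / denom
    if kind == "mtvi":
        nir, green, red = (spectrum.at(w) for w in b)
        outer = c.get("outer", 1.2)
        inner = c.get("inner", 1.2)
        redk = c.get("red", 2.5)
        return outer * (inner * (nir - green) - redk * (red - green))
    if kind == "nmdi":
        nir, swir1, swir2 = (spectrum.at(w) for w in b)
        diff = swir1 - swir2
        if c.get("variant", "literature") == "sum_denominator":
            denom = nir + (swir1 + swir2)
        else:
            denom = nir + diff
        if denom == 0:
            raise IndexComputationError(f"zero denominator in {definition.name}")
        return (nir - diff) / denom
    raise IndexComputationError(f"unknown index kind {kind!r}")


def index_table(
    dataset: SpectralDataset, definitions: Sequence[IndexDefinition]
) -> pd.DataFrame:
    """Index matrix: one row per sample (sorted key), one column per index.

    Per-cell failures are re-raised with sample and index context.
    """
    names = [d.name for d in definitions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate index names in definitions")
    rows = {}
    for key, spectrum in sorted(dataset.records, key=lambda r: r[0]):
        vals = []
        for d in definitions:
            try:
                vals.append(compute_index(spectrum, d))
            except (IndexComputationError, KeyError) as exc:
                raise IndexComputationError(
                    f"sample {key.sample_id()}, index {d.name}: {exc}"
                ) from exc
        rows[key.sample_id()] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    out.index.name = "sample_id"
    return out


def load_definitions(path: str | Path) -> list[IndexDefinition]:
    """Load index definitions from a YAML list of {name, kind, bands, constants}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("definitions YAML must be a list")
    return [
        IndexDefinition(
            name=item["name"],
            kind=item["kind"],
            bands=tuple(item["bands"]),
            constants=dict(item.get("constants", {})),
        )
        for item in raw
    ]
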