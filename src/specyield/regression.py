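"""Treatment-subset simple regressions between indices and agronomic traits.

Replicates the reporting structure of index-vs-trait tables under five
grouping schemes applied to an experiment of S seasons x 3 irrigation
rates x 5 plant densities x R replicates. Replicate means are formed
first; season stays a separate data point throughout. On the reference
design (2 seasons, 3 replicates) the schemes give the sample counts:

================  ==============================================  ==
scheme            points entering each regression                  n
================  ==============================================  ==
per_irrigation    densities x seasons, within one rate            10
per_density       rates x seasons, within one density              6
pooled_rates      rate means over densities, x seasons             6
pooled_densities  density means over rates, x seasons             10
all_pooled        every season x rate x density mean              30
================  ==============================================  ==

Means for the pooled schemes are taken over *index values* and trait
values, not over spectra: indices are nonlinear in reflectance, so the
order matters, and the tables are built from per-plot derived
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "GROUPING_SCHEMES",
    "simple_linear_fit",
    "significance_stars",
    "iter_groups",
    "subset_regressions",
    "production_function",
]

GROUPING_SCHEMES = (
    "per_irrigation",
    "per_density",
    "pooled_rates_means",
    "pooled_density_means",
    "all_pooled",
)

TREATMENT_COLS = ["season", "irrigation", "density"]


@dataclass
class RegressionResult:
    """Simple OLS fit: slope, intercept, R^2 (= squared Pearson r), p, n."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    defined: bool = True


def simple_linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with a two-sided t-test on the slope (n-2 df).

    A constant regressor yields a flagged-undefined result rather than
    an exception, so table builders can mask such cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, n, defined=False)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=n,
    )


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def _replicate_means(merged: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    return (
        merged.groupby(TREATMENT_COLS, as_index=False)[value_cols]
        .mean()
        .sort_values(TREATMENT_COLS, ignore_index=True)
    )


def iter_groups(
    merged: pd.DataFrame, scheme: str, value_cols: list[str]
) -> Iterator[tuple[str, pd.DataFrame]]:
    """Yield (group label, data frame of points) for one grouping scheme.

    ``merged`` holds one row per plot with treatment columns plus the
    value columns (indices and traits); replicate means are always
    taken first.
    """
    means = _replicate_means(merged, value_cols)
    if scheme == "per_irrigation":
        for rate, grp in means.groupby("irrigation", sort=True):
            yield f"I{rate:.2f}", grp
    elif scheme == "per_density":
        for dens, grp in means.groupby("density", sort=True):
            yield f"D{int(dens)}", grp
    elif scheme == "pooled_rates_means":
        pooled = (
            means.groupby(["season", "irrigation"], as_index=False)[value_cols].mean()
        )
        yield "all_rates", pooled
    elif scheme == "pooled_density_means":
        pooled = (
            means.groupby(["season", "density"], as_index=False)[value_cols].mean()
        )
        yield "all_densities", pooled
    elif scheme == "all_pooled":
        yield "all", means
    else:
        raise ValueError(f"unknown grouping scheme {scheme!r}")


def subset_regressions(
    index_matrix: pd.DataFrame,
    agronomy: pd.DataFrame,
    scheme: str,
    traits: Sequence[str] = ("GLA", "TDW", "GY", "WUE"),
) -> pd.DataFrame:
    """Tidy regression table for every (index, trait) cell under one scheme.

    ``index_matrix`` is indexed by sample_id (one column per index);
    ``agronomy`` carries sample_id plus treatment columns and traits.
    Groups with fewer than 3 points are skipped. Columns: scheme,
    group, index, trait, n, slope, intercept, r2, p, stars,
    significant (bold flag at p <= 0.05).
    """
    agro = agronomy.set_index("sample_id") if "sample_id" in agronomy.columns else agronomy
    missing = [t for t in traits if t not in agro.columns]
    if missing:
        raise ValueError(f"agronomy table lacks trait columns {missing}")
    merged = index_matrix.join(agro, how="inner")
    if len(merged) != len(index_matrix):
        raise ValueError("index matrix and agronomy table keys do not align")
    index_cols = list(index_matrix.columns)
    value_cols = index_cols + list(traits)
    rows = []
    for label, grp in iter_groups(merged.reset_index(), scheme, value_cols):
        if len(grp) < 3:
            continue
        for trait in traits:
            yv = grp[trait].to_numpy()
            for idx_name in index_cols:
                res = simple_linear_fit(grp[idx_name].to_numpy(), yv)
                rows.append(
                    {
                        "scheme": scheme,
                        "group": label,
                        "index": idx_name,
                        "trait": trait,
                        "n": res.n,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r2": res.r2,
                        "p": res.p,
                        "stars": significance_stars(res.p) if res.defined else "",
                        "significant": bool(res.defined and res.p <= 0.05),
                    }
                )
    return pd.DataFrame(rows)


def production_function(
    GY: Sequence[float], ET: Sequence[float]
) -> tuple[RegressionResult, float | None]:
    """Linear yield-vs-seasonal-ET production function.

    Returns the OLS fit of GY on ET and the basal seasonal ET
    (-intercept/slope, the ET at which the fitted line crosses zero
    yield), reported only for a positive slope.
    """
    gy = np.asarray(GY, dtype=float)
    et = np.asarray(ET, dtype=float)
    if et.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(et) == 0:
        raise ValueError("ET values do not vary")
    res = simple_linear_fit(et, gy)
    basal = -res.intercept / res.slope if res.slope > 0 else None
    return res, basal
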